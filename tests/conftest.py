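import warnings

import pytest

from fnast8 import io
from fnast8.simulate import default_config, make_fixture_tables, simulate_analysis_frame

DEMO_SEED = 2


@pytest.fixture(scope="session")
def fixture_frame():
    """Deterministic analysis rows matching the published per-cohort
    endorsement counts (derivation cohorts only)."""
    return make_fixture_tables()


@pytest.fixture(scope="session")
def fixture_frame_with_validation():
    return make_fixture_tables(include_validation=True)


@pytest.fixture(scope="session")
def demo_cfg():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return default_config(seed=DEMO_SEED)


@pytest.fixture(scope="session")
def demo_frames(demo_cfg):
    """(derivation rows, validation rows) for the planted-effect demo
    scenario at the packaged demo seed."""
    frame, _ = simulate_analysis_frame(demo_cfg)
    is_val = frame["cohort_id"] == "mother"
    return (
        frame[~is_val].reset_index(drop=True),
        frame[is_val].reset_index(drop=True),
    )
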