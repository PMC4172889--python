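import pytest

from tumorletfdg import TumorletParams, build_grid, run_pipeline


@pytest.fixture(scope="session")
def params() -> TumorletParams:
    return TumorletParams()


@pytest.fixture(scope="session")
def default_grid():
    return build_grid()


@pytest.fixture(scope="session")
def grid_result(params):
    """Full default pipeline: 1315 scenarios with TD50 and uptake scores."""
    return run_pipeline(params)
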