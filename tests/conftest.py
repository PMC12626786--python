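import numpy as np
import pytest

from survcea.cli_reports import RunConfig, build_model
from survcea.synthetic_data import default_params


@pytest.fixture(scope="session")
def preset_model():
    """Decision model built from the synthetic two-arm trial preset via the
    full pipeline (simulate -> digitize -> reconstruct -> fit -> model)."""
    config = RunConfig(seed=1, psa=False, dsa=False, do_scenarios=False)
    model, diagnostics = build_model(config)
    return model


@pytest.fixture(scope="session")
def param_specs():
    return default_params()


@pytest.fixture(scope="session")
def wtp_3x():
    return 3.0 * 12_569.82
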