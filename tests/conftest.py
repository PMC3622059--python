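import numpy as np
import pytest

from clsense import configs
from clsense.experiments import (
    measure_calibration,
    measure_glycine_kcl,
    run_experiment,
)


@pytest.fixture(scope="session")
def fig5_metrics():
    """Rendered glycine + 100 mM KCl challenge (control solution)."""
    return measure_glycine_kcl(render=True)


@pytest.fixture(scope="session")
def calibration_metrics():
    """Rendered perforated-patch calibration experiment."""
    return measure_calibration(render=True)


@pytest.fixture(scope="session")
def fig5_run():
    """Full RunResult of the rendered fig5 configuration."""
    return run_experiment(configs.fig5_glycine_kcl_config(), render=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
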