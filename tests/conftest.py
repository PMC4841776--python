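import numpy as np
import pytest

from plugadapt import synthdata
from plugadapt.spectra import default_grid


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def small_experiment():
    """A cut-down adapting experiment for unit-level smoke tests."""
    templates = synthdata.make_templates(seed=108)
    params = synthdata.ListenerParams(
        n_sessions=4, trials_per_session=160, seed=7, template_set=templates
    )
    return synthdata.simulate_experiment(params)


@pytest.fixture(scope="session")
def adapting_experiment():
    """Full-scale adapting listener: 7 sessions x 800 trials."""
    templates = synthdata.make_templates(seed=121)
    params = synthdata.ListenerParams(seed=20, template_set=templates)
    return synthdata.simulate_experiment(params)


@pytest.fixture(scope="session")
def null_experiment():
    """Full-scale non-adapting listener (constant bias and spectral weight)."""
    templates = synthdata.make_templates(seed=121)
    params = synthdata.ListenerParams(
        seed=21,
        bias_start_deg=10.0,
        bias_end_deg=10.0,
        spectral_weight_start=0.2,
        spectral_weight_end=0.2,
        template_set=templates,
    )
    return synthdata.simulate_experiment(params)
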