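import numpy as np
import pytest

from vfcsf.crf import CRFSpec
from vfcsf.csf import CSFParamSet
from vfcsf.fitting import FIXED_CELLS, FitOptions, full_tying
from vfcsf.observer import ExperimentDesign, make_observer, simulate_experiment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def default_crf():
    return CRFSpec(ct=-1.0)


@pytest.fixture
def lp_params():
    return CSFParamSet(model="LP", alpha=2.0, beta=1.0, delta=100.0)


@pytest.fixture(scope="session")
def paperlike_trials():
    """One simulated observer, moderate budget, all three conditions."""
    observer = make_observer("paper-like")
    design = ExperimentDesign.small(trials_per_sf=60, seed=7)
    return observer, simulate_experiment(observer, design)


@pytest.fixture(scope="session")
def small_fit(paperlike_trials):
    """An LP fit of the fixed-size trials under the most permissive tying."""
    from vfcsf.fitting import fit_model

    _, trials = paperlike_trials
    fixed = trials[trials["scaled"] == 0]
    return fixed, fit_model(
        fixed, "LP", full_tying("LP", FIXED_CELLS), opts=FitOptions(n_starts=6, seed=0)
    )
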