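import numpy as np
import pytest
from scipy.special import expit

from undersmooth.datagen import Cohort, DGPSpec, generate_sim1


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture(scope="session")
def small_confounded_cohort():
    """A small sparse-binary cohort with genuine confounding.

    20 covariates, the first 6 confound exposure and outcome; cheap enough
    for repeated path fits in unit tests.
    """
    spec = DGPSpec(
        design_id="custom", n=1500, d=20, confounder_count=6,
        coefficient_low=0.2, coefficient_high=0.9,
        target_exposure_prevalence=0.35, target_outcome_incidence=0.15,
        coefficient_seed=11, data_seed=12,
    )
    return generate_sim1(spec)


@pytest.fixture(scope="session")
def separable_free_cohort(rng):
    """Exposure independent of all covariates (pure-noise design)."""
    n, d = 1200, 8
    X = (rng.random((n, d)) < 0.3).astype(float)
    A = (rng.random(n) < 0.4).astype(int)
    Y = rng.normal(size=n)
    return Cohort(Y=Y, A=A, X=X)
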