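import numpy as np
import pytest

from famsrm import (
    RoundRobinData,
    SRMParameterSet,
    generate_predictor_condition,
    model_implied_moments,
)
from famsrm.core import MeasurementMatrices


@pytest.fixture(scope="session")
def default_params() -> SRMParameterSet:
    """The standard data-generating variance components."""
    return SRMParameterSet.simulation_defaults()


@pytest.fixture(scope="session")
def default_mm(default_params) -> MeasurementMatrices:
    return model_implied_moments(default_params)


@pytest.fixture(scope="session")
def complete_data(default_params) -> RoundRobinData:
    """500 complete families with role-specific outcomes (fixed seed)."""
    return generate_predictor_condition(500, default_params, seed=20240101)


@pytest.fixture(scope="session")
def toy_model() -> MeasurementMatrices:
    """Full-rank single-factor model: 3 indicators, unit loadings."""
    lam = np.ones((3, 1))
    return MeasurementMatrices(
        loading=lam,
        factor_cov=np.array([[0.8]]),
        resid_cov=0.5 * np.eye(3),
        mean_vector=np.array([1.0, -2.0, 0.5]),
    )


def random_valid_params(rng: np.random.Generator) -> SRMParameterSet:
    """A random parameter set with comfortably PD Psi and Theta."""
    from famsrm.core import DYADS, ROLES, UNORDERED_PAIRS

    act = {r: rng.uniform(0.5, 2.0) for r in ROLES}
    par = {r: rng.uniform(0.5, 2.0) for r in ROLES}
    gen = {r: rng.uniform(-0.3, 0.3) * np.sqrt(act[r] * par[r]) for r in ROLES}
    resid = {d: rng.uniform(0.5, 2.5) for d in DYADS}
    recip = {}
    for p in UNORDERED_PAIRS:
        a, b = p.split("/")
        recip[p] = rng.uniform(-0.3, 0.3) * np.sqrt(resid[a + b] * resid[b + a])
    return SRMParameterSet(
        fam_var=rng.uniform(0.3, 2.0), act_var=act, par_var=par,
        gen_recip=gen, resid_var=resid, dyad_recip=recip,
    )
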