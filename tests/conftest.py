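import numpy as np
import pandas as pd
import pytest

from geowaz.design import ModelSpec, SmoothSpec, assemble_design
from geowaz.sampler import HyperPriors, MCMCConfig, run_gibbs
from geowaz.simulate import recovery_scenario, simulate, tiny_scenario

#: full survey-style model: every categorical of the emulated questionnaire,
#: three P-spline smooths, and the region MRF term
FULL_CATEGORICALS = {
    "child_sex": "male",
    "residence": "urban",
    "electricity": "yes",
    "head_sex": "male",
    "diarrhoea": "no",
    "anaemia": "not_anaemic",
    "education": "no",
}
FULL_SMOOTHS = (
    SmoothSpec("child_age_months"),
    SmoothSpec("mother_age"),
    SmoothSpec("mother_bmi"),
)


def full_model_spec() -> ModelSpec:
    return ModelSpec(
        response="waz",
        categorical=dict(FULL_CATEGORICALS),
        smooths=FULL_SMOOTHS,
        spatial="region",
    )


@pytest.fixture(scope="session")
def recovery_fit():
    """One moderate synthetic dataset fitted with the full model."""
    scen = recovery_scenario(seed=11)
    data, truth = simulate(scen)
    design = assemble_design(data, full_model_spec(), adjacency=scen.adjacency())
    samples = run_gibbs(
        design, HyperPriors(), MCMCConfig(iterations=1600, burnin=400, thin=2, seed=5)
    )
    return scen, data, truth, design, samples


@pytest.fixture(scope="session")
def tiny_fit():
    """A seconds-scale fit on the tiny scenario (no spatial recovery claims)."""
    scen = tiny_scenario(seed=2)
    data, truth = simulate(scen)
    spec = ModelSpec(
        response="waz",
        categorical={"child_sex": "male", "electricity": "yes"},
        smooths=(SmoothSpec("mother_bmi", n_knots=10),),
        spatial="region",
    )
    design = assemble_design(data, spec, adjacency=scen.adjacency())
    samples = run_gibbs(
        design, HyperPriors(), MCMCConfig(iterations=600, burnin=100, thin=1, seed=4)
    )
    return scen, data, truth, design, samples


def batch_means_se(chain: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a chain mean via batch means."""
    chain = np.asarray(chain, dtype=float)
    n = chain.size // n_batches * n_batches
    batches = chain[:n].reshape(n_batches, -1).mean(axis=1)
    return float(batches.std(ddof=1) / np.sqrt(n_batches))
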