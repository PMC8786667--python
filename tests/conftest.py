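import numpy as np
import pytest

from csmf import AgeGroup, CauseTaxonomy, MCMCSettings, StudyDataset, child_taxonomy
from csmf.misclassification import default_matrix
from csmf.simulate import generate_covariates, generate_studies, sparse_truth


@pytest.fixture(scope="session")
def tax_child():
    return child_taxonomy()


@pytest.fixture(scope="session")
def tiny_taxonomy():
    """Four generic causes, last one the base."""
    return CauseTaxonomy.custom(
        AgeGroup.CHILD_1TO59M, ("a", "b", "c", "d"), base_cause="d"
    )


def make_study(deaths, causes, study_id="S0", covariates=(), country="KEN", **kw):
    return StudyDataset(
        study_id=study_id,
        country=country,
        midyear=2010,
        age_group=AgeGroup.CHILD_1TO59M,
        reported_causes=tuple(causes),
        deaths=np.asarray(deaths),
        covariates=np.asarray(covariates, dtype=float),
        covariate_names=tuple(f"x{i+1}" for i in range(len(covariates))),
        **kw,
    )


@pytest.fixture(scope="session")
def small_bundle(tax_child):
    """20 studies x 1000 deaths from a sparse truth; used by several tests."""
    cov = generate_covariates(10, 15, 3, seed=101)
    truth = sparse_truth(tax_child, 3, n_nonzero=2, seed=101)
    studies, matrices, truth = generate_studies(
        truth, cov, tax_child, [1000] * 20, seed=102
    )
    return studies, matrices, truth


@pytest.fixture(scope="session")
def quick_mcmc():
    return MCMCSettings(n_chains=2, n_iter=400, burn_in=400, seed=7)
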