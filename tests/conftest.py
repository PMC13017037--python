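import numpy as np
import pytest

from traitnet.cohort import CohortConfig, generate_cohort
from traitnet.scoring import TRAITS, build_trait_table


def planted_latent_corr(pairs, partial_corr=0.45):
    """Correlation matrix whose only nonzero partial correlations are `pairs`.

    Builds a unit-diagonal precision matrix with -partial_corr at each pair,
    inverts, and rescales to a correlation matrix (partial correlations are
    invariant to the diagonal rescaling).
    """
    p = len(TRAITS)
    ix = {t: i for i, t in enumerate(TRAITS)}
    theta = np.eye(p)
    for a, b in pairs:
        theta[ix[a], ix[b]] = theta[ix[b], ix[a]] = -partial_corr
    S = np.linalg.inv(theta)
    d = np.sqrt(np.diag(S))
    S = S / np.outer(d, d)
    np.fill_diagonal(S, 1.0)
    return S


@pytest.fixture(scope="session")
def cohort24():
    """Default-condition cohort: 24 wild-caught subjects, study missing rate."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def trait_table24(cohort24):
    return build_trait_table(cohort24)


@pytest.fixture(scope="session")
def complete_table24():
    """Fully observed 24-subject trait table (no dropout)."""
    cohort = generate_cohort(CohortConfig(seed=5, missing_rate=0.0))
    return build_trait_table(cohort)
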