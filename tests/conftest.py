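import numpy as np
import pandas as pd
import pytest

from sepsismet.synthetic import CohortSpec, make_cohort, plant_missingness


@pytest.fixture(scope="session")
def default_cohort():
    """Study-shaped synthetic cohort (52 x 63, 19 deaths) with missingness."""
    spec = CohortSpec(seed=11)
    return plant_missingness(make_cohort(spec), spec)


@pytest.fixture(scope="session")
def complete_cohort():
    """Complete (no-missingness) study-shaped cohort."""
    return make_cohort(CohortSpec(seed=11, missing_rate=0.0, n_high_missing_features=0))


@pytest.fixture
def correlated_matrix():
    """60 x 10 positive concentration matrix with strong feature correlation."""
    rng = np.random.default_rng(42)
    p = 10
    L = np.linalg.cholesky(0.8 * np.ones((p, p)) + 0.2 * np.eye(p))
    Z = rng.standard_normal((60, p)) @ L.T
    return pd.DataFrame(np.exp(Z), columns=[f"m{j}" for j in range(p)])
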