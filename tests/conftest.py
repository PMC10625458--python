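import numpy as np
import pytest

from snpscreen import CohortData
from snpscreen.simulate import make_fixture


def random_noties_cohort(seed: int, n_lo: int = 10, n_hi: int = 60, k_max: int = 3) -> CohortData:
    """Small random cohort with continuous (hence untied) times, >=30% events."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    k = int(rng.integers(1, k_max + 1))
    X = rng.standard_normal((n, k))
    beta = rng.uniform(-0.5, 0.5, size=k)
    latent = rng.exponential(size=n) / np.exp(X @ beta)
    cens = rng.exponential(scale=np.quantile(latent, 0.7), size=n)
    time = np.minimum(latent, cens)
    event = (latent <= cens).astype(int)
    if event.sum() < 2:  # keep the partial likelihood informative
        event[np.argsort(latent)[:2]] = 1
        time[np.argsort(latent)[:2]] = latent[np.argsort(latent)[:2]]
    return CohortData(time=time, event=event, covariates=X)


@pytest.fixture
def cox6():
    return make_fixture("cox6")


@pytest.fixture
def aug3():
    return make_fixture("aug3")


@pytest.fixture
def censor_first():
    return make_fixture("censor-first")
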