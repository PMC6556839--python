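import numpy as np
import pytest

from efficog import CohortSpec, WeightedNetwork, sample_cohort

#: CALM-like one-factor loadings used throughout the recovery tests
COG_LOADINGS = (0.75, 0.62, 0.66, 0.82, 0.59)

#: coarse density grid for speed in cohort-level tests (AUC needs >= 2)
FAST_DENSITIES = (0.3, 0.45, 0.6, 0.75, 0.9)


def random_network(rng: np.random.Generator, n: int, density: float = 0.6) -> WeightedNetwork:
    """Random symmetric FA-like network, edges present with prob ``density``."""
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w = np.zeros((n, n))
    w[iu[present], ju[present]] = rng.uniform(0.05, 0.95, present.sum())
    return WeightedNetwork.from_array(w + w.T)


def one_factor_data(
    rng: np.random.Generator, n: int, loadings=COG_LOADINGS
) -> tuple[np.ndarray, np.ndarray]:
    """(data, latent) under a single-factor measurement model."""
    lam = np.asarray(loadings)
    g = rng.standard_normal(n)
    x = lam * g[:, None] + np.sqrt(1 - lam**2) * rng.standard_normal((n, lam.size))
    return x, g


@pytest.fixture(scope="session")
def small_cohort():
    """Small but fully structured cohort shared by read-only tests."""
    spec = CohortSpec(
        n_subjects=80,
        n_nodes=12,
        template_density=0.7,
        densities=FAST_DENSITIES,
        seed=42,
    )
    return sample_cohort(spec)
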