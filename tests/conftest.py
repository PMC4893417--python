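import numpy as np
import pytest

from akisem import synthetic_cohort as sc
from akisem.path_algebra import TraceGraph


@pytest.fixture(scope="session")
def canonical_graph():
    """Standardized path diagram built from the canonical coefficients."""
    directed = {}
    directed.update(sc.LOADINGS)
    directed.update(sc.STRUCTURAL_PATHS)
    return TraceGraph.from_edges(directed, dict(sc.RESIDUAL_CORRELATIONS))


@pytest.fixture(scope="session")
def big_cohort():
    """Large simulated cohort (continuous mortality) for moment checks."""
    cfg = sc.CohortConfig(n_patients=100_000, seed=3,
                          mortality_mode="propensity")
    lats = sc.simulate_latents(cfg)
    matrix = sc.simulate_indicators(lats, cfg)
    return cfg, lats, matrix


@pytest.fixture(scope="session")
def small_cohort():
    cfg = sc.CohortConfig(n_patients=200, seed=11)
    lats = sc.simulate_latents(cfg)
    return cfg, lats, sc.simulate_indicators(lats, cfg)


@pytest.fixture(scope="session")
def latent_frame(big_cohort):
    import pandas as pd

    _, lats, _ = big_cohort
    return pd.DataFrame.from_dict({r.patient_id: r.scores for r in lats},
                                  orient="index")


def assert_loadings_close(a, b, atol):
    """Match factor columns up to permutation and sign, then compare."""
    import itertools

    a = np.asarray(a)
    b = np.asarray(b)
    assert a.shape == b.shape
    k = a.shape[1]
    best = np.inf
    for perm in itertools.permutations(range(k)):
        ap = a[:, perm].copy()
        for j in range(k):
            if np.sum(ap[:, j] * b[:, j]) < 0:
                ap[:, j] = -ap[:, j]
        best = min(best, np.abs(ap - b).max())
    assert best < atol, f"loadings differ by {best:.4g} after alignment"
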