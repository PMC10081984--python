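import numpy as np
import pytest

from stbss import MultivariateField, SpaceTimeLocations


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_locations(rng, n, d=2, t_int=True):
    """Irregular locations; integer times by default (exact-lag friendly)."""
    coords = rng.uniform(0, 5, size=(n, d))
    times = rng.integers(1, 12, size=n).astype(float) if t_int else rng.uniform(0, 10, n)
    return SpaceTimeLocations(coords, times)


def product_design(m_side=3, T=10, spacing=1.0):
    """Regular m_side x m_side site grid observed at T equidistant times."""
    g = np.arange(m_side, dtype=float) * spacing
    gx, gy = np.meshgrid(g, g, indexing="ij")
    sites = np.column_stack([gx.ravel(), gy.ravel()])
    m = sites.shape[0]
    coords = np.repeat(sites, T, axis=0)
    times = np.tile(np.arange(1.0, T + 1), m)
    return SpaceTimeLocations(coords, times)


def brute_force_lacf(values, locs, spec):
    """O(n^2) double-loop oracle for the sample LACF."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    xc = values - values.mean(axis=0)
    M = np.zeros((p, p))
    ssq = 0.0
    for i in range(n):
        for j in range(n):
            h = locs.coords[i] - locs.coords[j]
            tau = locs.times[i] - locs.times[j]
            w = float(spec.weight_from_lags(np.linalg.norm(h), tau))
            ssq += w * w
            if w != 0.0:
                M += w * np.outer(xc[i], xc[j])
    F = np.sqrt(ssq / n)
    return M / (n * F), F


@pytest.fixture
def small_field(rng):
    locs = random_locations(rng, 40)
    return MultivariateField(rng.standard_normal((40, 3))), locs
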