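"""Spatio-temporal kernel functions and pairwise weight structures.

A kernel ``f(h, tau)`` assigns a non-negative weight to a space-time lag,
the product of a spatial factor (depending on ``h`` only through its
Euclidean norm) and a temporal factor (depending on ``tau`` only through
its absolute value).  Kernels generate the pair weights that enter the
local autocovariance (LACF) scatter matrices; the canonical zero-radius
ball kernel ``f0`` selects only coincident space-time points and its LACF
is the ordinary covariance matrix.

Supported factors are the ball (indicator of a closed ball), the ring
(indicator of a half-open annulus, strict at the inner radius), the Gauss
kernel scaled so that the weight drops to ``exp(-0.5 * q95**2)`` at the
nominal radius (``q95`` the 95% standard-normal quantile), and -- for the
temporal axis on equidistant time stamps -- an exact-lag indicator
``I(|tau| = lag)``.  A combined-metric Gauss kernel expressed through the
space-time distance ``(a1*|h|^2 + a2*tau^2)**0.5`` is available as well;
with matched coefficients it coincides with the separable Gauss kernel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import norm

from .exceptions import InvalidParameterError

__all__ = [
    "SpaceTimeLocations",
    "Ball",
    "Ring",
    "Gauss",
    "ExactLag",
    "KernelSpec",
    "st_distance",
    "kernel_weight",
    "weight_matrix",
    "WeightMatrix",
    "f0_kernel",
    "preset_kernels",
    "spec_from_dict",
    "spec_to_dict",
    "kernel_list_from_config",
    "PRESET_NAMES",
]

#: 95% quantile of the standard normal distribution, the Gauss-kernel scale.
Q95 = float(norm.ppf(0.95))

#: Sparse storage is used when the nonzero fraction falls below this.
SPARSE_THRESHOLD = 0.25

#: Above this sample size, finite-support kernels use a neighbour index
#: instead of the dense double loop.
_DENSE_N = 2000


# ---------------------------------------------------------------------------
# sample locations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpaceTimeLocations:
    """The ``n`` sampled space-time coordinates ``(s_i, t_i)``.

    Parameters
    ----------
    coords : (n, d) array
        Spatial coordinates in domain units (grid units, meters, ...).
    times : (n,) array
        Time stamps in domain units (hours, integer indices, ...).
    """

    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        times = np.asarray(self.times, dtype=float).ravel()
        if coords.shape[0] != times.shape[0]:
            raise InvalidParameterError(
                f"coords has {coords.shape[0]} rows but times has {times.shape[0]}"
            )
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise InvalidParameterError("need n >= 1 locations in d >= 1 dimensions")
        if not (np.isfinite(coords).all() and np.isfinite(times).all()):
            raise InvalidParameterError("coordinates and times must be finite")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "times", times)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]

    def subset(self, index: np.ndarray) -> "SpaceTimeLocations":
        return SpaceTimeLocations(self.coords[index], self.times[index])

    def product_design(self):
        """Detect a sites x times product structure.

        Returns ``(sites, time_grid, site_idx, time_idx)`` when every
        combination of a distinct spatial site and a distinct time stamp
        occurs exactly once, with the time grid equidistant; ``None``
        otherwise.  Several estimators use this structure for fast
        pair enumeration.
        """
        sites, site_idx = np.unique(self.coords, axis=0, return_inverse=True)
        tgrid, time_idx = np.unique(self.times, return_inverse=True)
        m, T = sites.shape[0], tgrid.shape[0]
        if m * T != self.n or T < 1:
            return None
        counts = np.bincount(site_idx * T + time_idx, minlength=m * T)
        if not (counts == 1).all():
            return None
        if T > 1:
            steps = np.diff(tgrid)
            if not np.allclose(steps, steps[0], rtol=0, atol=1e-9 * max(1.0, abs(steps[0]))):
                return None
        return sites, tgrid, site_idx.ravel(), time_idx.ravel()


# ---------------------------------------------------------------------------
# kernel factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Ball:
    """Closed-ball indicator ``I(x <= radius)``; ``radius = 0`` keeps zero lag only."""

    radius: float

    def __post_init__(self):
        if self.radius < 0:
            raise InvalidParameterError(f"ball radius must be >= 0, got {self.radius}")

    def weight(self, x: np.ndarray) -> np.ndarray:
        return (x <= self.radius + 1e-12).astype(float)

    @property
    def support(self) -> float:
        return self.radius


@dataclass(frozen=True)
class Ring:
    """Half-open annulus indicator ``I(inner < x <= outer)`` (strict inner edge)."""

    inner: float
    outer: float

    def __post_init__(self):
        inner, outer = self.inner, self.outer
        if inner < 0 or outer < 0:
            raise InvalidParameterError("ring radii must be >= 0")
        if inner > outer:
            warnings.warn(
                f"ring radii given as (inner={inner}, outer={outer}); swapping",
                UserWarning,
                stacklevel=2,
            )
            object.__setattr__(self, "inner", outer)
            object.__setattr__(self, "outer", inner)
        elif inner == outer:
            raise InvalidParameterError("ring requires inner < outer")

    def weight(self, x: np.ndarray) -> np.ndarray:
        return ((x > self.inner) & (x <= self.outer + 1e-12)).astype(float)

    @property
    def support(self) -> float:
        return self.outer


@dataclass(frozen=True)
class Gauss:
    """Gaussian decay ``exp(-0.5 * (q95 * x / radius)**2)``.

    The scaling makes the weight at ``x = radius`` equal the standard
    normal density ratio at its 95% quantile, so ``radius`` plays the
    role of an effective bandwidth comparable to the indicator radii.
    """

    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidParameterError(
                f"gauss radius must be > 0 (division by zero otherwise), got {self.radius}"
            )

    def weight(self, x: np.ndarray) -> np.ndarray:
        return np.exp(-0.5 * (Q95 * np.asarray(x, dtype=float) / self.radius) ** 2)

    @property
    def support(self) -> float:
        return math.inf


@dataclass(frozen=True)
class ExactLag:
    """Temporal indicator ``I(|tau| = lag)`` within an absolute tolerance.

    The adaptation of the indicator kernels for equidistant time stamps:
    only pairs at exactly the requested serial lag contribute.
    """

    lag: float
    tol: float = 1e-9

    def __post_init__(self):
        if self.lag < 0:
            raise InvalidParameterError(f"exact lag must be >= 0, got {self.lag}")
        if self.tol < 0:
            raise InvalidParameterError("tolerance must be >= 0")

    def weight(self, x: np.ndarray) -> np.ndarray:
        return (np.abs(np.asarray(x, dtype=float) - self.lag) <= self.tol).astype(float)

    @property
    def support(self) -> float:
        return self.lag + self.tol


_SPATIAL_TYPES = (Ball, Ring, Gauss)
_TEMPORAL_TYPES = (Ball, Ring, Gauss, ExactLag)


# ---------------------------------------------------------------------------
# kernel specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KernelSpec:
    """A spatio-temporal kernel: spatial factor x temporal factor.

    Either both ``spatial`` and ``temporal`` parts are given, or the
    combined-metric Gauss mode is requested through coefficients
    ``(a1, a2)`` casting squared spatial and temporal lags to a common
    scale; the weight is then ``exp(-0.5 * q95**2 * (a1*|h|^2 + a2*tau^2))``.
    """

    spatial: object = None
    temporal: object = None
    a1: float | None = None
    a2: float | None = None

    def __post_init__(self):
        metric = self.a1 is not None or self.a2 is not None
        if metric:
            if self.spatial is not None or self.temporal is not None:
                raise InvalidParameterError(
                    "metric mode (a1, a2) excludes separate spatial/temporal parts"
                )
            if self.a1 is None or self.a2 is None:
                raise InvalidParameterError("metric mode needs both a1 and a2")
            if self.a1 < 0 or self.a2 < 0 or (self.a1 == 0 and self.a2 == 0):
                raise InvalidParameterError("need a1 >= 0, a2 >= 0, not both zero")
        else:
            if not isinstance(self.spatial, _SPATIAL_TYPES):
                raise InvalidParameterError(
                    f"invalid spatial part {self.spatial!r} (ball/ring/gauss)"
                )
            if not isinstance(self.temporal, _TEMPORAL_TYPES):
                raise InvalidParameterError(
                    f"invalid temporal part {self.temporal!r} (ball/ring/gauss/exact_lag)"
                )

    @property
    def is_metric(self) -> bool:
        return self.a1 is not None

    def weight_from_lags(self, h_norm, tau):
        """Vectorized weight from spatial-lag norms and temporal lags."""
        h_norm = np.abs(np.asarray(h_norm, dtype=float))
        tau = np.abs(np.asarray(tau, dtype=float))
        if self.is_metric:
            return np.exp(-0.5 * Q95**2 * (self.a1 * h_norm**2 + self.a2 * tau**2))
        return self.spatial.weight(h_norm) * self.temporal.weight(tau)

    @property
    def spatial_support(self) -> float:
        if self.is_metric:
            return math.inf if self.a1 == 0 else math.inf  # Gauss: unbounded
        return self.spatial.support

    @property
    def temporal_support(self) -> float:
        if self.is_metric:
            return math.inf
        return self.temporal.support

    def key(self) -> tuple:
        """Hashable identity used for caching LACFs across method presets."""
        return (
            type(self.spatial).__name__ if self.spatial is not None else "metric",
            self.spatial,
            type(self.temporal).__name__ if self.temporal is not None else "metric",
            self.temporal,
            self.a1,
            self.a2,
        )


def f0_kernel() -> KernelSpec:
    """The zero-radius ball kernel whose LACF is the covariance matrix."""
    return KernelSpec(Ball(0.0), Ball(0.0))


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def st_distance(h, tau, a1: float, a2: float) -> float:
    """Combined space-time distance ``(a1*|h|^2 + a2*tau^2)**0.5``.

    The coefficients ``a1, a2 >= 0`` (not both zero) cast the disparate
    units of space and time onto a common scale.
    """
    if a1 < 0 or a2 < 0:
        raise InvalidParameterError("metric coefficients must be >= 0")
    if a1 == 0 and a2 == 0:
        raise InvalidParameterError("metric coefficients must not both be zero")
    h = np.asarray(h, dtype=float)
    hn = np.linalg.norm(np.atleast_1d(h), axis=-1) if h.ndim else np.abs(h)
    return np.sqrt(a1 * hn**2 + a2 * np.abs(tau) ** 2)


def kernel_weight(spec: KernelSpec, h, tau) -> float:
    """Evaluate a kernel at the spatial lag vector ``h`` and temporal lag ``tau``.

    ``h`` may be a lag vector or a scalar already holding ``|h|``.
    """
    h = np.asarray(h, dtype=float)
    hn = np.linalg.norm(np.atleast_1d(h), axis=-1) if h.ndim else np.abs(h)
    out = spec.weight_from_lags(hn, tau)
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class WeightMatrix:
    """An ``n x n`` symmetric pair-weight structure with its nonzero count."""

    matrix: object  # ndarray or scipy.sparse matrix
    n_pairs: int

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def sum_of_squares(self) -> float:
        if sp.issparse(self.matrix):
            return float(self.matrix.multiply(self.matrix).sum())
        return float(np.sum(np.asarray(self.matrix) ** 2))


def _candidate_pairs(locs: SpaceTimeLocations, r_s: float, r_t: float):
    """Unordered pairs (i < j) with ``|h| <= r_s`` and ``|tau| <= r_t``.

    Built from a KD-tree on per-axis normalized coordinates; the returned
    set is a superset of the kernel support and is filtered exactly by
    the caller.  Requires finite support radii.
    """
    eps = 1e-9
    su = locs.coords / max(r_s, eps)
    tu = locs.times[:, None] / max(r_t, eps)
    pts = np.hstack([su, tu])
    tree = cKDTree(pts)
    # |h| <= r_s and |tau| <= r_t imply a combined norm of at most sqrt(2)
    pairs = tree.query_pairs(math.sqrt(2.0) * (1 + 1e-9), output_type="ndarray")
    if len(pairs) == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.intp)
    i, j = pairs[:, 0], pairs[:, 1]
    dh = np.linalg.norm(locs.coords[i] - locs.coords[j], axis=1)
    dt = np.abs(locs.times[i] - locs.times[j])
    keep = (dh <= r_s + 1e-12) & (dt <= r_t + 1e-12)
    return i[keep], j[keep]


def weight_matrix(
    spec: KernelSpec,
    locs: SpaceTimeLocations,
    sparse_threshold: float = SPARSE_THRESHOLD,
) -> WeightMatrix:
    """Materialize ``f(s_i - s_j, t_i - t_j)`` over all ordered pairs.

    Entry ``(i, j)`` is the kernel weight at the lag between samples
    ``i`` and ``j``; the matrix is exactly symmetric because kernels are
    even, and includes the diagonal whenever the kernel admits zero lag.
    Sparse storage is used when the nonzero fraction is below
    ``sparse_threshold``.
    """
    n = locs.n
    finite = math.isfinite(spec.spatial_support) and math.isfinite(spec.temporal_support)
    if n > _DENSE_N and finite:
        i, j = _candidate_pairs(locs, spec.spatial_support, spec.temporal_support)
        dh = np.linalg.norm(locs.coords[i] - locs.coords[j], axis=1)
        dt = locs.times[i] - locs.times[j]
        w = spec.weight_from_lags(dh, dt)
        keep = w != 0
        i, j, w = i[keep], j[keep], w[keep]
        w0 = float(spec.weight_from_lags(0.0, 0.0))
        rows = np.concatenate([i, j])
        cols = np.concatenate([j, i])
        vals = np.concatenate([w, w])
        if w0 != 0.0:
            diag = np.arange(n)
            rows = np.concatenate([rows, diag])
            cols = np.concatenate([cols, diag])
            vals = np.concatenate([vals, np.full(n, w0)])
        mat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
        nnz = mat.nnz
        if nnz / (n * n) >= sparse_threshold:
            return WeightMatrix(mat.toarray(), nnz)
        return WeightMatrix(mat, nnz)

    # dense double loop, built blockwise to bound memory
    mat = np.empty((n, n), dtype=float)
    block = max(1, int(2e7 // max(n, 1)))
    for start in range(0, n, block):
        stop = min(start + block, n)
        dh = np.linalg.norm(
            locs.coords[start:stop, None, :] - locs.coords[None, :, :], axis=2
        )
        dt = locs.times[start:stop, None] - locs.times[None, :]
        mat[start:stop] = spec.weight_from_lags(dh, dt)
    nnz = int(np.count_nonzero(mat))
    if n > 1 and nnz / (n * n) < sparse_threshold:
        return WeightMatrix(sp.csr_matrix(mat), nnz)
    return WeightMatrix(mat, nnz)


# ---------------------------------------------------------------------------
# presets and config parsing
# ---------------------------------------------------------------------------

def _ball0() -> Ball:
    return Ball(0.0)


def preset_kernels(name: str) -> list[KernelSpec]:
    """Expand a named kernel preset to its kernel list.

    The presets pair three families of kernels with the two estimators:
    sole temporal (zero spatial radius, serial lags), sole spatial (unit
    rings at serial lag zero), spatio-temporal (ring x lag combinations),
    and their union:

    - ``stAMUSE.t``: ball(0) x lag 1
    - ``stSOBI.t``: ball(0) x lags 1, 2, 3
    - ``stAMUSE.s``: ring(0, 1) x lag 0
    - ``stSOBI.s``: rings (0,1), (1,2), (2,3) x lag 0
    - ``stAMUSE.st``: ring(0, 1) x lag 1
    - ``stSOBI.st``: rings (0,1), (1,2), (2,3) x lags 1, 2, 3 (nine kernels)
    - ``stSOBI.st2``: union of the stSOBI.t, .s and .st lists
    """
    rings = [Ring(0.0, 1.0), Ring(1.0, 2.0), Ring(2.0, 3.0)]
    lags = [ExactLag(1.0), ExactLag(2.0), ExactLag(3.0)]
    table: dict[str, list[KernelSpec]] = {
        "stAMUSE.t": [KernelSpec(_ball0(), ExactLag(1.0))],
        "stSOBI.t": [KernelSpec(_ball0(), lag) for lag in lags],
        "stAMUSE.s": [KernelSpec(rings[0], ExactLag(0.0))],
        "stSOBI.s": [KernelSpec(r, ExactLag(0.0)) for r in rings],
        "stAMUSE.st": [KernelSpec(rings[0], ExactLag(1.0))],
        "stSOBI.st": [KernelSpec(r, lag) for r in rings for lag in lags],
    }
    table["stSOBI.st2"] = table["stSOBI.t"] + table["stSOBI.s"] + table["stSOBI.st"]
    if name not in table:
        raise InvalidParameterError(
            f"unknown kernel preset {name!r}; available: {sorted(table)}"
        )
    return table[name]


PRESET_NAMES = (
    "stAMUSE.t",
    "stSOBI.t",
    "stAMUSE.s",
    "stSOBI.s",
    "stAMUSE.st",
    "stSOBI.st",
    "stSOBI.st2",
)


def _part_from_dict(d: dict, temporal: bool):
    kind = d.get("type")
    if kind == "ball":
        return Ball(float(d["radius"]))
    if kind == "ring":
        return Ring(float(d["inner"]), float(d["outer"]))
    if kind == "gauss":
        return Gauss(float(d["radius"]))
    if kind == "exact_lag" and temporal:
        return ExactLag(float(d["lag"]), float(d.get("tol", 1e-9)))
    raise InvalidParameterError(f"unknown kernel part {d!r}")


def spec_from_dict(d: dict) -> KernelSpec:
    """Build a kernel spec from its config mapping.

    E.g. ``{"spatial": {"type": "ring", "inner": 0, "outer": 1},
    "temporal": {"type": "exact_lag", "lag": 2}}`` or
    ``{"metric": {"a1": 1.0, "a2": 0.5}}``.
    """
    if "metric" in d:
        m = d["metric"]
        return KernelSpec(a1=float(m["a1"]), a2=float(m["a2"]))
    return KernelSpec(
        _part_from_dict(d["spatial"], temporal=False),
        _part_from_dict(d["temporal"], temporal=True),
    )


def _part_to_dict(part) -> dict:
    if isinstance(part, Ball):
        return {"type": "ball", "radius": part.radius}
    if isinstance(part, Ring):
        return {"type": "ring", "inner": part.inner, "outer": part.outer}
    if isinstance(part, Gauss):
        return {"type": "gauss", "radius": part.radius}
    if isinstance(part, ExactLag):
        return {"type": "exact_lag", "lag": part.lag, "tol": part.tol}
    raise InvalidParameterError(f"unknown kernel part {part!r}")


def spec_to_dict(spec: KernelSpec) -> dict:
    if spec.is_metric:
        return {"metric": {"a1": spec.a1, "a2": spec.a2}}
    return {
        "spatial": _part_to_dict(spec.spatial),
        "temporal": _part_to_dict(spec.temporal),
    }


def kernel_list_from_config(obj) -> list[KernelSpec]:
    """Accept a preset name, a single kernel mapping or a list of mappings."""
    if isinstance(obj, str):
        return preset_kernels(obj)
    if isinstance(obj, dict):
        return [spec_from_dict(obj)]
    return [spec_from_dict(d) for d in obj]
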