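"""Gaussian space-time field simulation and the simulation-study harness.

Latent components are centered, unit-variance Gaussian random fields
with stationary space-time covariance built from univariate blocks:

- ``Matern(sigma2, nu, rho)`` -- spatial Matern covariance
  ``sigma2 / (2**(nu-1) Gamma(nu)) * (h/rho)**nu * K_nu(h/rho)``;
- ``ExpAR1(sigma2, phi)`` -- temporal exponential covariance
  ``sigma2 * phi**|tau|`` of an AR(1) process;
- ``WhiteNoise(sigma2)`` -- nugget on its own axis;
- ``Product(spatial, temporal)`` -- separable product ``C_sp * C_t``;
- ``ProductSum(k1, k2, k3, spatial, temporal)`` -- the product-sum class
  ``k1*C_t*C_sp + k2*C_sp + k3*C_t`` with ``k1 > 0``, ``k2, k3 >= 0``;
- ``Gneiting(sigma2, alpha, gamma, r1, r2)`` -- the non-separable
  Gneiting class with ``psi(u) = u**alpha / r1 + 1`` and
  ``phi(h) = exp(-h**gamma / r2)`` in two spatial dimensions.

The six named model presets reproduce the canonical three-component
benchmark settings: sole spatial (Matern, independent in time), sole
temporal (AR(1), independent in space), two separable product models,
a product-sum model and a Gneiting model.

Sampling exploits the sites x times product structure where possible
(matrix-normal draws from the spatial and temporal Cholesky factors and
sums of independent draws for the product-sum class); non-separable
models fall back to a dense Cholesky of the full ``n x n`` covariance,
guarded by a size limit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gamma as gamma_fn, kv

from .exceptions import InvalidParameterError, SizeGuardError
from .kernels import SpaceTimeLocations, preset_kernels
from .lacf import MultivariateField, lacf_batch
from .metrics import mdi
from .unmixing import (
    joint_diagonalize,
    pca_baseline,
    pseudo_eigenvalues,
    random_guess,
    whiten,
)

__all__ = [
    "Matern",
    "ExpAR1",
    "WhiteNoise",
    "Product",
    "ProductSum",
    "Gneiting",
    "cov_value",
    "MODEL_PRESETS",
    "model_preset",
    "simulate_domain",
    "simulate_latent",
    "mix_field",
    "SimulationConfig",
    "run_study",
    "summarize_study",
    "DEFAULT_MIXING",
]

#: Dense n x n Cholesky sampling is refused above this sample size.
DENSE_GUARD = 6000

_ZERO_TOL = 1e-9


# ---------------------------------------------------------------------------
# covariance models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Matern:
    """Stationary spatial Matern covariance (variance, shape, scale)."""

    sigma2: float = 1.0
    nu: float = 1.0
    rho: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0 or self.nu <= 0 or self.rho <= 0:
            raise InvalidParameterError("matern requires sigma2, nu, rho > 0")

    def cov(self, h):
        h = np.abs(np.asarray(h, dtype=float))
        x = h / self.rho
        with np.errstate(invalid="ignore"):
            val = (
                self.sigma2
                / (2.0 ** (self.nu - 1.0) * gamma_fn(self.nu))
                * x**self.nu
                * kv(self.nu, x)
            )
        return np.where(h < _ZERO_TOL, self.sigma2, val)


@dataclass(frozen=True)
class ExpAR1:
    """Temporal exponential covariance ``sigma2 * phi**|tau|`` (AR(1))."""

    sigma2: float = 1.0
    phi: float = 0.5

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise InvalidParameterError("exp_ar1 requires sigma2 > 0")
        if not (-1.0 < self.phi < 1.0):
            raise InvalidParameterError(f"exp_ar1 requires phi in (-1, 1), got {self.phi}")

    def cov(self, tau):
        a = np.abs(np.asarray(tau, dtype=float))
        if self.phi >= 0:
            return self.sigma2 * self.phi**a
        # negative phi alternates in sign; cos(pi*a) interpolates (-1)**a
        return self.sigma2 * np.abs(self.phi) ** a * np.cos(np.pi * a)


@dataclass(frozen=True)
class WhiteNoise:
    """Nugget: ``sigma2`` at zero lag on its own axis, zero elsewhere."""

    sigma2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise InvalidParameterError("white noise requires sigma2 > 0")

    def cov(self, lag):
        return self.sigma2 * (np.abs(np.asarray(lag, dtype=float)) < _ZERO_TOL)


@dataclass(frozen=True)
class Product:
    """Separable model ``C(h, tau) = C_sp(h) * C_t(tau)``."""

    spatial: object
    temporal: object

    def __post_init__(self):
        if not isinstance(self.spatial, (Matern, WhiteNoise)):
            raise InvalidParameterError("product spatial part must be Matern or WhiteNoise")
        if not isinstance(self.temporal, (ExpAR1, WhiteNoise)):
            raise InvalidParameterError("product temporal part must be ExpAR1 or WhiteNoise")


@dataclass(frozen=True)
class ProductSum:
    """Product-sum model ``k1*C_t*C_sp + k2*C_sp + k3*C_t``."""

    k1: float
    k2: float
    k3: float
    spatial: object
    temporal: object

    def __post_init__(self):
        if self.k1 <= 0 or self.k2 < 0 or self.k3 < 0:
            raise InvalidParameterError("product-sum requires k1 > 0, k2 >= 0, k3 >= 0")
        if not isinstance(self.spatial, (Matern, WhiteNoise)):
            raise InvalidParameterError("product-sum spatial part must be Matern or WhiteNoise")
        if not isinstance(self.temporal, (ExpAR1, WhiteNoise)):
            raise InvalidParameterError("product-sum temporal part must be ExpAR1 or WhiteNoise")


@dataclass(frozen=True)
class Gneiting:
    """Non-separable Gneiting covariance in two spatial dimensions.

    ``C(h, tau) = sigma2 / psi * exp(-h**(2*gamma) / (r2 * psi**gamma))``
    with ``psi = |tau|**(2*alpha) / r1 + 1``; the squared lag arguments
    enter through the generating functions evaluated at ``|tau|**2`` and
    ``|h|**2``, and the single ``psi`` power corresponds to spatial
    dimension 2.
    """

    sigma2: float = 1.0
    alpha: float = 0.5
    gamma: float = 0.5
    r1: float = 1.0
    r2: float = 1.0

    def __post_init__(self):
        if self.sigma2 <= 0:
            raise InvalidParameterError("gneiting requires sigma2 > 0")
        if not (0 < self.alpha <= 1) or not (0 < self.gamma <= 1):
            raise InvalidParameterError("gneiting requires alpha, gamma in (0, 1]")
        if self.r1 <= 0 or self.r2 <= 0:
            raise InvalidParameterError("gneiting requires r1, r2 > 0")


def cov_value(model, h_norm, tau):
    """Evaluate a covariance model at spatial-lag norm ``h_norm`` and lag ``tau``.

    Sole spatial blocks (Matern) are evaluated at ``h_norm`` only and
    sole temporal blocks (ExpAR1) at ``tau`` only; a bare WhiteNoise is
    the nugget at zero space-time lag.
    """
    h = np.abs(np.asarray(h_norm, dtype=float))
    t = np.abs(np.asarray(tau, dtype=float))
    if isinstance(model, Matern):
        return model.cov(h)
    if isinstance(model, ExpAR1):
        return model.cov(t)
    if isinstance(model, WhiteNoise):
        return model.sigma2 * ((h < _ZERO_TOL) & (t < _ZERO_TOL))
    if isinstance(model, Product):
        return model.spatial.cov(h) * model.temporal.cov(t)
    if isinstance(model, ProductSum):
        csp, ct = model.spatial.cov(h), model.temporal.cov(t)
        return model.k1 * ct * csp + model.k2 * csp + model.k3 * ct
    if isinstance(model, Gneiting):
        psi = t ** (2.0 * model.alpha) / model.r1 + 1.0
        return (model.sigma2 / psi) * np.exp(
            -(h ** (2.0 * model.gamma)) / (model.r2 * psi**model.gamma)
        )
    raise InvalidParameterError(f"unknown covariance model {model!r}")


#: The six benchmark model presets (three unit-variance components each).
MODEL_PRESETS: dict[str, list] = {
    "model1": [
        Product(Matern(1.0, 0.7, 1.0), WhiteNoise(1.0)),
        Product(Matern(1.0, 1.0, 1.5), WhiteNoise(1.0)),
        Product(Matern(1.0, 1.3, 2.0), WhiteNoise(1.0)),
    ],
    "model2": [
        Product(WhiteNoise(1.0), ExpAR1(1.0, 0.4)),
        Product(WhiteNoise(1.0), ExpAR1(1.0, 0.6)),
        Product(WhiteNoise(1.0), ExpAR1(1.0, 0.75)),
    ],
    "model3": [
        Product(Matern(1.0, 0.7, 1.0), ExpAR1(1.0, 0.4)),
        Product(Matern(1.0, 1.0, 1.5), ExpAR1(1.0, 0.6)),
        Product(Matern(1.0, 1.3, 2.0), ExpAR1(1.0, 0.75)),
    ],
    "model4": [
        Product(Matern(1.0, 0.7, 1.0), ExpAR1(1.0, 0.4)),
        Product(Matern(1.0, 0.7, 1.0), ExpAR1(1.0, 0.6)),
        Product(Matern(1.0, 1.0, 1.5), ExpAR1(1.0, 0.6)),
    ],
    "model5": [
        ProductSum(5 / 8, 2 / 8, 1 / 8, Matern(1.0, 0.7, 1.0), ExpAR1(1.0, 0.4)),
        ProductSum(1 / 8, 5 / 8, 2 / 8, Matern(1.0, 1.0, 1.5), ExpAR1(1.0, 0.6)),
        ProductSum(2 / 8, 1 / 8, 5 / 8, Matern(1.0, 1.3, 2.0), ExpAR1(1.0, 0.75)),
    ],
    "model6": [
        Gneiting(1.0, 0.35, 0.5, 0.85, 0.8),
        Gneiting(1.0, 0.6, 0.5, 2.3, 2.0),
        Gneiting(1.0, 0.9, 0.5, 9.5, 3.5),
    ],
}


def model_preset(name: str) -> list:
    key = name.lower().replace(" ", "")
    if key not in MODEL_PRESETS:
        raise InvalidParameterError(
            f"unknown model preset {name!r}; available: {sorted(MODEL_PRESETS)}"
        )
    return MODEL_PRESETS[key]


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def simulate_domain(n_sp: int, seed: int) -> SpaceTimeLocations:
    """Draw the benchmark space-time sampling design.

    The spatial domain ``(0, n_sp]^2`` is overlaid with a quarter-unit
    grid of ``(4*n_sp)**2`` candidate points from which ``n_sp**2``
    distinct sites are drawn uniformly without replacement (irregular
    sampling); times are the integers ``1..n_t`` with ``n_t = 2*n_sp**2``
    (dense in time relative to space).  Locations are all site x time
    combinations, site-major.
    """
    if n_sp < 2:
        raise InvalidParameterError(f"n_sp must be >= 2, got {n_sp}")
    rng = np.random.default_rng(seed)
    k = np.arange(1, 4 * n_sp + 1) / 4.0
    gx, gy = np.meshgrid(k, k, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    m = n_sp**2
    idx = rng.choice(grid.shape[0], size=m, replace=False)
    sites = grid[idx]
    n_t = 2 * m
    times = np.arange(1, n_t + 1, dtype=float)
    coords = np.repeat(sites, n_t, axis=0)
    tcol = np.tile(times, m)
    return SpaceTimeLocations(coords, tcol)


def _spatial_matrix(model, sites: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=2)
    return np.asarray(model.cov(d), dtype=float)


def _temporal_matrix(model, tgrid: np.ndarray) -> np.ndarray:
    d = np.abs(tgrid[:, None] - tgrid[None, :])
    return np.asarray(model.cov(d), dtype=float)


def _cholesky_jitter(C: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor with a diagonal jitter fallback.

    On factorization failure, ``1e-10 * trace/n`` is added to the
    diagonal and the jitter grows by a decade for up to three retries;
    needed for near-singular Matern matrices at dense quarter-unit
    spacing.
    """
    n = C.shape[0]
    base = 1e-10 * np.trace(C) / max(n, 1)
    jitter = 0.0
    for attempt in range(4):
        try:
            return np.linalg.cholesky(C + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter = base * 10.0**attempt
    raise np.linalg.LinAlgError(
        f"Cholesky failed even with jitter {jitter:.1e}"
    )


def _dense_component(model, locs: SpaceTimeLocations, rng) -> np.ndarray:
    n = locs.n
    if n > DENSE_GUARD:
        raise SizeGuardError(
            f"dense sampling of n={n} exceeds the guard ({DENSE_GUARD}); "
            "use a product design with a separable model"
        )
    dh = np.linalg.norm(locs.coords[:, None, :] - locs.coords[None, :, :], axis=2)
    dt = locs.times[:, None] - locs.times[None, :]
    C = np.asarray(cov_value(model, dh, dt), dtype=float)
    L = _cholesky_jitter(C)
    return L @ rng.standard_normal(n)


def _kron_component(model, sites, tgrid, site_idx, time_idx, rng) -> np.ndarray:
    m, T = sites.shape[0], tgrid.shape[0]

    def separable_draw(sp_model, t_model):
        Ls = _cholesky_jitter(_spatial_matrix(sp_model, sites))
        Lt = _cholesky_jitter(_temporal_matrix(t_model, tgrid))
        X = Ls @ rng.standard_normal((m, T)) @ Lt.T
        return X[site_idx, time_idx]

    if isinstance(model, Product):
        return separable_draw(model.spatial, model.temporal)
    if isinstance(model, ProductSum):
        out = math.sqrt(model.k1) * separable_draw(model.spatial, model.temporal)
        if model.k2 > 0:
            Ls = _cholesky_jitter(_spatial_matrix(model.spatial, sites))
            u = Ls @ rng.standard_normal(m)
            out = out + math.sqrt(model.k2) * u[site_idx]
        if model.k3 > 0:
            Lt = _cholesky_jitter(_temporal_matrix(model.temporal, tgrid))
            v = Lt @ rng.standard_normal(T)
            out = out + math.sqrt(model.k3) * v[time_idx]
        return out
    raise InvalidParameterError(f"no Kronecker sampling path for {model!r}")


def simulate_latent(
    locs: SpaceTimeLocations,
    models,
    seed: int,
    method: str = "auto",
) -> MultivariateField:
    """Sample mutually independent centered Gaussian components.

    Component ``i`` follows ``models[i]``.  On a sites x times product
    design, separable and product-sum models use the fast matrix-normal
    (Kronecker) path; other models -- and arbitrary designs -- use a
    dense Cholesky of the full space-time covariance, guarded to
    ``n <= 6000``.  Bare Matern/ExpAR1/WhiteNoise blocks must be wrapped
    in ``Product`` to state the behaviour on the other axis explicitly.
    ``method`` may force ``"kron"`` or ``"dense"``.
    """
    models = list(models)
    for mod in models:
        if isinstance(mod, (Matern, ExpAR1, WhiteNoise)):
            raise InvalidParameterError(
                f"{type(mod).__name__} is a marginal building block; wrap it in "
                "Product(...) to define a space-time component model"
            )
    rng = np.random.default_rng(seed)
    design = locs.product_design()
    if method not in ("auto", "kron", "dense"):
        raise InvalidParameterError(f"unknown sampling method {method!r}")
    if method == "kron" and design is None:
        warnings.warn(
            "Kronecker path requested on a non-product design; using dense sampling",
            UserWarning,
            stacklevel=2,
        )
        method = "dense"

    cols = []
    for mod in models:
        kron_ok = design is not None and isinstance(mod, (Product, ProductSum))
        if method == "dense" or not kron_ok:
            cols.append(_dense_component(mod, locs, rng))
        else:
            sites, tgrid, site_idx, time_idx = design
            cols.append(_kron_component(mod, sites, tgrid, site_idx, time_idx, rng))
    return MultivariateField(np.column_stack(cols))


def mix_field(latent: MultivariateField, A: np.ndarray, m=None) -> MultivariateField:
    """Apply the mixing model ``x = A z + m`` row-wise."""
    A = np.asarray(A, dtype=float)
    p = latent.p
    if A.shape != (p, p):
        raise InvalidParameterError(f"A must be {p} x {p}, got {A.shape}")
    if np.linalg.matrix_rank(A) < p:
        raise InvalidParameterError("mixing matrix A is singular")
    m = np.zeros(p) if m is None else np.asarray(m, dtype=float).ravel()
    if m.shape != (p,):
        raise InvalidParameterError(f"location vector must have length {p}")
    return MultivariateField(latent.values @ A.T + m)


# ---------------------------------------------------------------------------
# study harness
# ---------------------------------------------------------------------------

#: A fixed non-trivial mixing matrix used when a study asks for mixed data.
DEFAULT_MIXING = np.array(
    [
        [1.0, 0.5, -0.3],
        [-0.4, 1.2, 0.6],
        [0.2, -0.7, 0.9],
    ]
)


@dataclass
class SimulationConfig:
    """Configuration of a simulation study.

    ``models`` are preset names (``model1`` .. ``model6``) or explicit
    model lists; ``methods`` are kernel-preset names plus optionally
    ``"PCA"`` and ``"random"``; each (model, n_sp) cell is replicated
    ``reps`` times with sites redrawn per replicate.  ``A`` and ``m``
    default to the identity mixing and zero location, which is without
    loss of generality for the affine equivariant estimators.
    """

    models: list
    methods: list
    n_sp: list
    reps: int = 50
    seed: int = 0
    A: np.ndarray | None = None
    m: np.ndarray | None = None

    def __post_init__(self):
        if self.reps < 1:
            raise InvalidParameterError("reps must be >= 1")
        if self.A is not None:
            A = np.asarray(self.A, dtype=float)
            if np.linalg.matrix_rank(A) < A.shape[0]:
                raise InvalidParameterError("mixing matrix A is singular")
            self.A = A


def _method_kernels(name: str):
    if name in ("PCA", "random"):
        return None
    return preset_kernels(name)


def _estimate_w_many(field, locs, methods: list[str], guess_seed: int):
    """Estimate W for several method presets on one dataset.

    The whitening and every distinct whitened LACF are computed once and
    shared across presets; per preset only the (joint) diagonalization
    of the small p x p matrices remains.  Results match running the
    stand-alone estimators kernel list by kernel list.
    """
    xw, whitener, mean, locs_cc = whiten(field, locs)
    kernel_lists = {name: _method_kernels(name) for name in methods}
    unique: dict[tuple, object] = {}
    for specs in kernel_lists.values():
        if specs is None:
            continue
        for spec in specs:
            unique.setdefault(spec.key(), spec)
    keys = list(unique)
    lacfs = lacf_batch(xw, locs_cc, [unique[k] for k in keys]) if keys else []
    mats = {k: (lac.matrix + lac.matrix.T) / 2.0 for k, lac in zip(keys, lacfs)}

    out = {}
    for name in methods:
        specs = kernel_lists[name]
        if name == "PCA":
            out[name] = pca_baseline(field, locs).W
            continue
        if name == "random":
            out[name] = random_guess(field, locs, guess_seed).W
            continue
        Ml = [mats[spec.key()] for spec in specs]
        if len(Ml) == 1:
            _, U = np.linalg.eigh(Ml[0])
            U = U[:, ::-1]
        else:
            U = joint_diagonalize(Ml)
            lam = pseudo_eigenvalues(U, Ml)
            U = U[:, np.argsort(-np.sum(lam**2, axis=1), kind="stable")]
        out[name] = U.T @ whitener
    return out


def run_study(config: SimulationConfig) -> pd.DataFrame:
    """Run the simulation study and score every cell with the MDI.

    Per replicate: draw the sampling design, sample the latent field,
    mix it, estimate the unmixing matrix with every requested method and
    score ``MDI(W_hat, A)``.  Returns a tidy frame with columns
    ``rep, model, method, n_sp, mdi, seed``; per-replicate failures are
    recorded as missing values, not raised.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for model_entry in config.models:
        if isinstance(model_entry, str):
            model_name, models = model_entry, model_preset(model_entry)
        else:
            model_name, models = "custom", list(model_entry)
        p = len(models)
        A = np.eye(p) if config.A is None else config.A
        m = np.zeros(p) if config.m is None else np.asarray(config.m, dtype=float)
        for n_sp in config.n_sp:
            for rep in range(config.reps):
                rep_seed = int(rng.integers(0, 2**31 - 1))
                row_base = {
                    "rep": rep,
                    "model": model_name,
                    "n_sp": n_sp,
                    "seed": rep_seed,
                }
                try:
                    locs = simulate_domain(n_sp, rep_seed)
                    latent = simulate_latent(locs, models, rep_seed + 1)
                    observed = mix_field(latent, A, m)
                    ws = _estimate_w_many(
                        observed, locs, list(config.methods), rep_seed + 2
                    )
                    for name, W in ws.items():
                        rows.append(
                            {**row_base, "method": name, "mdi": mdi(W, A).value}
                        )
                except Exception as exc:  # pragma: no cover - defensive
                    warnings.warn(
                        f"replicate failed ({model_name}, n_sp={n_sp}, rep={rep}): {exc}",
                        UserWarning,
                        stacklevel=2,
                    )
                    for name in config.methods:
                        rows.append({**row_base, "method": name, "mdi": np.nan})
    return pd.DataFrame(rows, columns=["rep", "model", "method", "n_sp", "mdi", "seed"])


def summarize_study(results: pd.DataFrame) -> pd.DataFrame:
    """Mean MDI (and SE) per (model, method, n_sp) cell."""
    g = results.groupby(["model", "method", "n_sp"])["mdi"]
    out = g.agg(mean_mdi="mean", sd="std", n_ok="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n_ok"].clip(lower=1))
    return out.drop(columns="sd")
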