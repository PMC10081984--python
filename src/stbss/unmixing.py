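"""Unmixing matrix estimation: whitening plus (joint) diagonalization.

Under the space-time blind source separation model ``x = A z + m`` the
latent components are zero mean, unit variance and spatio-temporally
uncorrelated, so every LACF of ``z`` is diagonal.  Estimation follows
the classical algebraic BSS outline:

1. whiten the observations with the inverse symmetric square root of
   the covariance (the ``f0`` LACF), reducing the problem to finding an
   orthogonal rotation;
2. find the rotation ``U`` that (jointly) diagonalizes one or several
   whitened LACFs -- exactly via an eigendecomposition for a single
   kernel (stAMUSE), approximately via Givens-rotation sweeps maximizing
   the summed squared diagonals for several kernels (stSOBI);
3. compose ``W = U^T @ whitener`` and recover scores
   ``(x - mean) @ W^T``.

Both estimators are affine equivariant: the recovered sources do not
depend on the mixing, up to order and sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import (
    ConvergenceWarning,
    IdentifiabilityWarning,
    InvalidParameterError,
    RankDeficiencyError,
)
from .kernels import ExactLag, KernelSpec, Ring, SpaceTimeLocations, f0_kernel, spec_to_dict
from .lacf import MultivariateField, lacf_batch

__all__ = [
    "UnmixingResult",
    "whiten",
    "stamuse",
    "stsobi",
    "joint_diagonalize",
    "pseudo_eigenvalues",
    "latent_scores",
    "pca_baseline",
    "random_guess",
]

#: Whitening rejects covariances with condition number above this.
_MAX_CONDITION = 1e12


@dataclass(frozen=True)
class UnmixingResult:
    """Output of an unmixing estimator.

    ``W`` maps centered observations to latent scores and factors as
    ``W = U^T @ whitener`` with ``U`` orthogonal.  ``pseudo_eigs`` holds
    the quadratic forms ``lambda_{i,l} = u_i^T M_l u_i`` of the rotation
    columns in the whitened LACFs; components are ordered so that
    ``sum_l lambda_{i,l}**2`` is non-increasing (for stAMUSE: so that
    the diagonalized LACF values decrease).
    """

    W: np.ndarray
    mean: np.ndarray
    whitener: np.ndarray | None
    U: np.ndarray
    pseudo_eigs: np.ndarray
    kernel_list: list
    method: str
    diag_values: np.ndarray | None = None

    @property
    def p(self) -> int:
        return self.W.shape[0]

    def pseudo_eig_table(self) -> pd.DataFrame:
        """Pseudo-eigenvalues, one row per kernel (Type / Par / Lag), one
        column per latent component."""
        rows = []
        for l, spec in enumerate(self.kernel_list):
            if spec.is_metric:
                ktype, par, lag = "Metric", (spec.a1, spec.a2), ""
            else:
                sp_part = spec.spatial
                ktype = type(sp_part).__name__
                if isinstance(sp_part, Ring):
                    par = (sp_part.inner, sp_part.outer)
                else:
                    par = sp_part.radius
                t_part = spec.temporal
                if isinstance(t_part, ExactLag):
                    lag = t_part.lag
                elif isinstance(t_part, Ring):
                    lag = (t_part.inner, t_part.outer)
                else:
                    lag = t_part.radius
            row = {"Type": ktype, "Par": par, "Lag": lag}
            for i in range(self.p):
                row[f"z{i + 1}"] = self.pseudo_eigs[i, l]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "W": self.W.tolist(),
            "mean": self.mean.tolist(),
            "whitener": None if self.whitener is None else self.whitener.tolist(),
            "U": self.U.tolist(),
            "pseudo_eigenvalues": self.pseudo_eigs.tolist(),
            "kernels": [spec_to_dict(k) for k in self.kernel_list],
            "diag_values": None if self.diag_values is None else self.diag_values.tolist(),
        }


# ---------------------------------------------------------------------------
# whitening
# ---------------------------------------------------------------------------

def _inverse_sqrt(cov: np.ndarray) -> np.ndarray:
    """Symmetric inverse square root of a positive definite matrix."""
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    top = vals[-1]
    if top <= 0 or vals[0] <= 0 or top / vals[0] > _MAX_CONDITION:
        raise RankDeficiencyError(
            f"covariance numerically rank deficient: smallest eigenvalue "
            f"{vals[0]:.3e} against largest {top:.3e}"
        )
    floor = 1e-12 * top
    vals = np.maximum(vals, floor)
    return (vecs / np.sqrt(vals)) @ vecs.T


def whiten(field: MultivariateField, locs: SpaceTimeLocations):
    """Whiten a field with respect to its ``f0`` covariance.

    Returns ``(whitened field, whitener, mean, complete locations)``.
    The whitened values have sample mean zero and ``f0``-covariance
    ``I_p``; rows with missing values are dropped.
    """
    cov_lacf = lacf_batch(field, locs, [f0_kernel()])[0]
    whitener = _inverse_sqrt(cov_lacf.matrix)
    mask = field.complete_mask
    values = field.values[mask]
    locs_cc = locs if mask.all() else locs.subset(mask)
    mean = values.mean(axis=0)
    xw = (values - mean) @ whitener.T
    return MultivariateField(xw), whitener, mean, locs_cc


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def _fix_signs(W: np.ndarray, U: np.ndarray):
    """Scale each row of W (and matching column of U) so its largest-absolute
    element is positive; ties broken by the first such element."""
    for i in range(W.shape[0]):
        row = W[i]
        j = int(np.argmax(np.abs(row)))
        if row[j] < 0:
            W[i] = -row
            U[:, i] = -U[:, i]
    return W, U


def joint_diagonalize(
    matrices,
    tol: float = 1e-10,
    max_sweeps: int = 100,
) -> np.ndarray:
    """Orthogonal approximate joint diagonalizer via cyclic Givens sweeps.

    Maximizes ``sum_l ||diag(U^T M_l U)||_F**2``; since orthogonal
    rotations preserve each matrix's Frobenius mass this equals
    minimizing the total off-diagonal mass.  For every index pair the
    rotation angle is the closed-form maximizer of the pairwise
    objective (Jacobi angle over the stacked matrices).  Terminates when
    all angles in a sweep fall below ``tol``, or at ``max_sweeps`` with
    a convergence warning.
    """
    Ms = np.array([np.asarray(M, dtype=float) for M in matrices])
    if Ms.ndim != 3 or Ms.shape[1] != Ms.shape[2] or Ms.shape[0] < 1:
        raise InvalidParameterError("need at least one square matrix")
    scale = max(1.0, float(np.abs(Ms).max()))
    if np.abs(Ms - Ms.transpose(0, 2, 1)).max() > 1e-8 * scale:
        raise InvalidParameterError("input matrices must be symmetric (within 1e-8)")
    Ms = (Ms + Ms.transpose(0, 2, 1)) / 2.0
    p = Ms.shape[1]
    U = np.eye(p)
    if p == 1:
        return U

    objective = float(np.sum(np.diagonal(Ms, axis1=1, axis2=2) ** 2))
    for sweep in range(max_sweeps):
        max_angle = 0.0
        for i in range(p - 1):
            for j in range(i + 1, p):
                dd = Ms[:, i, i] - Ms[:, j, j]
                od = Ms[:, i, j] + Ms[:, j, i]
                a = float(np.sum(dd**2 - od**2))
                b = float(np.sum(2.0 * dd * od))
                theta = 0.25 * np.arctan2(b, a)
                if abs(theta) <= tol:
                    continue
                max_angle = max(max_angle, abs(theta))
                c, s = np.cos(theta), np.sin(theta)
                # rotate rows/cols i, j of every matrix and columns of U
                Mi, Mj = Ms[:, i, :].copy(), Ms[:, j, :].copy()
                Ms[:, i, :] = c * Mi + s * Mj
                Ms[:, j, :] = -s * Mi + c * Mj
                Mi, Mj = Ms[:, :, i].copy(), Ms[:, :, j].copy()
                Ms[:, :, i] = c * Mi + s * Mj
                Ms[:, :, j] = -s * Mi + c * Mj
                Ui, Uj = U[:, i].copy(), U[:, j].copy()
                U[:, i] = c * Ui + s * Uj
                U[:, j] = -s * Ui + c * Uj
        new_objective = float(np.sum(np.diagonal(Ms, axis1=1, axis2=2) ** 2))
        if new_objective < objective - 1e-9 * max(1.0, objective):
            raise AssertionError(
                "joint diagonalization objective decreased across a sweep"
            )
        objective = new_objective
        if max_angle <= tol:
            return U
    warnings.warn(
        f"joint diagonalization did not converge in {max_sweeps} sweeps "
        f"(last max angle {max_angle:.2e})",
        ConvergenceWarning,
        stacklevel=2,
    )
    return U


def pseudo_eigenvalues(U: np.ndarray, whitened_lacfs) -> np.ndarray:
    """Quadratic forms ``lambda_{i,l} = u_i^T M_l u_i`` as a p x L matrix.

    ``lambda_{i,l}`` measures the spatio-temporal second-order dependence
    of component ``i`` at kernel ``l``; the squared values are summed to
    order components.
    """
    U = np.asarray(U, dtype=float)
    cols = []
    for M in whitened_lacfs:
        M = np.asarray(M, dtype=float)
        if M.shape != (U.shape[0], U.shape[0]):
            raise InvalidParameterError("matrix dimension does not match U")
        cols.append(np.einsum("ip,ij,jp->p", U, M, U))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def stamuse(
    field: MultivariateField,
    locs: SpaceTimeLocations,
    spec: KernelSpec,
) -> UnmixingResult:
    """Unmixing by simultaneous diagonalization of covariance and one LACF.

    Solves the generalized eigenvalue problem exactly: ``W`` satisfies
    ``W Cov W^T = I`` and ``W LACF_f W^T = D_f`` with the diagonal of
    ``D_f`` ordered decreasingly.  Identifiability requires the latent
    LACF diagonal values to be pairwise distinct; a warning is emitted
    when consecutive diagonal entries nearly coincide.
    """
    xw, whitener, mean, locs_cc = whiten(field, locs)
    M = lacf_batch(xw, locs_cc, [spec])[0].matrix
    M = (M + M.T) / 2.0
    vals, vecs = np.linalg.eigh(M)
    order = np.argsort(-vals, kind="stable")
    vals, U = vals[order], vecs[:, order]
    gaps = -np.diff(vals)
    if len(gaps) and gaps.min() < 1e-8:
        warnings.warn(
            f"nearly equal diagonal values (smallest gap {gaps.min():.2e}); "
            "identifiability at risk",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    W = U.T @ whitener
    W, U = _fix_signs(W, U)
    return UnmixingResult(
        W=W,
        mean=mean,
        whitener=whitener,
        U=U,
        pseudo_eigs=vals[:, None],
        kernel_list=[spec],
        method="stAMUSE",
        diag_values=vals,
    )


def stsobi(
    field: MultivariateField,
    locs: SpaceTimeLocations,
    specs,
    tol: float = 1e-10,
    max_sweeps: int = 100,
) -> UnmixingResult:
    """Unmixing by approximate joint diagonalization of several whitened LACFs.

    With a single kernel the result coincides with stAMUSE up to sign
    and order.  Components are ordered by decreasing
    ``sum_l lambda_{i,l}**2``.
    """
    specs = list(specs)
    if len(specs) < 1:
        raise InvalidParameterError("stSOBI needs at least one kernel")
    xw, whitener, mean, locs_cc = whiten(field, locs)
    mats = [lac.matrix for lac in lacf_batch(xw, locs_cc, specs)]
    mats = [(M + M.T) / 2.0 for M in mats]
    U = joint_diagonalize(mats, tol=tol, max_sweeps=max_sweeps)
    lam = pseudo_eigenvalues(U, mats)
    order = np.argsort(-np.sum(lam**2, axis=1), kind="stable")
    U = U[:, order]
    lam = lam[order]
    W = U.T @ whitener
    W, U = _fix_signs(W, U)
    return UnmixingResult(
        W=W,
        mean=mean,
        whitener=whitener,
        U=U,
        pseudo_eigs=lam,
        kernel_list=specs,
        method="stSOBI",
    )


def latent_scores(result: UnmixingResult, field: MultivariateField) -> MultivariateField:
    """Recover latent scores ``(x - mean) @ W^T`` for every row of ``field``."""
    if field.p != result.p:
        raise InvalidParameterError(
            f"field has p={field.p} but unmixing result has p={result.p}"
        )
    return MultivariateField((field.values - result.mean) @ result.W.T)


def pca_baseline(field: MultivariateField, locs: SpaceTimeLocations) -> UnmixingResult:
    """Principal component analysis on the ``f0`` covariance.

    The orthogonal loadings diagonalize the covariance with variances in
    decreasing order; unlike the BSS estimators, PCA uses only marginal
    second moments and ignores spatio-temporal dependence.
    """
    cov = lacf_batch(field, locs, [f0_kernel()])[0].matrix
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2.0)
    order = np.argsort(-vals, kind="stable")
    vals, V = vals[order], vecs[:, order]
    mask = field.complete_mask
    mean = field.values[mask].mean(axis=0)
    W = V.T.copy()
    U = V.copy()
    W, U = _fix_signs(W, U)
    return UnmixingResult(
        W=W,
        mean=mean,
        whitener=None,
        U=U,
        pseudo_eigs=vals[:, None],
        kernel_list=[f0_kernel()],
        method="PCA",
        diag_values=vals,
    )


def random_guess(
    field: MultivariateField,
    locs: SpaceTimeLocations,
    seed: int,
) -> UnmixingResult:
    """Whitening followed by a Haar-random orthogonal rotation.

    All algebraic BSS estimators share the whitening step and differ in
    the rotation; drawing the rotation uniformly at random therefore
    serves as the worst-case baseline.  The draw uses the QR
    decomposition of a standard normal matrix with sign correction and
    is reproducible given ``seed``.
    """
    xw, whitener, mean, _ = whiten(field, locs)
    p = xw.p
    rng = np.random.default_rng(seed)
    G = rng.standard_normal((p, p))
    Q, R = np.linalg.qr(G)
    Q = Q * np.sign(np.where(np.diag(R) == 0, 1.0, np.diag(R)))
    W = Q.T @ whitener
    return UnmixingResult(
        W=W,
        mean=mean,
        whitener=whitener,
        U=Q,
        pseudo_eigs=np.zeros((p, 1)),
        kernel_list=[],
        method="random",
    )
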