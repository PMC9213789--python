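"""Henderson's mixed-model equations for BLUP / GBLUP / ssGBLUP.

The model is ``y = Xb + Zg + e`` with ``g ~ N(0, K sigma_a^2)`` and
``e ~ N(0, I sigma_e^2)``; the equations solved are::

    [ X'X   X'Z          ] [b]   [X'y]
    [ Z'X   Z'Z + Kinv*l ] [g] = [Z'y]      l = sigma_e^2 / sigma_a^2

``Kinv = A^-1`` gives pedigree BLUP, a dense ``G^-1`` gives GBLUP and the
structured single-step ``H^-1`` gives ssGBLUP; unphenotyped and ungenotyped
animals are carried by the same equations. Small systems are solved densely;
large ones by Jacobi-preconditioned conjugate gradients on the (symmetric
positive-definite) coefficient matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg

from .relationship import HInverse

__all__ = ["MixedModelSolution", "solve_mme"]

_DENSE_LIMIT = 3000


@dataclass
class MixedModelSolution:
    """Fixed-effect estimates, random-effect predictions and diagnostics."""

    b: np.ndarray  # fixed effects
    g: np.ndarray  # additive predictions, one per pedigree animal
    converged: bool
    iterations: int
    residual_norm: float


def _kinv_matvec(kinv, x: np.ndarray) -> np.ndarray:
    if isinstance(kinv, HInverse):
        return kinv.matvec(x)
    return kinv @ x


def _kinv_diag(kinv) -> np.ndarray:
    if isinstance(kinv, HInverse):
        return kinv.diagonal()
    if sparse.issparse(kinv):
        return np.asarray(kinv.diagonal())
    return np.diag(kinv)


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    z_idx: np.ndarray,
    kinv,
    lam: float,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> MixedModelSolution:
    """Solve the mixed-model equations.

    Parameters
    ----------
    y
        Phenotype vector (n records).
    X
        Fixed-effect design (n x p), typically a column of ones.
    z_idx
        Animal (pedigree row) of each record; encodes the incidence Z.
    kinv
        Relationship inverse: sparse matrix, dense matrix or `HInverse`.
    lam
        Variance ratio sigma_e^2 / sigma_a^2; must be positive.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != y.size:
        X = X.T
    z_idx = np.asarray(z_idx, dtype=np.int64)
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if y.size != z_idx.size or X.shape[0] != y.size:
        raise ValueError("y, X and z_idx must agree on the number of records")
    n_animals = kinv.shape[0]
    if z_idx.size and (z_idx.min() < 0 or z_idx.max() >= n_animals):
        raise ValueError("z_idx refers to animals outside the relationship matrix")
    p = X.shape[1]

    # Z'Z is diagonal with per-animal record counts; Z'y accumulates records.
    counts = np.bincount(z_idx, minlength=n_animals).astype(np.float64)
    zty = np.bincount(z_idx, weights=y, minlength=n_animals)
    ztx = np.zeros((n_animals, p))
    for j in range(p):
        ztx[:, j] = np.bincount(z_idx, weights=X[:, j], minlength=n_animals)
    xtx = X.T @ X
    rhs = np.concatenate([X.T @ y, zty])

    dim = p + n_animals
    if dim <= _DENSE_LIMIT:
        K = kinv.to_dense() if isinstance(kinv, HInverse) else (
            kinv.toarray() if sparse.issparse(kinv) else np.asarray(kinv, dtype=np.float64)
        )
        C = np.zeros((dim, dim))
        C[:p, :p] = xtx
        C[:p, p:] = ztx.T
        C[p:, :p] = ztx
        C[p:, p:] = lam * K
        C[p:, p:][np.diag_indices(n_animals)] += counts
        try:
            sol = np.linalg.solve(C, rhs)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular mixed-model equations (rank {np.linalg.matrix_rank(C)} < {dim}); "
                "check for confounded fixed effects"
            ) from err
        resid = float(np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300))
        return MixedModelSolution(b=sol[:p], g=sol[p:], converged=True, iterations=0, residual_norm=resid)

    def matvec(v: np.ndarray) -> np.ndarray:
        b, g = v[:p], v[p:]
        top = xtx @ b + ztx.T @ g
        bottom = ztx @ b + counts * g + lam * _kinv_matvec(kinv, g)
        return np.concatenate([top, bottom])

    diag = np.concatenate([np.maximum(np.diag(xtx), 1e-12), counts + lam * _kinv_diag(kinv)])
    op = LinearOperator((dim, dim), matvec=matvec)
    pre = LinearOperator((dim, dim), matvec=lambda v: v / diag)
    sol, info = cg(op, rhs, rtol=rtol, atol=0.0, maxiter=maxiter, M=pre)
    resid = float(np.linalg.norm(matvec(sol) - rhs) / max(np.linalg.norm(rhs), 1e-300))
    return MixedModelSolution(
        b=sol[:p], g=sol[p:], converged=info == 0, iterations=int(info) if info > 0 else maxiter if info else 0,
        residual_norm=resid,
    )
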