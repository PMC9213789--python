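"""Pedigree (numerator) relationship machinery.

Implements the standard animal-model toolkit: Meuwissen-Luo inbreeding
coefficients, the tabular relationship matrix A for small pedigrees, the
sparse direct inverse of A (Henderson's rules with inbreeding), and
matrix-free products ``A @ X`` via the ``A = T D T'`` decomposition
(Colleau's indirect method), from which arbitrary A sub-blocks such as the
genotyped block A22 are assembled without ever forming A.

Pedigrees are coded positionally: animal ``i`` has parents ``sire[i]`` and
``dam[i]`` given as row indices ``< i``, or ``-1`` when unknown.
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy import sparse

__all__ = [
    "validate_pedigree",
    "inbreeding",
    "mendelian_variances",
    "a_matrix",
    "a_inverse",
    "a_times",
    "a_submatrix",
    "numerator_relationship",
]


def validate_pedigree(sire: np.ndarray, dam: np.ndarray) -> None:
    """Reject pedigrees that are not topologically ordered (parents first)."""
    n = sire.size
    idx = np.arange(n)
    if np.any(sire >= idx) or np.any(dam >= idx):
        bad = int(np.flatnonzero((sire >= idx) | (dam >= idx))[0])
        raise ValueError(
            f"pedigree not ordered: animal {bad} has a parent with an equal or "
            "later index (cycle or self-parenting)"
        )


@njit(cache=True)
def _inbreeding_kernel(sire, dam):  # pragma: no cover - exercised via inbreeding()
    n = sire.size
    F = np.zeros(n)
    D = np.empty(n)
    w = np.zeros(n)
    nxt = np.full(n, -2, dtype=np.int64)  # -2 = not in list, -1 = list end
    # Full sibs share F; cache by parent pair (pedigrees are grouped by litter).
    prev_s, prev_d, prev_f = -3, -3, 0.0
    for i in range(n):
        s, d = sire[i], dam[i]
        if s == -1 and d == -1:
            D[i] = 1.0
        elif s == -1:
            D[i] = 0.75 - 0.25 * F[d]
        elif d == -1:
            D[i] = 0.75 - 0.25 * F[s]
        else:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        if s == -1 or d == -1:
            F[i] = 0.0
            continue
        if s == prev_s and d == prev_d:
            F[i] = prev_f
            continue
        # Meuwissen & Luo traversal: F_i = sum_k w_k^2 D_k - 1 over ancestors
        fi = -1.0
        w[i] = 1.0
        nxt[i] = -1
        head = i
        while head != -2 and head != -1:
            k = head
            wk = w[k]
            r = 0.5 * wk
            ks, kd = sire[k], dam[k]
            if ks != -1:
                if nxt[ks] == -2:  # insert ks after its first larger list member
                    j = k
                    while nxt[j] != -1 and nxt[j] > ks:
                        j = nxt[j]
                    nxt[ks] = nxt[j]
                    nxt[j] = ks
                w[ks] += r
            if kd != -1:
                if nxt[kd] == -2:
                    j = k
                    while nxt[j] != -1 and nxt[j] > kd:
                        j = nxt[j]
                    nxt[kd] = nxt[j]
                    nxt[j] = kd
                w[kd] += r
            fi += wk * wk * D[k]
            w[k] = 0.0
            head = nxt[k]
            nxt[k] = -2
        F[i] = fi
        # D of later animals depends on F of their parents; entries for i's
        # descendants are filled on their own iteration, so nothing to redo.
        prev_s, prev_d, prev_f = s, d, fi
    return F, D


def inbreeding(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen-Luo algorithm."""
    F, _ = mendelian_variances(sire, dam)
    return F


_FD_CACHE: dict = {}


def mendelian_variances(sire: np.ndarray, dam: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(F, D): inbreeding and Mendelian-sampling variances (diagonal of D in A = TDT').

    Results are memoised on the pedigree content: evaluation pipelines call
    this many times for the same (large, immutable) pedigree.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    key = (sire.size, hash(sire.tobytes()), hash(dam.tobytes()))
    if key not in _FD_CACHE:
        validate_pedigree(sire, dam)
        if len(_FD_CACHE) > 8:
            _FD_CACHE.clear()
        _FD_CACHE[key] = _inbreeding_kernel(sire, dam)
    return _FD_CACHE[key]


def a_matrix(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method.

    Quadratic in pedigree size; intended for small pedigrees and as the
    oracle for the sparse/indirect routes.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    validate_pedigree(sire, dam)
    n = sire.size
    if n > 20000:
        raise ValueError("tabular A is quadratic in pedigree size; use a_times/a_submatrix")
    return _tabular_kernel(sire, dam)


@njit(cache=True)
def _tabular_kernel(sire, dam):  # pragma: no cover
    n = sire.size
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        for j in range(i):
            aij = 0.0
            if s != -1:
                aij += 0.5 * A[j, s]
            if d != -1:
                aij += 0.5 * A[j, d]
            A[i, j] = aij
            A[j, i] = aij
        aii = 1.0
        if s != -1 and d != -1:
            aii += 0.5 * A[s, d]
        A[i, i] = aii
    return A


def a_inverse(sire: np.ndarray, dam: np.ndarray) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding accounted for."""
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    _, D = mendelian_variances(sire, dam)
    alpha = 1.0 / D
    n = sire.size
    idx = np.arange(n)
    rows = [idx]
    cols = [idx]
    vals = [alpha]
    has_s = sire != -1
    has_d = dam != -1
    for par, has in ((sire, has_s), (dam, has_d)):
        p, i, a = par[has], idx[has], alpha[has]
        rows += [p, i, p]
        cols += [i, p, p]
        vals += [-0.5 * a, -0.5 * a, 0.25 * a]
    both = has_s & has_d
    s, d, a = sire[both], dam[both], alpha[both]
    rows += [s, d]
    cols += [d, s]
    vals += [0.25 * a, 0.25 * a]
    ainv = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    )
    return ainv.tocsr()


@njit(cache=True)
def _a_times_kernel(sire, dam, D, X):  # pragma: no cover
    n, m = X.shape
    V = X.copy()
    for j in range(n - 1, -1, -1):  # V = T' X (children scatter to parents)
        s, d = sire[j], dam[j]
        if s != -1 or d != -1:
            for c in range(m):
                vj = 0.5 * V[j, c]
                if s != -1:
                    V[s, c] += vj
                if d != -1:
                    V[d, c] += vj
    for i in range(n):  # Y = T (D V), forward substitution
        for c in range(m):
            V[i, c] *= D[i]
        s, d = sire[i], dam[i]
        if s != -1 or d != -1:
            for c in range(m):
                acc = V[i, c]
                if s != -1:
                    acc += 0.5 * V[s, c]
                if d != -1:
                    acc += 0.5 * V[d, c]
                V[i, c] = acc
    return V


def a_times(sire: np.ndarray, dam: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Matrix-free product ``A @ X`` in O(n_pedigree * n_columns)."""
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    _, D = mendelian_variances(sire, dam)
    X2 = np.asarray(X, dtype=np.float64)
    single = X2.ndim == 1
    if single:
        X2 = X2[:, None]
    out = _a_times_kernel(sire, dam, D, np.ascontiguousarray(X2))
    return out[:, 0] if single else out


@njit(cache=True)
def _closure_kernel(sire, dam, mark):  # pragma: no cover
    for i in range(mark.size - 1, -1, -1):
        if mark[i]:
            if sire[i] != -1:
                mark[sire[i]] = True
            if dam[i] != -1:
                mark[dam[i]] = True


def ancestor_closure(sire: np.ndarray, dam: np.ndarray, ids: np.ndarray) -> np.ndarray:
    """Row indices of ``ids`` plus all their ancestors, sorted."""
    mark = np.zeros(np.asarray(sire).size, dtype=bool)
    mark[np.asarray(ids, np.int64)] = True
    _closure_kernel(np.asarray(sire, np.int64), np.asarray(dam, np.int64), mark)
    return np.flatnonzero(mark)


def a_submatrix(
    sire: np.ndarray, dam: np.ndarray, ids: np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Dense A block for ``ids`` (e.g. the genotyped block A22) without forming A.

    Relationships flow only through ancestors, so the computation runs on
    the ancestor closure of ``ids`` — usually a small fraction of a deep
    litter pedigree — which leaves the result exact.
    """
    sire = np.asarray(sire, np.int64)
    dam = np.asarray(dam, np.int64)
    ids = np.asarray(ids, np.int64)
    closure = ancestor_closure(sire, dam, ids)
    if closure.size < 0.7 * sire.size:
        remap = np.full(sire.size, -1, np.int64)
        remap[closure] = np.arange(closure.size)
        sub_sire = np.where(sire[closure] >= 0, remap[sire[closure]], -1)
        sub_dam = np.where(dam[closure] >= 0, remap[dam[closure]], -1)
        return a_submatrix(sub_sire, sub_dam, remap[ids], chunk)
    _, D = mendelian_variances(sire, dam)
    n, k = sire.size, ids.size
    out = np.empty((k, k))
    for lo in range(0, k, chunk):
        hi = min(lo + chunk, k)
        E = np.zeros((n, hi - lo))
        E[ids[lo:hi], np.arange(hi - lo)] = 1.0
        out[:, lo:hi] = _a_times_kernel(sire, dam, D, E)[ids]
    return 0.5 * (out + out.T)


def numerator_relationship(
    sire: np.ndarray, dam: np.ndarray
) -> tuple[np.ndarray, sparse.csr_matrix, np.ndarray]:
    """(A, A^-1, F) for a (small) pedigree; the two routes are consistent."""
    A = a_matrix(sire, dam)
    Ainv = a_inverse(sire, dam)
    F = np.diag(A) - 1.0
    return A, Ainv, F
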