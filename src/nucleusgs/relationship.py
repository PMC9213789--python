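"""Genomic (G) and single-step (H) relationship matrices.

G follows VanRaden's first method: column-centered dosages scaled by the
total heterozygosity of the markers used. H^-1 is the standard single-step
construction: A^-1 plus a correction ``Gw^-1 - A22^-1`` on the genotyped
block, with ``Gw`` a weighted blend of G and A22 that guarantees
invertibility and keeps pedigree and genomic information on a common base.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = ["genomic_relationship", "HInverse", "h_inverse"]


def genomic_relationship(
    M: np.ndarray, freqs: np.ndarray | None = None
) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    Parameters
    ----------
    M
        Dosage matrix (individuals x markers) with entries in {0, 1, 2}.
    freqs
        Per-marker allele frequencies of the counted allele. Estimated from
        ``M`` itself when omitted (the usual case: the genotyped set is the
        base). Monomorphic markers contribute nothing.
    """
    M = np.asarray(M, dtype=np.float64)
    if M.ndim != 2:
        raise ValueError("dosage matrix must be 2-D (individuals x markers)")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=np.float64)
    if p.size != M.shape[1]:
        raise ValueError("freqs length must match marker count")
    het = 2.0 * np.sum(p * (1.0 - p))
    if het <= 0:
        raise ValueError("all markers are monomorphic; G is undefined")
    Z = M - 2.0 * p
    if Z.size > 4_000_000:
        # the cross-product dominates large builds; single precision is
        # ample for relationship entries accumulated over thousands of
        # markers and halves the GEMM time
        G = (Z.astype(np.float32) @ Z.astype(np.float32).T).astype(np.float64) / het
    else:
        G = (Z @ Z.T) / het
    return G


@dataclass
class HInverse:
    """H^-1 = A^-1 + [0, 0; 0, Gw^-1 - A22^-1] held in structured form.

    ``ainv`` is the sparse pedigree inverse over the full pedigree and
    ``delta`` the dense genotyped-block correction, indexed by
    ``genotyped``. ``matvec`` applies H^-1 without assembling it.
    """

    ainv: sparse.csr_matrix
    genotyped: np.ndarray  # pedigree row indices of the genotyped block
    delta: np.ndarray  # dense (k, k) correction Gw^-1 - A22^-1

    @property
    def shape(self) -> tuple[int, int]:
        return self.ainv.shape

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.ainv @ x
        if self.genotyped.size:
            y[self.genotyped] += self.delta @ x[self.genotyped]
        return y

    def diagonal(self) -> np.ndarray:
        d = np.asarray(self.ainv.diagonal()).copy()
        if self.genotyped.size:
            d[self.genotyped] += np.diag(self.delta)
        return d

    def to_dense(self) -> np.ndarray:
        H = self.ainv.toarray()
        if self.genotyped.size:
            H[np.ix_(self.genotyped, self.genotyped)] += self.delta
        return H


def tune_g_to_a22(G: np.ndarray, a22: np.ndarray) -> np.ndarray:
    """Rescale G onto the pedigree base: ``a + b*G`` matching A22's means.

    The two coefficients equate the mean diagonal and the overall mean of G
    with those of A22, compensating for allele frequencies being estimated
    in the genotyped animals rather than the pedigree base population.
    """
    ma_g, md_g = float(G.mean()), float(np.diag(G).mean())
    ma_a, md_a = float(a22.mean()), float(np.diag(a22).mean())
    if md_g - ma_g == 0:
        raise ValueError("degenerate G: diagonal mean equals overall mean")
    b = (md_a - ma_a) / (md_g - ma_g)
    a = ma_a - b * ma_g
    return a + b * G


def h_inverse(
    ainv: sparse.spmatrix,
    a22: np.ndarray,
    G: np.ndarray,
    genotyped: np.ndarray,
    blend: float = 0.05,
    tune: bool = True,
) -> HInverse:
    """Assemble the single-step H^-1.

    With ``tune`` (default) G is first rescaled onto the pedigree base via
    :func:`tune_g_to_a22`; then ``Gw = (1 - blend) * G + blend * A22`` is
    inverted in place of G. The 5% blend guarantees invertibility.
    """
    genotyped = np.asarray(genotyped, dtype=np.int64)
    if not 0.0 <= blend <= 1.0:
        raise ValueError("blend must lie in [0, 1]")
    if genotyped.size == 0:
        return HInverse(ainv=sparse.csr_matrix(ainv), genotyped=genotyped, delta=np.zeros((0, 0)))
    k = genotyped.size
    if G.shape != (k, k) or a22.shape != (k, k):
        raise ValueError("G and A22 must be square on the genotyped set")
    if tune:
        G = tune_g_to_a22(G, a22)
    Gw = (1.0 - blend) * G + blend * a22
    try:
        gw_inv = _spd_inverse(Gw)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"blended genomic matrix is singular (blend={blend}); increase the blend"
        ) from err
    a22_inv = _spd_inverse(a22)
    delta = gw_inv - a22_inv
    delta = 0.5 * (delta + delta.T)
    return HInverse(ainv=sparse.csr_matrix(ainv), genotyped=genotyped, delta=delta)


def _spd_inverse(M: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite matrix via Cholesky."""
    from scipy.linalg import lapack

    c, info = lapack.dpotrf(M, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"matrix not positive definite (potrf info={info})")
    inv, info = lapack.dpotri(c, lower=1)
    if info != 0:
        raise np.linalg.LinAlgError(f"inversion failed (potri info={info})")
    return inv + np.tril(inv, -1).T
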