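"""Average-information REML for the single-random-effect animal model.

Estimates ``(sigma_a^2, sigma_e^2)`` in ``y = Xb + g + e`` with
``g ~ N(0, K sigma_a^2)`` where K is the relationship matrix among the
phenotyped individuals (marginalising the unphenotyped ones is exact for
variance estimation). K is eigendecomposed once, after which every AI-REML
iteration costs O(n): in the rotated coordinates the phenotypic covariance
is diagonal, so scores, the average-information matrix and the EM fallback
update are all closed-form diagonal expressions.

Mirroring common practice of repeating the estimation on re-drawn phenotype
subsets and averaging, ``reml_varcomp`` can run ``n_repeats`` fits on random
subsets of the records and average the estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VarianceComponents", "reml_varcomp"]


@dataclass
class VarianceComponents:
    """Additive and residual variance estimates with standard errors."""

    sigma_a2: float
    sigma_e2: float
    se_a2: float
    se_e2: float
    converged: bool
    iterations: int
    boundary: bool  # additive variance pinned near zero

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def h2(self) -> float:
        return self.sigma_a2 / self.sigma_p2

    @property
    def lambda_mme(self) -> float:
        return self.sigma_e2 / max(self.sigma_a2, 1e-12)


def _reml_fit(
    y: np.ndarray, X: np.ndarray, K: np.ndarray, tol: float, max_iter: int
) -> VarianceComponents:
    n = y.size
    s, U = np.linalg.eigh(K)
    s = np.maximum(s, 0.0)
    ys = U.T @ y
    Xs = U.T @ X
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("phenotypes have zero variance; REML is undefined")
    theta = np.array([0.5 * vy, 0.5 * vy])
    floor = 1e-8 * vy

    def core(th):
        d = th[0] * s + th[1]
        dinv = 1.0 / d
        Xw = Xs * dinv[:, None]
        xtvx = Xs.T @ Xw
        xtvx_inv = np.linalg.inv(xtvx)
        beta = xtvx_inv @ (Xw.T @ ys)
        py = dinv * (ys - Xs @ beta)
        return d, dinv, Xw, xtvx_inv, py

    def proj(v, dinv, Xw, xtvx_inv):
        # P v = V^-1 v - V^-1 X (X'V^-1X)^-1 X'V^-1 v  (rotated coords)
        return dinv * v - Xw @ (xtvx_inv @ (Xw.T @ v))

    def tr_PD(w, dinv, Xw, xtvx_inv):
        # trace(P diag(w))
        t1 = float(np.sum(w * dinv))
        T = Xw.T @ (Xw * w[:, None])
        return t1 - float(np.trace(xtvx_inv @ T))

    converged = False
    it = 0
    ai = np.eye(2)
    for it in range(1, max_iter + 1):
        d, dinv, Xw, xtvx_inv, py = core(theta)
        q_a = s * py  # dV/d(sigma_a2) @ Py
        q_e = py
        yPVPy_a = float(py @ q_a)
        yPVPy_e = float(py @ q_e)
        score = -0.5 * np.array(
            [
                tr_PD(s, dinv, Xw, xtvx_inv) - yPVPy_a,
                tr_PD(np.ones(n), dinv, Xw, xtvx_inv) - yPVPy_e,
            ]
        )
        Pq_a = proj(q_a, dinv, Xw, xtvx_inv)
        Pq_e = proj(q_e, dinv, Xw, xtvx_inv)
        ai = 0.5 * np.array(
            [[q_a @ Pq_a, q_a @ Pq_e], [q_a @ Pq_e, q_e @ Pq_e]]
        )
        try:
            step = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            step = None
        pinned = np.zeros(2, bool)
        if step is None:
            # EM fallback keeps estimates in the parameter space.
            em_a = theta[0] + (theta[0] ** 2 / n) * (yPVPy_a - tr_PD(s, dinv, Xw, xtvx_inv))
            em_e = theta[1] + (theta[1] ** 2 / n) * (yPVPy_e - tr_PD(np.ones(n), dinv, Xw, xtvx_inv))
            new = np.array([max(em_a, floor), max(em_e, floor)])
        else:
            new = theta + step
            if np.any(new <= 0):
                # boundary handling: pin the offending variance at the floor
                # and take a reduced Newton step in the free component, so
                # the free component still reaches its own optimum
                pinned = new <= 0
                new = theta.copy()
                new[pinned] = floor
                free = ~pinned
                if free.any():
                    sub = np.linalg.solve(
                        ai[np.ix_(free, free)], score[free]
                    )
                    cand = theta[free] + sub
                    halvings = 0
                    while np.any(cand <= 0) and halvings < 40:
                        sub *= 0.5
                        cand = theta[free] + sub
                        halvings += 1
                    new[free] = np.maximum(cand, floor)
        at_floor = new <= 2 * floor
        free = ~at_floor
        rel = (
            np.max(np.abs(new[free] - theta[free]) / np.maximum(np.abs(theta[free]), 1e-12))
            if free.any()
            else 0.0
        )
        boundary_ok = np.all(score[at_floor] < 0) if at_floor.any() else True
        theta = new
        if rel < tol and boundary_ok:
            converged = True
            break

    try:
        se = np.sqrt(np.maximum(np.diag(np.linalg.inv(ai)), 0.0))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return VarianceComponents(
        sigma_a2=float(theta[0]),
        sigma_e2=float(theta[1]),
        se_a2=float(se[0]),
        se_e2=float(se[1]),
        converged=converged,
        iterations=it,
        boundary=bool(theta[0] <= 10 * floor),
    )


def reml_varcomp(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray,
    n_repeats: int = 1,
    subset_frac: float = 0.9,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> VarianceComponents:
    """AI-REML with EM fallback; optionally averaged over record subsets.

    With ``n_repeats > 1``, each repeat fits a random ``subset_frac`` of the
    records (without replacement) and the estimates (and standard errors)
    are averaged.
    """
    y = np.asarray(y, dtype=np.float64)
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] != y.size:
        X = X.T
    K = np.asarray(K, dtype=np.float64)
    if y.size < 2:
        raise ValueError("need at least two phenotyped individuals")
    if K.shape != (y.size, y.size):
        raise ValueError("K must be square on the phenotyped individuals")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")

    if n_repeats == 1:
        return _reml_fit(y, X, K, tol, max_iter)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = y.size
    m = max(int(round(subset_frac * n)), 2)
    fits = []
    for _ in range(n_repeats):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        fits.append(_reml_fit(y[idx], X[idx], K[np.ix_(idx, idx)], tol, max_iter))
    return VarianceComponents(
        sigma_a2=float(np.mean([f.sigma_a2 for f in fits])),
        sigma_e2=float(np.mean([f.sigma_e2 for f in fits])),
        se_a2=float(np.mean([f.se_a2 for f in fits])),
        se_e2=float(np.mean([f.se_e2 for f in fits])),
        converged=all(f.converged for f in fits),
        iterations=int(np.max([f.iterations for f in fits])),
        boundary=any(f.boundary for f in fits),
    )
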