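"""L1-penalized regression (LASSO) by pathwise cyclic coordinate descent.

This is the sensing engine of the two-step method.  The internal objective is

    O(x) = (1/2n) ||y - A x||^2 + lam ||x||_1,

whose coordinate subproblem is solved exactly by the soft-thresholding
(shrinkage) operator S(v, lam) = sign(v) * max(|v| - lam, 0).  Coordinates are
swept cyclically with an active-set acceleration (full sweeps alternate with
sweeps over the current support, as in glmnet); convergence is declared when
the fractional objective decrease over a full sweep falls below ``tol``
(default 1e-4).

Two penalty conventions are in play and must not be confused:

* ``lam`` as passed to :func:`fit_lasso` is the soft-threshold level of the
  objective above (correlation units, for standardized columns).
* The pipeline-level penalization is quoted in *phenotype-variance units*
  (``lam_var = var(eps) + sigma2_NL``, the two-stage rule implemented by
  :func:`estimate_lambda`).  :func:`penalty_scale` maps variance units to a
  threshold via the universal Gaussian-noise penalty
  ``lam = sqrt(2 * lam_var * log(q) / n)`` for an n x q design — i.e.
  ``lam_var`` plays the role of the residual variance sigma^2 in the classic
  sigma * sqrt(2 log q / n) rate.  See docs/methods.md for the calibration
  argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = ["LassoFit", "shrink", "fit_lasso", "penalty_scale", "estimate_lambda", "kkt_violation"]


@dataclass
class LassoFit:
    """Result of a coordinate-descent LASSO fit."""

    x_hat: np.ndarray
    lam: float
    objective_trace: np.ndarray
    n_used: int
    converged: bool
    sweeps: int

    @property
    def support(self) -> np.ndarray:
        return np.nonzero(self.x_hat)[0]

    @property
    def objective(self) -> float:
        return float(self.objective_trace[-1])


def shrink(v: float, lam: float) -> float:
    """Soft-thresholding operator: v -> sign(v) * max(|v| - lam, 0)."""
    if lam < 0:
        raise ValueError(f"shrinkage threshold must be non-negative, got {lam}")
    if v > lam:
        return v - lam
    if v < -lam:
        return v + lam
    return 0.0


@njit(cache=False)
def _sweep(A, x, r, cnorm, lam, indices, n):
    """One cyclic pass over ``indices``; updates x and residual r in place."""
    for k in range(indices.shape[0]):
        j = indices[k]
        cj = cnorm[j]
        if cj == 0.0:
            continue
        xj = x[j]
        dot = 0.0
        for a in range(n):
            dot += A[a, j] * r[a]
        rho = cj * xj + dot / n
        if rho > lam:
            new = (rho - lam) / cj
        elif rho < -lam:
            new = (rho + lam) / cj
        else:
            new = 0.0
        d = new - xj
        if d != 0.0:
            x[j] = new
            for a in range(n):
                r[a] -= d * A[a, j]


@njit(cache=False)
def _objective(r, x, lam, n):
    rss = 0.0
    for a in range(n):
        rss += r[a] * r[a]
    l1 = 0.0
    for j in range(x.shape[0]):
        l1 += abs(x[j])
    return 0.5 * rss / n + lam * l1


def fit_lasso(
    A: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-4,
    max_sweeps: int = 2000,
    x0: np.ndarray | None = None,
) -> LassoFit:
    """Minimize (1/2n)||y - A x||^2 + lam ||x||_1 by coordinate descent.

    ``A`` should have standardized columns (zero columns are tolerated and
    stay at coefficient zero).  ``x0`` provides a warm start.  Zeros in the
    returned coefficient vector are exact (produced by the shrinkage branch).
    """
    A = np.asarray(A, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if lam < 0:
        raise ValueError(f"lam must be non-negative, got {lam}")
    if not (np.isfinite(A).all() and np.isfinite(y).all()):
        raise ValueError("design or response contains non-finite entries")
    n, q = A.shape
    if y.shape != (n,):
        raise ValueError(f"response length {y.shape} does not match design rows {n}")
    if not A.flags.f_contiguous:
        A = np.asfortranarray(A)

    x = np.zeros(q) if x0 is None else np.array(x0, dtype=np.float64)
    r = y - A @ x
    cnorm = np.einsum("aj,aj->j", A, A) / n
    all_idx = np.arange(q, dtype=np.int64)

    trace = [_objective(r, x, lam, n)]
    sweeps = 0
    converged = False
    while sweeps < max_sweeps:
        _sweep(A, x, r, cnorm, lam, all_idx, n)
        sweeps += 1
        obj = _objective(r, x, lam, n)
        trace.append(obj)
        if abs(trace[-2] - obj) <= tol * max(abs(obj), 1e-300):
            converged = True
            break
        # active-set refinement until it stabilizes, then re-check all coords
        active = np.nonzero(x)[0].astype(np.int64)
        while active.size and sweeps < max_sweeps:
            _sweep(A, x, r, cnorm, lam, active, n)
            sweeps += 1
            obj = _objective(r, x, lam, n)
            trace.append(obj)
            if abs(trace[-2] - obj) <= tol * max(abs(obj), 1e-300):
                break

    return LassoFit(
        x_hat=x,
        lam=lam,
        objective_trace=np.asarray(trace),
        n_used=n,
        converged=converged,
        sweeps=sweeps,
    )


def kkt_violation(A: np.ndarray, y: np.ndarray, fit: LassoFit) -> float:
    """Maximum violation of the LASSO stationarity conditions at ``fit``.

    At an exact solution, (1/n) A_j . r == lam * sign(x_j) on the support and
    |(1/n) A_j . r| <= lam off it.  Returns the largest absolute violation in
    the gradient (correlation) units of ``lam``.
    """
    n = A.shape[0]
    grad = A.T @ (y - A @ fit.x_hat) / n
    on = fit.x_hat != 0
    viol_on = np.abs(grad[on] - fit.lam * np.sign(fit.x_hat[on]))
    viol_off = np.maximum(np.abs(grad[~on]) - fit.lam, 0.0)
    candidates = np.concatenate([viol_on, viol_off])
    return float(candidates.max()) if candidates.size else 0.0


def ols_refit(A: np.ndarray, y: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Unpenalized least-squares refit on a selected support.

    The L1 fit is used for *selection*; refitting on the support removes the
    shrinkage bias when coefficient *values* matter (e.g. the asymptotic
    hyperplane behind the nonlinear-variance estimate).  Returns a full-length
    coefficient vector, zero off the support.
    """
    support = np.asarray(support, dtype=int)
    x = np.zeros(A.shape[1])
    if support.size:
        coef, *_ = np.linalg.lstsq(A[:, support], y, rcond=None)
        x[support] = coef
    return x


def penalty_scale(lam_var: float, n: int, q: int) -> float:
    """Map a penalization in phenotype-variance units to a soft threshold.

    ``sqrt(2 * lam_var * log(q) / n)`` — the universal penalty for Gaussian
    noise of variance ``lam_var`` against ``q`` candidate predictors.  With
    the two-stage rule ``lam_var = var(eps) + sigma2_NL``, the unfittable
    part of the phenotype (environmental noise plus epistatic residue around
    the best linear model) is exactly what this threshold guards against.
    """
    if not 0 < lam_var:
        raise ValueError(f"lam_var must be positive, got {lam_var}")
    return float(np.sqrt(2.0 * lam_var * np.log(max(q, 2)) / n))


def estimate_lambda(
    gm,
    y: np.ndarray,
    noise_var: float,
    mode: str = "synthetic",
    real_factor: float = 1.5,
    epsilon: np.ndarray | None = None,
    asymptotic_ratio: float = 0.95,
    tol: float = 1e-4,
) -> float:
    """Two-stage penalization estimate, in phenotype-variance units.

    Stage 1 fits the linear model with ``lam_var = noise_var`` at a sample
    size close to the locus count (``n = asymptotic_ratio * p`` when that
    many individuals are available) to obtain the asymptotic linear-effects
    vector; the nonlinear variance ``sigma2_NL`` is the variance of the
    phenotype around that hyperplane after removing the noise share (exactly,
    when the realized noise ``epsilon`` is known; otherwise by subtracting
    ``noise_var`` from the residual variance).  The returned penalization is
    ``noise_var + sigma2_NL``, multiplied by ``real_factor`` (in [1.5, 2])
    in ``mode="real"`` to compensate for inter-locus correlation in real
    genotype panels.
    """
    if not 0 < noise_var < 1:
        raise ValueError(f"noise_var must lie in (0, 1), got {noise_var}")
    if mode not in ("synthetic", "real"):
        raise ValueError(f"mode must be 'synthetic' or 'real', got {mode!r}")
    from .genotypes import GenotypeMatrix, standardize_lenient

    X = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    n_avail, p = X.shape
    n_use = min(n_avail, max(int(round(asymptotic_ratio * p)), 1))
    A = np.asfortranarray(standardize_lenient(X[:n_use]))
    yy = np.asarray(y, dtype=float)[:n_use]
    lam_cd = penalty_scale(noise_var, n_use, p)
    yc = yy - yy.mean()
    fit = fit_lasso(A, yc, lam_cd, tol=tol)
    x_star = ols_refit(A, yc, fit.support)
    resid = yc - A @ x_star
    if epsilon is not None:
        sigma2_nl = float(np.var(resid - np.asarray(epsilon)[:n_use]))
    else:
        sigma2_nl = max(float(np.var(resid)) - noise_var, 0.0)
    lam_var = noise_var + sigma2_nl
    if mode == "real":
        lam_var *= real_factor
    return lam_var
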