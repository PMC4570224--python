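"""Step 1: sample-size scan, phase-transition detection, and the asymptotic
linear fit with its model-zero analysis.

The recovery phase transition is detected operationally: LASSO is refit at
increasing sample sizes n, and at each n the median two-sided p-value of the
selected (nonzero-support) markers is recorded, together with its discrete
first derivative in n.  The scan terminates at the first n where both the
median p-value and |derivative| have collapsed by a factor of 1e6 relative to
their values at the start of the scan; that n is the terminal sample size
n_star, the operational entry point of the good-recovery phase.

The asymptotic fit runs the same LASSO at n close to p.  At that sample size
linear recovery is essentially ideal, so the fitted vector x_star is a
property of the generative model itself: the best sparse linear approximation
(hyperplane) to the nonlinear architecture.  The variance left around it,
sigma2_NL = var(y - g x_star - eps), is the nonlinear variance; truly causal
loci whose best univariate linear fit has slope indistinguishable from zero
(nonlinearity hides them from any linear method) are "model zeros".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix, standardize_lenient
from .lasso import LassoFit, fit_lasso, ols_refit, penalty_scale
from .pheno_models import TrueModel

__all__ = [
    "GridSpec",
    "ScanTrace",
    "AsymptoticFit",
    "support_pvalues",
    "scan",
    "asymptotic_fit",
    "classify_false_positives",
    "FP_BINS",
]

TERMINATION_RATIO = 1e-6
FP_BINS = ("0", "1", "2", "3", "4-6")


@dataclass
class GridSpec:
    """Geometric sample-size grid: n_0, ceil(factor * n_0), ... up to max_n."""

    start: int = 50
    factor: float = 1.25
    max_n: int | None = None

    def sizes(self, n_available: int) -> list[int]:
        cap = n_available if self.max_n is None else min(self.max_n, n_available)
        out: list[int] = []
        n = self.start
        while n <= cap:
            out.append(n)
            nxt = math.ceil(self.factor * n)
            if nxt <= n:
                nxt = n + 1
            n = nxt
        return out


@dataclass
class ScanTrace:
    """Trajectory of the Step-1 sample-size scan."""

    n_grid: np.ndarray
    median_p: np.ndarray
    derivative: np.ndarray
    n_star: int | None
    support_at_n_star: np.ndarray
    terminated: bool
    support_sizes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    fit_at_n_star: LassoFit | None = None
    row_order: np.ndarray | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "n": self.n_grid,
                "median_p": self.median_p,
                "derivative": self.derivative,
                "support_size": self.support_sizes,
            }
        )


@dataclass
class AsymptoticFit:
    """Linear fit at n close to p, with nonlinear-variance bookkeeping."""

    x_star: np.ndarray
    sigma2_NL: float
    model_zero_fraction: float
    support: np.ndarray
    n_used: int
    lam_var: float
    causal_pvalues: np.ndarray | None = None


def univariate_pvalues(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the slope of y on each (standardized) column.

    Columns with zero variance (all-zero after lenient standardization) get
    p = 1: a flat regressor carries no evidence.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    sd_y = y.std()
    if sd_y == 0:
        raise ValueError("response is constant; univariate regression is degenerate")
    if n < 3:
        raise ValueError("need at least 3 observations for a slope t-test")
    yc = y - y.mean()
    col_ss = np.einsum("aj,aj->j", A, A)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A.T @ yc) / np.sqrt(col_ss * (yc @ yc))
    r = np.where(col_ss == 0, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def joint_refit_pvalues(A: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-coefficient t-test p-values from a joint OLS refit on all columns.

    Alternative to the marginal tests: fits y on the whole (standardized)
    support at once and tests each coefficient given the others.  Requires
    more observations than columns.
    """
    A = np.asarray(A, dtype=float)
    y = np.asarray(y, dtype=float)
    n, q = A.shape
    if n <= q + 1:
        raise ValueError(
            f"joint refit needs n > q + 1 (got n={n}, q={q}); "
            "use the marginal method near the n ~ support regime"
        )
    X = np.column_stack([np.ones(n), A])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - q - 1
    s2 = (resid @ resid) / dof
    cov = s2 * np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.diag(cov)[1:])
    t = np.divide(coef[1:], se, out=np.zeros(q), where=se > 0)
    return 2.0 * stats.t.sf(np.abs(t), df=dof)


def support_pvalues(
    gm: GenotypeMatrix | np.ndarray,
    y: np.ndarray,
    support: np.ndarray,
    method: str = "marginal",
) -> np.ndarray:
    """P-values of the supported loci.

    ``method="marginal"`` (default, the GWAS convention — well defined even
    when the support size approaches n): univariate OLS slope t-tests.
    ``method="refit"``: per-coefficient tests from one joint OLS refit on
    the support.  Empty support returns an empty array; the scan treats that
    as median 1.
    """
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        return np.array([])
    X = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    A = standardize_lenient(X[:, support])
    if method == "marginal":
        return univariate_pvalues(A, y)
    if method == "refit":
        return joint_refit_pvalues(A, y)
    raise ValueError(f"unknown p-value method {method!r}")


def scan(
    gm: GenotypeMatrix,
    y: np.ndarray,
    lam_var: float,
    grid: GridSpec | None = None,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-4,
) -> ScanTrace:
    """Scan sample size upward until the median-p phase transition completes.

    At each grid n the first n rows of a once-shuffled individual ordering
    are used (scans are nested, enabling warm starts), LASSO is fit at the
    variance-units penalization ``lam_var`` (threshold rescaled per n via
    :func:`~episense.lasso.penalty_scale`), and the median p-value of the
    selected support is recorded.  Termination: both the median p-value and
    the magnitude of its first discrete derivative fall below 1e-6 of their
    initial values (the level at the first grid point; the derivative between
    the first two grid points).  If the grid is exhausted first, the full
    trace is returned with ``terminated=False``.
    """
    grid = grid or GridSpec()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)
    order = rng.permutation(gm.n)
    sizes = grid.sizes(gm.n)
    if not sizes:
        raise ValueError(
            f"grid start {grid.start} exceeds available individuals {gm.n}"
        )

    med, der, supp_sizes = [], [], []
    x_warm: np.ndarray | None = None
    n_star: int | None = None
    support_at_n_star = np.array([], dtype=int)
    fit_at_n_star: LassoFit | None = None
    terminated = False

    for k, n in enumerate(sizes):
        rows = order[:n]
        A = np.asfortranarray(standardize_lenient(gm.dosages[rows]))
        y_sub = y[rows]
        yc = y_sub - y_sub.mean()
        lam_cd = penalty_scale(lam_var, n, gm.p)
        fit = fit_lasso(A, yc, lam_cd, tol=tol, x0=x_warm)
        x_warm = fit.x_hat.copy()
        support = fit.support
        supp_sizes.append(support.size)
        if support.size:
            pvals = univariate_pvalues(A[:, support], y_sub)
            med.append(float(np.median(pvals)))
        else:
            med.append(1.0)
        if k == 0:
            der.append(np.nan)
        else:
            der.append((med[k] - med[k - 1]) / (sizes[k] - sizes[k - 1]))

        if k >= 2:
            p0 = med[0]
            d0 = abs(der[1]) if der[1] != 0 else p0 / (sizes[1] - sizes[0])
            if (
                med[k] <= TERMINATION_RATIO * p0
                and abs(der[k]) <= TERMINATION_RATIO * d0
            ):
                n_star = n
                support_at_n_star = support
                fit_at_n_star = fit
                terminated = True
                break

    return ScanTrace(
        n_grid=np.asarray(sizes[: len(med)]),
        median_p=np.asarray(med),
        derivative=np.asarray(der),
        n_star=n_star,
        support_at_n_star=support_at_n_star,
        terminated=terminated,
        support_sizes=np.asarray(supp_sizes),
        fit_at_n_star=fit_at_n_star,
        row_order=order,
    )


def asymptotic_fit(
    gm: GenotypeMatrix,
    y: np.ndarray,
    epsilon: np.ndarray | None = None,
    lam_var: float | None = None,
    noise_var: float = 0.3,
    ratio: float = 0.95,
    model: TrueModel | None = None,
    model_zero_pvalue: float = 0.01,
    tol: float = 1e-4,
) -> AsymptoticFit:
    """LASSO linear fit at n close to p (default n = 0.95 p).

    ``lam_var`` defaults to ``noise_var`` — the stage-1 penalization of the
    two-stage rule.  ``sigma2_NL`` is computed exactly as
    var(y - A x_star - eps) when the realized noise is supplied (simulation
    mode); on real data it falls back to var(residual) - noise_var, clipped
    at zero.  When the generative model is supplied, each causal locus is
    classified as a model zero if its univariate slope p-value at this near-
    asymptotic n exceeds ``model_zero_pvalue``.
    """
    y = np.asarray(y, dtype=float)
    n_use = min(gm.n, max(int(round(ratio * gm.p)), 2))
    lam_var = noise_var if lam_var is None else lam_var
    A = np.asfortranarray(standardize_lenient(gm.dosages[:n_use]))
    yc = y[:n_use] - y[:n_use].mean()
    lam_cd = penalty_scale(lam_var, n_use, gm.p)
    fit = fit_lasso(A, yc, lam_cd, tol=tol)
    # L1 for selection, OLS refit on the support for the hyperplane values:
    # the penalized coefficients carry shrinkage bias that would inflate
    # sigma2_NL.
    x_star = ols_refit(A, yc, fit.support)
    resid = yc - A @ x_star
    if epsilon is not None:
        sigma2_nl = float(np.var(resid - np.asarray(epsilon)[:n_use]))
    else:
        sigma2_nl = max(float(np.var(resid)) - noise_var, 0.0)

    causal_pvalues = None
    mz_fraction = 0.0
    if model is not None and model.n_causal:
        eff = model.effective_causal_indices
        if eff.size:
            causal_pvalues = univariate_pvalues(A[:, eff], y[:n_use])
            mz_fraction = float(np.mean(causal_pvalues > model_zero_pvalue))

    return AsymptoticFit(
        x_star=x_star,
        sigma2_NL=sigma2_nl,
        model_zero_fraction=mz_fraction,
        support=fit.support,
        n_used=n_use,
        lam_var=lam_var,
        causal_pvalues=causal_pvalues,
    )


def classify_false_positives(
    support: np.ndarray, model: TrueModel
) -> dict[str, object]:
    """Count true/false positives of a selected support against the model.

    False positives are selected loci with no effect in the generative model
    (zero in both z and Z of the bilinear form).  The histogram bin labels
    match the convention 0 / 1 / 2 / 3 / 4-6 (counts of 7 or more, never
    observed in practice, fall in the last bin).
    """
    support = np.asarray(support, dtype=int)
    causal = set(model.effective_causal_indices.tolist())
    tp = sum(1 for j in support if j in causal)
    fp = support.size - tp
    if fp <= 3:
        bin_label = str(fp)
    else:
        bin_label = "4-6"
    return {"TP": tp, "FP": fp, "bin": bin_label}
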