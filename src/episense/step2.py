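"""Step 2: quadratic feature expansion over the selected subspace and the
nonlinear-effect fit.

Given the s loci selected in Step 1, the general quadratic model restricted
to that subspace is linear in its coefficient vector X: the design G(g) has
s linear columns, s squared columns, and s(s-1)/2 pairwise-product columns
(s(s-1)/2 + 2s in total).  The same L1-penalized fit used in Step 1 then
extracts the sparse X, which maps back to linear effects z_hat and a
symmetric interaction matrix Z_hat on the original locus indices.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import sparse

from .genotypes import GenotypeMatrix, standardize_lenient
from .lasso import LassoFit, fit_lasso, penalty_scale

__all__ = [
    "FeatureExpansion",
    "Step2Fit",
    "expand_features",
    "fit_step2",
    "pack_effects",
    "unpack_effects",
    "expansion_size",
]


def expansion_size(s: int) -> int:
    """Number of quadratic-expansion columns: s(s-1)/2 + 2s."""
    return s * (s - 1) // 2 + 2 * s


@dataclass
class FeatureExpansion:
    """Standardized quadratic design over a locus subset.

    ``descriptors[k]`` is ``(kind, i, j)`` with kind in {"linear", "square",
    "pair"}; i, j are original locus indices (j is None except for pairs).
    ``means``/``scales`` standardize each raw expansion column, so fitted
    coefficients divide by ``scales`` to return to the units of the
    generative model (standardized dosages and their products).
    """

    design: np.ndarray
    descriptors: list[tuple[str, int, int | None]]
    means: np.ndarray
    scales: np.ndarray
    support: np.ndarray


@dataclass
class Step2Fit:
    """Fitted quadratic model over the Step-1 subspace."""

    support: np.ndarray
    G_columns: list[tuple[str, int, int | None]]
    X_hat: np.ndarray  # model units (per raw expansion column)
    z_hat: dict[int, float]
    Z_hat: sparse.csr_array
    sigma2_R: float
    lam_var: float
    fit: LassoFit


def expand_features(
    gm: GenotypeMatrix | np.ndarray, support: np.ndarray
) -> FeatureExpansion:
    """Build the quadratic design over ``support``.

    Column order is fixed: the s standardized linear terms, their s squares,
    then the s(s-1)/2 pairwise products in lexicographic pair order.  Squares
    and products are computed from the standardized dosages and then each
    expansion column is itself standardized (collinearity between a column
    and its square at extreme allele frequency is left to the penalizer).
    """
    support = np.asarray(support, dtype=int)
    if support.size == 0:
        raise ValueError("support must contain at least one locus")
    if len(np.unique(support)) != support.size:
        raise ValueError("support contains duplicate locus indices")
    X = gm.dosages if isinstance(gm, GenotypeMatrix) else np.asarray(gm)
    g = standardize_lenient(X[:, support])
    s = support.size

    cols = [g]
    descriptors: list[tuple[str, int, int | None]] = [
        ("linear", int(l), None) for l in support
    ]
    cols.append(g**2)
    descriptors += [("square", int(l), int(l)) for l in support]
    if s > 1:
        pair_idx = list(combinations(range(s), 2))
        pairs = np.column_stack([g[:, i] * g[:, j] for i, j in pair_idx])
        cols.append(pairs)
        descriptors += [
            ("pair", int(support[i]), int(support[j])) for i, j in pair_idx
        ]
    raw = np.column_stack(cols) if len(cols) > 1 else cols[0]

    means = raw.mean(axis=0)
    scales = raw.std(axis=0, ddof=0)
    safe = np.where(scales == 0, 1.0, scales)
    design = (raw - means) / safe
    design[:, scales == 0] = 0.0
    return FeatureExpansion(
        design=np.asfortranarray(design),
        descriptors=descriptors,
        means=means,
        scales=scales,
        support=support,
    )


def unpack_effects(
    X_hat: np.ndarray,
    descriptors: list[tuple[str, int, int | None]],
    p: int,
) -> tuple[dict[int, float], sparse.csr_array]:
    """Map an expansion coefficient vector to (z_hat, Z_hat).

    Pair coefficients c are split symmetrically (Z_ij = Z_ji = c/2), matching
    the convention used to rewrite the generative models in bilinear form, so
    recovered and generative interaction matrices compare entry by entry.
    """
    z_hat: dict[int, float] = {}
    rows, cols, vals = [], [], []
    for coef, (kind, i, j) in zip(X_hat, descriptors):
        if coef == 0:
            continue
        if kind == "linear":
            z_hat[i] = z_hat.get(i, 0.0) + float(coef)
        elif kind == "square":
            rows.append(i)
            cols.append(i)
            vals.append(float(coef))
        else:
            rows.extend([i, j])
            cols.extend([j, i])
            vals.extend([float(coef) / 2, float(coef) / 2])
    Z = sparse.csr_array(sparse.coo_array((vals, (rows, cols)), shape=(p, p)))
    return z_hat, Z


def pack_effects(
    z_hat: dict[int, float],
    Z_hat: sparse.sparray,
    descriptors: list[tuple[str, int, int | None]],
) -> np.ndarray:
    """Inverse of :func:`unpack_effects` for coefficients on the expansion."""
    Z = sparse.csr_array(Z_hat)
    out = np.zeros(len(descriptors))
    for k, (kind, i, j) in enumerate(descriptors):
        if kind == "linear":
            out[k] = z_hat.get(i, 0.0)
        elif kind == "square":
            out[k] = Z[i, i]
        else:
            out[k] = 2.0 * Z[i, j]
    return out


def fit_step2(
    gm: GenotypeMatrix,
    y: np.ndarray,
    support: np.ndarray,
    lam_var: float,
    epsilon: np.ndarray | None = None,
    rows: np.ndarray | None = None,
    noise_var: float = 0.3,
    tol: float = 1e-4,
    penalty_q: int | None = None,
) -> Step2Fit:
    """Fit the quadratic model on the Step-1 subspace by L1-penalized descent.

    ``rows`` selects the individuals to fit on (default: all; a Step-1 scan
    passes the same n_star rows it used).  The penalization is *reused* from
    Step 1: the same variance-units ``lam_var`` mapped at the genome-wide
    dimension (``penalty_q`` defaults to the full locus count), i.e. the same
    soft-threshold Step 1 applied at this sample size — not a weaker
    threshold re-derived for the small expanded design.  ``sigma2_R`` is the
    variance of the phenotype around the fitted quadratic model, net of
    noise — exact when the realized ``epsilon`` is given, otherwise
    var(residual) - noise_var.
    """
    y = np.asarray(y, dtype=float)
    if rows is None:
        rows = np.arange(gm.n)
    support = np.asarray(support, dtype=int)
    sub = gm.dosages[rows][:, support]
    expansion = expand_features(sub, np.arange(support.size))
    # expand_features standardized within the row subset using local column
    # numbers; remap descriptors onto the original locus indices.
    descriptors = []
    for kind, i, j in expansion.descriptors:
        oi = int(support[i])
        oj = None if j is None else int(support[j])
        descriptors.append((kind, oi, oi if kind == "square" else oj))
    expansion.descriptors = descriptors
    expansion.support = support

    F = expansion.design
    y_sub = y[rows]
    yc = y_sub - y_sub.mean()
    n, q = F.shape
    lam_cd = penalty_scale(lam_var, n, gm.p if penalty_q is None else penalty_q)
    fit = fit_lasso(F, yc, lam_cd, tol=tol)

    resid = yc - F @ fit.x_hat
    if epsilon is not None:
        sigma2_r = float(np.var(resid - np.asarray(epsilon)[rows]))
    else:
        sigma2_r = max(float(np.var(resid)) - noise_var, 0.0)

    safe = np.where(expansion.scales == 0, 1.0, expansion.scales)
    x_model_units = fit.x_hat / safe
    z_hat, Z_hat = unpack_effects(x_model_units, descriptors, gm.p)
    return Step2Fit(
        support=support,
        G_columns=descriptors,
        X_hat=x_model_units,
        z_hat=z_hat,
        Z_hat=Z_hat,
        sigma2_R=sigma2_r,
        lam_var=lam_var,
        fit=fit,
    )
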