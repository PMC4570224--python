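"""Generative genetic architectures: block-diagonal (BD), promiscuous (PS),
and the general bilinear form they embed into.

Both model families are sparse nonlinear (epistatic) maps from genotype to
phenotype.  With g_i the standardized dosage at causal locus i:

BD:  y = sum_i alpha_i g_i + sum_i beta_i g_i^2
         + sum_{i<s} gamma_i g_i g_{i+1} + eps
     — s causal loci, each with linear and quadratic effects, plus
     chain-coupled pairwise interactions within the block.

PS:  y = sum_{i<=s} alpha'_i g_i + sum_{i<=s'} beta'_i g_{s+i}^2
         + sum_{i<=s'/2} gamma'_i g_i g_{s+i} + eps
     — s purely-linear loci, s' purely-quadratic loci, and s'/2 cross
     interactions between the two groups.

Any such model is an instance of the general bilinear family
y = g.z + g.Z.g + eps with z a sparse linear-effect vector and Z a sparse
symmetric interaction matrix; :func:`to_general_form` performs the rewrite.

Phenotypes are normalized so that the realized total variance is 1 and the
realized environmental-noise variance equals ``noise_var`` (default 0.3),
giving broad-sense heritability H^2 = 0.7.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import json
import os

import numpy as np
from scipy import sparse

from .genotypes import GenotypeMatrix, standardize_lenient

__all__ = [
    "TrueModel",
    "PhenotypeSet",
    "sample_bd_model",
    "sample_ps_model",
    "to_general_form",
    "simulate_phenotypes",
]

DEFAULT_NOISE_VAR = 0.3

# BD coefficient distributions: positive O(1) means, sds below the means.
BD_ALPHA = (1.5, 0.5)
BD_BETA = (1.0, 0.2)
BD_GAMMA = (0.5, 0.1)
# PS quadratic/interaction coefficients: order unity, negatives excluded.
PS_BETA = (1.0, 0.25)
PS_GAMMA = (1.0, 0.25)


@dataclass
class TrueModel:
    """A generative architecture with its coefficients and causal-locus map.

    ``causal_indices[k]`` is the genome-wide column carrying model-internal
    locus k (BD: k in 0..s-1; PS: 0..s-1 linear block then s..s+s'-1
    quadratic block).
    """

    family: str  # "BD" | "PS" | "general"
    p: int
    causal_indices: np.ndarray
    s: int = 0
    s_prime: int = 0
    noise_var: float = DEFAULT_NOISE_VAR
    alpha: np.ndarray | None = None
    beta: np.ndarray | None = None
    gamma: np.ndarray | None = None
    alpha_p: np.ndarray | None = None
    beta_p: np.ndarray | None = None
    gamma_p: np.ndarray | None = None
    z: np.ndarray | None = None
    Z: sparse.sparray | None = None
    seed: int | None = None

    @property
    def n_causal(self) -> int:
        return len(self.causal_indices)

    @property
    def effective_causal_indices(self) -> np.ndarray:
        """Loci carrying a nonzero effect in the bilinear form (z, Z).

        A PS linear-block locus can draw alpha' = 0; if it is also uncoupled
        it has no effect on the phenotype and is excluded here (selection
        scoring should not demand its recovery).
        """
        if self.family == "BD":
            return self.causal_indices
        z, Z = to_general_form(self)
        touched = np.abs(z) > 0
        touched |= np.asarray(np.abs(Z).sum(axis=0)).ravel() > 0
        return np.nonzero(touched)[0]

    def to_json(self, path: str | os.PathLike) -> None:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        payload = {
            "family": self.family,
            "p": self.p,
            "s": self.s,
            "s_prime": self.s_prime,
            "noise_var": self.noise_var,
            "causal_indices": arr(self.causal_indices),
            "alpha": arr(self.alpha),
            "beta": arr(self.beta),
            "gamma": arr(self.gamma),
            "alpha_p": arr(self.alpha_p),
            "beta_p": arr(self.beta_p),
            "gamma_p": arr(self.gamma_p),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "TrueModel":
        with open(path) as fh:
            d = json.load(fh)

        def arr(a):
            return None if a is None else np.asarray(a, dtype=float)

        return cls(
            family=d["family"],
            p=d["p"],
            s=d["s"],
            s_prime=d["s_prime"],
            noise_var=d["noise_var"],
            causal_indices=np.asarray(d["causal_indices"], dtype=int),
            alpha=arr(d["alpha"]),
            beta=arr(d["beta"]),
            gamma=arr(d["gamma"]),
            alpha_p=arr(d["alpha_p"]),
            beta_p=arr(d["beta_p"]),
            gamma_p=arr(d["gamma_p"]),
            seed=d["seed"],
        )


@dataclass
class PhenotypeSet:
    """Simulated phenotypes with exact variance bookkeeping.

    ``y = genetic_component + epsilon`` holds exactly; ``variance_report``
    records the realized shares of the normalized phenotype.
    """

    y: np.ndarray
    epsilon: np.ndarray
    genetic_component: np.ndarray
    variance_report: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.y)

    def to_tsv(self, path: str | os.PathLike) -> None:
        import pandas as pd

        pd.DataFrame(
            {"individual_id": np.arange(self.n), "y": self.y}
        ).to_csv(path, sep="\t", index=False)


def _pick_causal(p: int, k: int, rng: np.random.Generator) -> np.ndarray:
    # Causal loci are scattered over the genome (not a contiguous prefix) so
    # that support-recovery scoring exercises the whole index space.
    return np.sort(rng.choice(p, size=k, replace=False))


def sample_bd_model(
    s: int, p: int, seed: int | np.random.Generator, noise_var: float = DEFAULT_NOISE_VAR
) -> TrueModel:
    """Draw a BD architecture: alpha ~ N(1.5, 0.5^2), beta ~ N(1.0, 0.2^2),
    gamma ~ N(0.5, 0.1^2), on a random size-s causal subset of the p loci."""
    if not 1 <= s <= p:
        raise ValueError(f"need 1 <= s <= p, got s={s}, p={p}")
    rng = np.random.default_rng(seed)
    return TrueModel(
        family="BD",
        p=p,
        s=s,
        causal_indices=_pick_causal(p, s, rng),
        noise_var=noise_var,
        alpha=rng.normal(*BD_ALPHA, size=s),
        beta=rng.normal(*BD_BETA, size=s),
        gamma=rng.normal(*BD_GAMMA, size=s - 1),
        seed=seed if isinstance(seed, int) else None,
    )


def _truncated_positive_normal(
    mean: float, sd: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = out <= 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out <= 0
    return out


def sample_ps_model(
    s: int,
    s_prime: int,
    p: int,
    seed: int | np.random.Generator,
    noise_var: float = DEFAULT_NOISE_VAR,
) -> TrueModel:
    """Draw a PS architecture: alpha' uniform on {-1, 0, 1}; beta', gamma'
    order-unity positive normals (N(1, 0.25^2) truncated to > 0)."""
    if s_prime % 2 != 0:
        raise ValueError(f"s_prime must be even (s'/2 interacting pairs), got {s_prime}")
    if s + s_prime > p:
        raise ValueError(f"need s + s_prime <= p, got {s}+{s_prime} > {p}")
    if s_prime // 2 > s:
        raise ValueError("s'/2 interacting pairs require s >= s'/2")
    rng = np.random.default_rng(seed)
    return TrueModel(
        family="PS",
        p=p,
        s=s,
        s_prime=s_prime,
        causal_indices=_pick_causal(p, s + s_prime, rng),
        noise_var=noise_var,
        alpha_p=rng.choice([-1.0, 0.0, 1.0], size=s),
        beta_p=_truncated_positive_normal(*PS_BETA, s_prime, rng),
        gamma_p=_truncated_positive_normal(*PS_GAMMA, s_prime // 2, rng),
        seed=seed if isinstance(seed, int) else None,
    )


def to_general_form(model: TrueModel) -> tuple[np.ndarray, sparse.csr_array]:
    """Rewrite a BD/PS model as (z, Z): y = g.z + g.Z.g + eps.

    Diagonal Z_ii absorbs the quadratic (g^2) coefficients; each cross term
    c * g_i g_j is split symmetrically, Z_ij = Z_ji = c/2; z absorbs the
    linear coefficients.
    """
    p = model.p
    c = model.causal_indices
    z = np.zeros(p)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add_sym(i: int, j: int, v: float) -> None:
        if i == j:
            rows.append(i)
            cols.append(j)
            vals.append(v)
        else:
            rows.extend([i, j])
            cols.extend([j, i])
            vals.extend([v / 2, v / 2])

    if model.family == "BD":
        for k in range(model.s):
            z[c[k]] += model.alpha[k]
            add_sym(c[k], c[k], model.beta[k])
        for k in range(model.s - 1):
            add_sym(c[k], c[k + 1], model.gamma[k])
    elif model.family == "PS":
        s, sp = model.s, model.s_prime
        for k in range(s):
            z[c[k]] += model.alpha_p[k]
        for k in range(sp):
            add_sym(c[s + k], c[s + k], model.beta_p[k])
        for k in range(sp // 2):
            add_sym(c[k], c[s + k], model.gamma_p[k])
    else:
        raise ValueError(f"cannot rewrite family {model.family!r}")

    Z = sparse.csr_array(
        sparse.coo_array((vals, (rows, cols)), shape=(p, p))
    )
    return z, Z


def genetic_values(model: TrueModel, G: np.ndarray) -> np.ndarray:
    """Evaluate the noiseless genetic component on standardized causal columns.

    ``G`` is the n x n_causal matrix of standardized dosages at
    ``model.causal_indices`` (in that order).
    """
    if model.family == "BD":
        g = G
        y = g @ model.alpha + (g**2) @ model.beta
        if model.s > 1:
            y = y + (g[:, :-1] * g[:, 1:]) @ model.gamma
        return y
    if model.family == "PS":
        s, sp = model.s, model.s_prime
        glin, gquad = G[:, :s], G[:, s:]
        y = glin @ model.alpha_p + (gquad**2) @ model.beta_p
        if sp:
            y = y + (glin[:, : sp // 2] * gquad[:, : sp // 2]) @ model.gamma_p
        return y
    raise ValueError(f"cannot evaluate family {model.family!r}")


def genetic_values_general(
    z: np.ndarray, Z: sparse.sparray, A: np.ndarray
) -> np.ndarray:
    """Evaluate y_genetic = A.z + diag(A Z A^T) for standardized full design A."""
    return A @ z + ((A @ Z.T) * A).sum(axis=1)


def simulate_phenotypes(
    model: TrueModel,
    gm: GenotypeMatrix,
    seed: int | np.random.Generator,
) -> PhenotypeSet:
    """Simulate phenotypes under ``model`` on genotype matrix ``gm``.

    Causal columns are standardized (over the full cohort) before the model
    is applied.  Environmental noise is drawn i.i.d. Gaussian; the genetic
    component and the noise are then rescaled so the realized in-sample
    variances are exactly var(eps) = noise_var and var(genetic) =
    1 - noise_var.
    """
    if model.n_causal and model.causal_indices.max() >= gm.p:
        raise IndexError("model causal indices out of range for this genotype matrix")
    rng = np.random.default_rng(seed)
    G = standardize_lenient(gm.dosages[:, model.causal_indices])
    g_raw = genetic_values(model, G)
    v_g = g_raw.var()
    if v_g <= 0:
        raise ValueError("degenerate model: genetic component has zero variance")
    g_scaled = g_raw * np.sqrt((1.0 - model.noise_var) / v_g)

    eps = rng.standard_normal(gm.n)
    eps = eps - eps.mean()
    # Remove the sample correlation with the (centered) genetic component so
    # the realized shares add to exactly 1 in-sample.
    gc = g_scaled - g_scaled.mean()
    eps -= (eps @ gc) / (gc @ gc) * gc
    eps *= np.sqrt(model.noise_var) / eps.std()

    y = g_scaled + eps

    # Linear/nonlinear split of the genetic term (model-term accounting: the
    # alpha part is "linear"; squares and cross terms are "nonlinear").
    if model.family == "BD":
        lin_raw = G @ model.alpha
    else:
        lin_raw = G[:, : model.s] @ model.alpha_p
    lin_scaled = lin_raw * np.sqrt((1.0 - model.noise_var) / v_g)

    report = {
        "total": float(y.var()),
        "noise": float(eps.var()),
        "genetic": float(g_scaled.var()),
        "linear": float(lin_scaled.var()),
        "nonlinear": float((g_scaled - lin_scaled).var()),
        "heritability": float(1.0 - eps.var() / y.var()),
    }
    return PhenotypeSet(
        y=y, epsilon=eps, genetic_component=g_scaled, variance_report=report
    )
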