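import numpy as np
import pytest

from episense import (
    GridSpec,
    TrueModel,
    asymptotic_fit,
    classify_false_positives,
    generate_snp_matrix,
    sample_bd_model,
    sample_mafs,
    sample_ps_model,
    scan,
    simulate_phenotypes,
    support_pvalues,
)
from episense.genotypes import standardize_lenient
from episense.step1 import univariate_pvalues


@pytest.fixture(scope="module")
def ps_instance():
    """Scaled-down PS instance (p = 2000) with enough individuals for a scan."""
    p = 2000
    maf = sample_mafs(p, 40)
    gm = generate_snp_matrix(p, p, maf, 41)
    model = sample_ps_model(3, 2, p, 42)
    ph = simulate_phenotypes(model, gm, 43)
    return gm, model, ph


class TestSupportPvalues:
    def test_strong_causal_locus_tiny_pvalue(self, small_gm, bd_small):
        model, ph = bd_small
        pv = support_pvalues(small_gm, ph.y, model.causal_indices)
        # alpha ~ 1.5 effects at n = 600 are overwhelming evidence
        assert np.median(pv) < 1e-10

    def test_null_locus_pvalues_uniform(self):
        """Marginal p-values of a no-effect locus are Uniform(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(300):
            A = rng.normal(size=(50, 1))
            A = standardize_lenient(A)
            y = rng.normal(size=50)
            pvals.append(univariate_pvalues(A, y)[0])
        assert stats.kstest(pvals, "uniform").pvalue > 1e-3

    def test_empty_support(self, small_gm, bd_small):
        _, ph = bd_small
        assert support_pvalues(small_gm, ph.y, np.array([], dtype=int)).size == 0

    def test_constant_response_rejected(self, small_gm):
        with pytest.raises(ValueError, match="constant"):
            support_pvalues(small_gm, np.ones(small_gm.n), np.array([0]))

    def test_joint_refit_method(self, small_gm, bd_small):
        model, ph = bd_small
        pv = support_pvalues(small_gm, ph.y, model.causal_indices, method="refit")
        assert pv.shape == (model.s,)
        assert np.median(pv) < 1e-10  # strong effects survive the joint test

    def test_joint_refit_needs_enough_rows(self, small_gm, bd_small):
        model, ph = bd_small
        gm_tiny = small_gm.dosages[: model.s + 1]
        from episense.step1 import joint_refit_pvalues
        from episense.genotypes import standardize_lenient

        with pytest.raises(ValueError, match="joint refit"):
            joint_refit_pvalues(
                standardize_lenient(gm_tiny[:, model.causal_indices]),
                ph.y[: model.s + 1],
            )


class TestScan:
    def test_phase_transition_and_termination(self, ps_instance):
        gm, model, ph = ps_instance
        trace = scan(gm, ph.y, lam_var=0.55, seed=1)
        assert np.all(np.diff(trace.n_grid) > 0)
        assert np.all((trace.median_p >= 0) & (trace.median_p <= 1))
        assert trace.terminated and trace.n_star in trace.n_grid
        assert trace.support_at_n_star.size > 0
        # the collapse spans many orders of magnitude
        assert trace.median_p.min() <= 1e-6 * trace.median_p[0]

    def test_deterministic(self, ps_instance):
        gm, _, ph = ps_instance
        a = scan(gm, ph.y, 0.55, seed=5)
        b = scan(gm, ph.y, 0.55, seed=5)
        assert a.n_star == b.n_star
        np.testing.assert_array_equal(a.median_p, b.median_p)
        np.testing.assert_array_equal(a.support_at_n_star, b.support_at_n_star)

    def test_pure_noise_never_terminates(self):
        p = 500
        maf = sample_mafs(p, 50)
        gm = generate_snp_matrix(p, p, maf, 51)
        y = np.random.default_rng(52).normal(size=p)
        trace = scan(gm, y, lam_var=1.0, seed=0)
        assert not trace.terminated
        assert trace.n_star is None

    def test_grid_spec(self):
        g = GridSpec(start=50, factor=1.25, max_n=100)
        assert g.sizes(1000) == [50, 63, 79, 99]
        assert GridSpec(start=200).sizes(100) == []


class TestAsymptoticFit:
    def test_purely_linear_model_has_no_nonlinear_variance(self):
        p = 500
        maf = sample_mafs(p, 60)
        gm = generate_snp_matrix(p, p, maf, 61)
        model = sample_bd_model(4, p, 62)
        model.beta = np.zeros_like(model.beta)
        model.gamma = np.zeros_like(model.gamma)
        ph = simulate_phenotypes(model, gm, 63)
        fit = asymptotic_fit(gm, ph.y, epsilon=ph.epsilon, model=model)
        assert fit.sigma2_NL < 0.02
        assert fit.model_zero_fraction == 0.0

    def test_constructed_slope_zero_locus_counts_as_model_zero(self):
        # PS linear-block locus with alpha' = 0 but a cross interaction:
        # marginally invisible to any linear fit, yet truly causal.
        p = 800
        maf = sample_mafs(p, 70)
        gm = generate_snp_matrix(p, p, maf, 71)
        model = sample_ps_model(2, 2, p, 72)
        model.alpha_p = np.array([0.0, 1.0])
        ph = simulate_phenotypes(model, gm, 73)
        fit = asymptotic_fit(gm, ph.y, epsilon=ph.epsilon, model=model)
        eff = model.effective_causal_indices
        hidden = model.causal_indices[0]
        k = np.nonzero(eff == hidden)[0][0]
        assert fit.causal_pvalues[k] > 0.01  # the hidden locus
        assert fit.model_zero_fraction >= 1 / eff.size

    def test_sigma2_nl_matches_projection_oracle(self):
        """Eq-style check: residual variance after the penalized linear fit
        matches an explicit least-squares projection of the genetic component
        onto the causal columns (small s, generous n)."""
        p = 600
        maf = sample_mafs(p, 80)
        gm = generate_snp_matrix(p, p, maf, 81)
        model = sample_bd_model(3, p, 82)
        ph = simulate_phenotypes(model, gm, 83)
        fit = asymptotic_fit(gm, ph.y, epsilon=ph.epsilon, model=model)
        A = standardize_lenient(gm.dosages[:, model.causal_indices])
        g = ph.genetic_component - ph.genetic_component.mean()
        coef, *_ = np.linalg.lstsq(A, g, rcond=None)
        oracle = float((g - A @ coef).var())
        assert fit.sigma2_NL == pytest.approx(oracle, abs=0.02)


class TestClassifyFalsePositives:
    def test_exact_recovery(self):
        model = sample_bd_model(5, 100, 90)
        out = classify_false_positives(model.causal_indices, model)
        assert out == {"TP": 5, "FP": 0, "bin": "0"}

    def test_one_extra(self):
        model = sample_bd_model(5, 100, 91)
        extra = np.setdiff1d(np.arange(100), model.causal_indices)[0]
        support = np.append(model.causal_indices, extra)
        out = classify_false_positives(support, model)
        assert out["FP"] == 1 and out["TP"] == 5 and out["bin"] == "1"

    def test_binning(self):
        model = sample_bd_model(2, 100, 92)
        others = np.setdiff1d(np.arange(100), model.causal_indices)
        for fp, label in [(2, "2"), (3, "3"), (4, "4-6"), (6, "4-6")]:
            support = np.concatenate([model.causal_indices, others[:fp]])
            assert classify_false_positives(support, model)["bin"] == label
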