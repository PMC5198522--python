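import numpy as np
import pytest
from scipy.stats import nbinom, poisson

from tediff import (
    DispersionMode,
    ModelKind,
    alternating_fit,
    build_design,
    dispersion_mle,
    fit_coefficients,
    nb_log_likelihood,
)
from tediff.count_io import Condition, Protocol, ValidationError
from tediff.glm_core import KAPPA_MIN, bias_corrected_dispersion

from conftest import grid_refine_loglik, make_design


def scipy_nb_loglik(y, mu, kappa):
    """Independent oracle via scipy's NB pmf parameterization."""
    y, mu, kappa = map(np.atleast_1d, (y, mu, kappa))
    kappa = np.broadcast_to(kappa, y.shape)
    out = 0.0
    for yi, mi, ki in zip(y, mu, kappa):
        if ki == 0:
            out += poisson.logpmf(yi, mi)
        else:
            r = 1.0 / ki
            out += nbinom.logpmf(yi, r, r / (r + mi))
    return out


class TestNBLogLikelihood:
    def test_zero_count_closed_form(self):
        # pmf at zero is (1 + kappa*mu)^(-1/kappa) = 1/2 here
        assert nb_log_likelihood([0], [1.0], [1.0]) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_matches_scipy_on_random_triples(self, rng):
        for _ in range(50):
            n = rng.integers(1, 10)
            y = rng.poisson(20, n).astype(float)
            mu = rng.uniform(0.5, 80, n)
            kappa = rng.uniform(1e-4, 5, n)
            assert nb_log_likelihood(y, mu, kappa) == pytest.approx(
                scipy_nb_loglik(y, mu, kappa), abs=1e-8
            )

    def test_poisson_limit(self, rng):
        y = rng.poisson(10, 6).astype(float)
        mu = rng.uniform(1, 30, 6)
        from math import lgamma

        pois = (y * np.log(mu) - mu - np.array([lgamma(v + 1.0) for v in y])).sum()
        assert nb_log_likelihood(y, mu, 1e-10) == pytest.approx(pois, abs=1e-6)
        assert nb_log_likelihood(y, mu, 0.0) == pytest.approx(pois, abs=1e-8)

    def test_negative_dispersion_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            nb_log_likelihood([1], [1.0], [-0.1])

    def test_iid_maximizer_is_sample_mean(self, rng):
        # the score equation sum (y - mu) / (mu (1 + kappa mu)) = 0 is
        # solved by the sample mean; confirm by 1-D grid search
        y = rng.poisson(25, 40).astype(float)
        kappa = 0.3
        grid = np.linspace(max(y.mean() - 10, 0.5), y.mean() + 10, 20001)
        lls = [nb_log_likelihood(y, np.full_like(y, m), kappa) for m in grid]
        assert grid[int(np.argmax(lls))] == pytest.approx(y.mean(), abs=2e-3)


class TestBuildDesign:
    def test_alt_is_saturated_rank_4(self):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        assert spec.X.shape == (8, 4)
        assert np.linalg.matrix_rank(spec.X) == 4

    def test_null_nested_in_alt(self):
        design = make_design(2)
        alt = build_design(design, ModelKind.ALT)
        null = build_design(design, ModelKind.NULL)
        assert null.X.shape == (8, 3)
        np.testing.assert_array_equal(null.X, alt.X[:, :3])

    def test_interaction_column_is_rf_and_treatment(self):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        rf = design.protocol_mask(Protocol.RIBO)
        trt = design.condition_mask(Condition.TREATMENT)
        np.testing.assert_array_equal(spec.X[:, 3], (rf & trt).astype(float))

    def test_single_protocol_design_impossible(self):
        # the interaction is undefined without both protocols; the
        # design type itself refuses to be constructed
        from tediff import ExperimentDesign

        with pytest.raises(ValidationError):
            ExperimentDesign(
                ("a", "b", "c", "d"),
                (Protocol.RNASEQ,) * 4,
                (Condition.CONTROL,) * 2 + (Condition.TREATMENT,) * 2,
            )


class TestFitCoefficients:
    def test_saturated_fit_reproduces_group_means(self, rng):
        design = make_design(3)
        spec = build_design(design, ModelKind.ALT)
        offsets = np.zeros(12)
        for _ in range(5):
            y = rng.poisson(rng.uniform(5, 200), 12).astype(float)
            y[0] += 1  # ensure positive
            fit = fit_coefficients(y, spec, offsets, kappa=0.1)
            for p in (Protocol.RNASEQ, Protocol.RIBO):
                for c in (Condition.CONTROL, Condition.TREATMENT):
                    m = design.protocol_mask(p) & design.condition_mask(c)
                    if y[m].mean() > 0:
                        assert fit.mu_hat[m].mean() == pytest.approx(
                            y[m].mean(), rel=1e-6, abs=1e-6
                        )

    def test_constant_counts_give_zero_effects(self):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        y = np.full(8, 17.0)
        fit = fit_coefficients(y, spec, np.zeros(8), kappa=0.2)
        assert fit.beta[0] == pytest.approx(np.log(17.0), abs=1e-6)
        np.testing.assert_allclose(fit.beta[1:], 0.0, atol=1e-6)

    def test_loglik_matches_grid_refinement(self, rng):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        offsets = np.log(rng.uniform(0.7, 1.4, 8))
        for _ in range(10):
            y = rng.negative_binomial(5, 0.1, 8).astype(float) + 1
            kappa = rng.uniform(0.05, 0.5)
            fit = fit_coefficients(y, spec, offsets, kappa)
            target = np.log(y * np.exp(-offsets) + 0.5)
            init, *_ = np.linalg.lstsq(spec.X, target, rcond=None)
            oracle_ll, _ = grid_refine_loglik(y, spec.X, offsets, kappa, init)
            assert fit.loglik == pytest.approx(oracle_ll, abs=1e-4)

    def test_all_zero_group_is_handled(self):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        y = np.array([10, 12, 11, 9, 8, 9, 0, 0], float)  # RF-treatment empty
        fit = fit_coefficients(y, spec, np.zeros(8), kappa=0.1)
        assert np.isfinite(fit.loglik)
        assert np.all(fit.mu_hat >= 1e-8 * (1 - 1e-9))

    def test_all_zero_gene_rejected(self):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        with pytest.raises(ValidationError, match="no positive count"):
            fit_coefficients(np.zeros(8), spec, np.zeros(8), kappa=0.1)


class TestDispersionMLE:
    def test_matches_grid_search(self, rng):
        y = rng.negative_binomial(10, 0.25, 30).astype(float)
        mu = np.full(30, y.mean())
        est = dispersion_mle(y, mu)
        grid = np.logspace(-6, 1, 10_000)
        lls = [nb_log_likelihood(y, mu, k) for k in grid]
        best = grid[int(np.argmax(lls))]
        spacing = np.log(grid[1]) - np.log(grid[0])
        assert abs(np.log(est.value) - np.log(best)) <= spacing

    def test_underdispersed_hits_lower_bound(self):
        y = np.full(20, 8.0)
        est = dispersion_mle(y, np.full(20, 8.0))
        assert est.value == pytest.approx(KAPPA_MIN)
        assert est.at_boundary

    def test_consistency_at_large_n(self):
        rng = np.random.default_rng(77)
        true_kappa = 0.1
        r = 1 / true_kappa
        mu = 50.0
        y = rng.negative_binomial(r, r / (r + mu), 200).astype(float)
        est = dispersion_mle(y, np.full(200, y.mean()))
        assert 0.05 <= est.value <= 0.2


class TestBiasCorrection:
    def test_boundary_estimate_unchanged(self):
        assert bias_corrected_dispersion(KAPPA_MIN, np.full(6, 10.0), 2) == KAPPA_MIN

    def test_correction_inflates_interior_estimates(self):
        k = bias_corrected_dispersion(0.1, np.full(6, 50.0), 2)
        assert k > 0.1
        # variance-scale arithmetic: 1.5*0.1 + 0.5/50
        assert k == pytest.approx(0.15 + 0.5 / 50.0, rel=1e-12)


class TestAlternatingFit:
    def test_single_round_reproduces_fit_coefficients(self, rng):
        design = make_design(2)
        spec = build_design(design, ModelKind.ALT)
        offsets = np.zeros(8)
        y = rng.poisson(40, 8).astype(float)
        kappa0 = {"rna": 0.1, "rf": 0.3}
        fit_alt, _ = alternating_fit(
            y, spec, offsets, mode=DispersionMode.SEPARATE, init_kappa=kappa0, max_outer=1
        )
        kv = np.where(design.protocol_mask(Protocol.RIBO), 0.3, 0.1)
        fit_direct = fit_coefficients(y, spec, offsets, kv)
        np.testing.assert_allclose(fit_alt.beta, fit_direct.beta, atol=1e-10)

    def test_nesting_alt_at_least_null(self, rng):
        design = make_design(3)
        alt = build_design(design, ModelKind.ALT)
        null = build_design(design, ModelKind.NULL)
        offsets = np.zeros(12)
        for _ in range(20):
            y = rng.negative_binomial(4, 0.08, 12).astype(float) + 1
            kappa = rng.uniform(0.05, 0.5)
            fa = fit_coefficients(y, alt, offsets, kappa)
            fn = fit_coefficients(y, null, offsets, kappa)
            assert fa.loglik >= fn.loglik - 1e-9

    def test_separate_mode_recovers_both_dispersions(self):
        # genes with lightly dispersed RNA-Seq and heavily dispersed RF
        # counts: the separate estimates bracket the truths, the joint
        # estimate sits between them
        rng = np.random.default_rng(11)
        design = make_design(5)
        spec = build_design(design, ModelKind.ALT)
        offsets = np.zeros(20)
        kap_rna, kap_rf = 0.01, 0.5
        est_rna, est_rf, est_joint = [], [], []
        for _ in range(500):
            mu = rng.lognormal(np.log(150), 0.8)
            r1, r2 = 1 / kap_rna, 1 / kap_rf
            y = np.concatenate(
                [
                    rng.negative_binomial(r1, r1 / (r1 + mu), 10),
                    rng.negative_binomial(r2, r2 / (r2 + mu), 10),
                ]
            ).astype(float)
            if not y.any():
                continue
            _, sep = alternating_fit(y, spec, offsets, mode=DispersionMode.SEPARATE)
            _, joint = alternating_fit(y, spec, offsets, mode=DispersionMode.JOINT)
            est_rna.append(sep["rna"].value)
            est_rf.append(sep["rf"].value)
            est_joint.append(joint["all"].value)
        med_rna, med_rf = np.median(est_rna), np.median(est_rf)
        assert kap_rna / 2 <= med_rna <= kap_rna * 2
        assert kap_rf / 2 <= med_rf <= kap_rf * 2
        assert med_rna < np.median(est_joint) < med_rf

    def test_joint_close_to_separate_when_dispersions_equal(self):
        rng = np.random.default_rng(13)
        design = make_design(5)
        spec = build_design(design, ModelKind.ALT)
        offsets = np.zeros(20)
        kappa = 0.15
        r = 1 / kappa
        sep_all, joint_all = [], []
        for _ in range(300):
            mu = rng.lognormal(np.log(100), 0.8)
            y = rng.negative_binomial(r, r / (r + mu), 20).astype(float)
            if not y.any():
                continue
            _, sep = alternating_fit(y, spec, offsets, mode=DispersionMode.SEPARATE)
            _, joint = alternating_fit(y, spec, offsets, mode=DispersionMode.JOINT)
            sep_all.append(0.5 * (sep["rna"].value + sep["rf"].value))
            joint_all.append(joint["all"].value)
        m_sep, m_joint = np.median(sep_all), np.median(joint_all)
        assert abs(m_sep - m_joint) / m_joint < 0.25
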