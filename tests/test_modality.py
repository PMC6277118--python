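"""Bayesian modality fits: parameter recovery, BIC arithmetic and model
choice, label ordering, prior-support constraints, and the eQTM call rule."""

import numpy as np
import pytest

from epiqtl.modality import (
    MCMCSettings,
    ModalityFit,
    classify_eqtm,
    classify_modality,
    compute_bic,
    fit_expression_bimodal,
    fit_expression_unimodal,
    fit_methylation_bimodal,
    fit_methylation_unimodal,
)


class TestExpressionUnimodal:
    def test_point_mass_limit(self, fast_mcmc):
        rng = np.random.default_rng(1)
        x = 3.0 + rng.normal(0, 1e-3, 200)
        fit = fit_expression_unimodal(x, fast_mcmc, seed=1)
        assert fit.params["mu"] == pytest.approx(3.0, abs=0.01)

    def test_parameter_recovery(self, fast_mcmc):
        rng = np.random.default_rng(2)
        x = rng.normal(5, 1, 500)
        fit = fit_expression_unimodal(x, fast_mcmc, seed=2)
        assert fit.params["mu"] == pytest.approx(5.0, abs=0.15)
        assert fit.params["sigma"] == pytest.approx(1.0, abs=0.15)
        assert fit.converged

    def test_minimum_sample_size(self, fast_mcmc):
        with pytest.raises(ValueError):
            fit_expression_unimodal(np.arange(5.0), fast_mcmc, seed=1)

    def test_negative_data_shift_round_trip(self, fast_mcmc):
        """Data below zero are shifted for the nonnegative prior and the
        reported mean is shifted back."""
        rng = np.random.default_rng(3)
        x = rng.normal(-4, 1, 300)
        fit = fit_expression_unimodal(x, fast_mcmc, seed=3)
        assert fit.shift > 0
        assert fit.params["mu"] == pytest.approx(-4.0, abs=0.25)


class TestExpressionBimodal:
    def test_mixture_recovery(self, fast_mcmc):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.normal(-2, 0.5, 100), rng.normal(2, 0.5, 100)])
        fit = fit_expression_bimodal(x, fast_mcmc, seed=4)
        assert fit.params["mu1"] == pytest.approx(-2.0, abs=0.2)
        assert fit.params["mu2"] == pytest.approx(2.0, abs=0.2)
        assert fit.params["omega1"] == pytest.approx(0.5, abs=0.1)

    def test_label_order_and_mass_box(self, fast_mcmc):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(1, 0.3, 60), rng.normal(4, 0.3, 140)])
        fit = fit_expression_bimodal(x, fast_mcmc, seed=5)
        assert fit.params["mu1"] < fit.params["mu2"]
        assert 0.1 <= fit.params["omega1"] <= 0.9
        assert fit.params["omega1"] + fit.params["omega2"] == pytest.approx(1.0)

    def test_degenerate_constant_input(self, fast_mcmc):
        with pytest.raises(ValueError, match="identical"):
            fit_expression_bimodal(np.full(50, 2.0), fast_mcmc, seed=1)

    def test_unimodal_data_prefers_unimodal_model(self, fast_mcmc):
        rng = np.random.default_rng(6)
        wins = 0
        for i in range(20):
            x = rng.normal(0, 1, 100)
            uni = fit_expression_unimodal(x, fast_mcmc, seed=10 + i)
            bi = fit_expression_bimodal(x, fast_mcmc, seed=110 + i)
            wins += uni.bic < bi.bic
        assert wins >= 18


class TestMethylationUnimodal:
    def test_parameter_recovery(self, fast_mcmc):
        rng = np.random.default_rng(6)
        x = rng.beta(0.3 * 50, 0.7 * 50, 500)
        fit = fit_methylation_unimodal(x, fast_mcmc, seed=6)
        assert fit.params["mu"] == pytest.approx(0.3, abs=0.03)
        assert fit.params["kappa"] == pytest.approx(50, abs=15)
        assert fit.params["alpha"] == pytest.approx(fit.params["mu"] * fit.params["kappa"])

    def test_symmetric_data(self, fast_mcmc):
        rng = np.random.default_rng(7)
        x = rng.beta(25, 25, 400)
        fit = fit_methylation_unimodal(x, fast_mcmc, seed=7)
        assert fit.params["mu"] == pytest.approx(0.5, abs=0.03)

    def test_domain_check(self, fast_mcmc):
        x = np.concatenate([np.full(30, 0.5), [1.2]])
        with pytest.raises(ValueError):
            fit_methylation_unimodal(x, fast_mcmc, seed=1)

    def test_boundary_values_clamped_not_rejected(self, fast_mcmc):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.beta(2, 10, 50), [0.0, 1.0]])
        fit = fit_methylation_unimodal(x, fast_mcmc, seed=8)
        assert 0 < fit.params["mu"] < 1


class TestMethylationBimodal:
    def test_mixture_recovery(self, fast_mcmc):
        rng = np.random.default_rng(8)
        z = rng.random(200) < 0.5
        x = np.where(z, rng.beta(0.15 * 50, 0.85 * 50, 200),
                     rng.beta(0.85 * 50, 0.15 * 50, 200))
        fit = fit_methylation_bimodal(x, fast_mcmc, seed=8)
        assert fit.params["mu1"] == pytest.approx(0.15, abs=0.05)
        assert fit.params["mu2"] == pytest.approx(0.85, abs=0.05)
        assert 0.2 <= fit.params["omega1"] <= 0.8
        assert fit.params["kappa"] > 0

    def test_inverted_mass_bounds_rejected(self, fast_mcmc):
        with pytest.raises(ValueError, match="mass bounds"):
            fit_methylation_bimodal(
                np.linspace(0.1, 0.9, 50), fast_mcmc, seed=1,
                mass_bounds=(0.8, 0.2),
            )

    def test_unimodal_beta_prefers_unimodal_model(self, fast_mcmc):
        rng = np.random.default_rng(9)
        wins = 0
        for i in range(20):
            x = rng.beta(0.4 * 30, 0.6 * 30, 100)
            uni = fit_methylation_unimodal(x, fast_mcmc, seed=20 + i)
            bi = fit_methylation_bimodal(x, fast_mcmc, seed=120 + i)
            wins += uni.bic < bi.bic
        assert wins >= 18


class TestBic:
    def test_direct_arithmetic(self):
        fit = ModalityFit(
            data_kind="expression", model="unimodal", params={},
            posterior_sd={}, log_likelihood=-150.0, bic=0.0, n_params=2,
            n=100, rhat=1.0, converged=True,
        )
        assert compute_bic(fit, 100) == pytest.approx(2 * np.log(100) + 300, abs=1e-10)

    def test_penalty_monotone_in_params(self):
        base = dict(data_kind="expression", model="m", params={},
                    posterior_sd={}, log_likelihood=-10.0, bic=0.0,
                    n=50, rhat=1.0, converged=True)
        f2 = ModalityFit(n_params=2, **base)
        f4 = ModalityFit(n_params=4, **base)
        assert compute_bic(f4, 50) > compute_bic(f2, 50)

    def test_penalty_vanishes_at_n_one(self):
        fit = ModalityFit(
            data_kind="expression", model="unimodal", params={},
            posterior_sd={}, log_likelihood=-7.5, bic=0.0, n_params=2,
            n=1, rhat=1.0, converged=True,
        )
        assert compute_bic(fit, 1) == pytest.approx(15.0)


class TestClassification:
    def test_bimodal_methylation_classified(self, fast_mcmc):
        rng = np.random.default_rng(10)
        z = rng.random(100) < 0.5
        x = np.where(z, rng.beta(0.15 * 50, 0.85 * 50, 100),
                     rng.beta(0.85 * 50, 0.15 * 50, 100))
        label, uni, bi = classify_modality(x, "methylation", fast_mcmc, seed=10)
        assert label == "bimodal"
        assert bi.bic < uni.bic

    def test_normal_expression_classified_unimodal(self, fast_mcmc):
        rng = np.random.default_rng(11)
        label, _, _ = classify_modality(rng.normal(0, 1, 100), "expression",
                                        fast_mcmc, seed=11)
        assert label == "unimodal"

    def test_reproducible_under_seed(self, fast_mcmc):
        rng = np.random.default_rng(12)
        x = rng.beta(5, 5, 80)
        a = fit_methylation_unimodal(x, fast_mcmc, seed=3)
        b = fit_methylation_unimodal(x, fast_mcmc, seed=3)
        assert a.params == b.params
        assert a.bic == b.bic

    @pytest.mark.parametrize(
        "expr_bimodal,meth_bimodal,expected",
        [(False, False, "linear"), (True, True, "bimodal"),
         (False, True, "discordant"), (True, False, "discordant")],
    )
    def test_eqtm_call_rule(self, fast_mcmc, expr_bimodal, meth_bimodal, expected):
        rng = np.random.default_rng(13)
        n = 100
        if expr_bimodal:
            expr = np.concatenate([rng.normal(2, 0.4, n // 2), rng.normal(6, 0.4, n // 2)])
        else:
            expr = rng.normal(4, 1, n)
        if meth_bimodal:
            z = rng.random(n) < 0.5
            meth = np.where(z, rng.beta(0.15 * 50, 0.85 * 50, n),
                            rng.beta(0.85 * 50, 0.15 * 50, n))
        else:
            meth = rng.beta(0.4 * 40, 0.6 * 40, n)
        cls = classify_eqtm(expr, meth, fast_mcmc, seed=14)
        assert cls.call == expected

    def test_correlation_sign(self, fast_mcmc):
        rng = np.random.default_rng(15)
        meth = rng.beta(3, 3, 120)
        expr = 8 - 4 * meth + rng.normal(0, 0.3, 120)
        cls = classify_eqtm(expr, meth, fast_mcmc, seed=15)
        assert cls.correlation_sign == "-"
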