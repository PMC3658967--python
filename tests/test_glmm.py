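"""Random-intercept logistic model: quadrature, boundaries, shrinkage,
recovery, and the mixed recalibration models."""

import json
import shutil
import subprocess

import numpy as np
import pytest
from scipy.special import expit

from clusterrisk import (
    RandomInterceptLogistic,
    fit_mixed_calibration_large,
    fit_mixed_calibration_slope,
    fit_random_intercept_logistic,
    fit_standard_logistic,
    marginal_loglik,
    variance_from_icc,
)


def simulate_clustered(J, per, sigma2, seed, alpha=-1.0, beta=(0.8,)):
    rng = np.random.default_rng(seed)
    u = rng.normal(0, np.sqrt(sigma2), J)
    cid = np.repeat(np.arange(J), per)
    X = rng.normal(size=(J * per, len(beta)))
    lp = alpha + X @ np.asarray(beta) + u[cid]
    y = (rng.uniform(size=lp.size) < expit(lp)).astype(int)
    return X, y, cid, u


class TestRandomInterceptFit:
    def test_unclustered_data_hits_zero_variance_boundary(self, unclustered_sample):
        s = unclustered_sample
        ri = fit_random_intercept_logistic(s.X, s.y, s.center_id)
        std = fit_standard_logistic(s.X, s.y)
        assert ri.sigma2_u0 <= 1e-4
        assert ri.alpha == pytest.approx(std.alpha, abs=1e-3)
        assert ri.beta == pytest.approx(std.beta, abs=1e-3)

    def test_quadrature_refinement_stability(self):
        # 15 adaptive nodes vs 101 non-adaptive nodes at the fitted optimum
        X, y, cid, _ = simulate_clustered(30, 40, 0.8, seed=10)
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        params = np.r_[fit.alpha, fit.beta]
        sigma = np.sqrt(fit.sigma2_u0)
        ll15 = marginal_loglik(X, y, cid, params, sigma, n_quad=15)
        ll101 = marginal_loglik(X, y, cid, params, sigma, n_quad=101, adaptive=False)
        assert ll15 == pytest.approx(ll101, rel=1e-5)

    def test_more_nodes_do_not_move_the_estimate(self):
        X, y, cid, _ = simulate_clustered(25, 30, 1.0, seed=11)
        s15 = fit_random_intercept_logistic(X, y, cid, compute_se=False).sigma2_u0
        s41 = fit_random_intercept_logistic(X, y, cid, n_quad=41,
                                            compute_se=False).sigma2_u0
        assert s15 == pytest.approx(s41, abs=1e-3)

    def test_marginal_loglik_degenerates_to_standard_at_zero_variance(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(200, 2))
        y = (rng.uniform(size=200) < 0.4).astype(int)
        cid = np.repeat(np.arange(10), 20)
        params = np.array([-0.4, 0.5, -0.2])
        from clusterrisk.glm import bernoulli_loglik

        expected = bernoulli_loglik(np.column_stack([np.ones(200), X]) @ params, y)
        assert marginal_loglik(X, y, cid, params, 0.0) == expected

    def test_parameter_recovery_at_icc_15(self):
        # average over replications: sigma2 and the unit coefficient recovered
        truth_s2 = variance_from_icc(0.15)
        s2s, betas = [], []
        for seed in range(5):
            X, y, cid, _ = simulate_clustered(
                50, 100, truth_s2, seed=100 + seed, alpha=-1.0, beta=(1.0,)
            )
            f = fit_random_intercept_logistic(X, y, cid, compute_se=False)
            s2s.append(f.sigma2_u0)
            betas.append(f.beta[0])
        se_mean_s2 = np.std(s2s, ddof=1) / np.sqrt(len(s2s))
        se_mean_b = np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert abs(np.mean(s2s) - truth_s2) < 3 * max(se_mean_s2, 0.02)
        assert abs(np.mean(betas) - 1.0) < 3 * max(se_mean_b, 0.01)

    def test_empirical_bayes_shrinks_toward_zero(self):
        X, y, cid, _ = simulate_clustered(12, 60, 0.6, seed=13, alpha=-0.3)
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        fe = fit.alpha + X @ fit.beta
        for j in range(12):
            mask = cid == j
            yj, fej = y[mask], fe[mask]
            if not 0 < yj.sum() < yj.size:
                continue
            d = 0.0  # unpooled per-cluster intercept deviation, Newton
            for _ in range(60):
                p = expit(fej + d)
                g = np.sum(yj - p)
                d += g / max(np.sum(p * (1 - p)), 1e-10)
                if abs(g) < 1e-10:
                    break
            assert abs(fit.u0_hat[j]) <= abs(d) + 1e-6

    def test_empirical_bayes_approaches_truth_with_big_clusters(self):
        X, y, cid, u = simulate_clustered(10, 3000, 0.8, seed=14)
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        # with few clusters the fixed intercept absorbs the mean of the
        # realized u's, so compare centred deviations
        dev_hat = fit.u0_hat - fit.u0_hat.mean()
        dev_true = u - u.mean()
        assert np.corrcoef(dev_hat, dev_true)[0, 1] > 0.99
        assert np.max(np.abs(dev_hat - dev_true)) < 0.1

    def test_posterior_mean_option(self):
        X, y, cid, _ = simulate_clustered(15, 40, 0.6, seed=15)
        mode = RandomInterceptLogistic(compute_se=False).fit(X, y, groups=cid)
        mean = RandomInterceptLogistic(eb_method="mean", compute_se=False).fit(
            X, y, groups=cid
        )
        assert mode.u0_ == pytest.approx(mean.u0_, abs=0.1)
        assert not np.allclose(mode.u0_, mean.u0_)

    def test_single_cluster_pins_variance_to_zero(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(150, 1))
        y = (rng.uniform(size=150) < 0.4).astype(int)
        fit = fit_random_intercept_logistic(X, y, np.zeros(150, int))
        assert fit.sigma2_u0 <= 1e-3

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
    def test_matches_lme4_glmer(self, tmp_path):
        import pandas as pd

        X, y, cid, _ = simulate_clustered(15, 40, 0.5, seed=17)
        df = pd.DataFrame({"x": X[:, 0], "y": y, "cl": cid})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = (
            f"d <- read.csv('{csv}');"
            "suppressMessages(library(lme4));"
            "m <- glmer(y ~ x + (1|cl), data=d, family=binomial, nAGQ=15);"
            "cat(jsonlite::toJSON(list(alpha=fixef(m)[[1]], beta=fixef(m)[[2]],"
            " s2=unname(unlist(VarCorr(m))), ll=as.numeric(logLik(m)))))"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        assert fit.alpha == pytest.approx(ref["alpha"], abs=2e-3)
        assert fit.beta[0] == pytest.approx(ref["beta"], abs=2e-3)
        assert fit.sigma2_u0 == pytest.approx(ref["s2"], abs=5e-3)
        assert fit.loglik == pytest.approx(ref["ll"], abs=1e-3)


class TestMixedCalibrationLarge:
    def test_offset_translation_identity(self):
        X, y, cid, _ = simulate_clustered(20, 50, 0.3, seed=20)
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        lp = fit.model.decision_function(X, groups=cid, conditional=True)
        shifted = fit_mixed_calibration_large(lp - 0.7, y, cid)
        assert shifted.fixed_intercept == pytest.approx(0.7, abs=0.02)

    def test_conditional_lp_on_own_sample_is_calibrated_within_clusters(self):
        X, y, cid, _ = simulate_clustered(20, 60, 0.6, seed=21)
        fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
        lp = fit.model.decision_function(X, groups=cid, conditional=True)
        cal = fit_mixed_calibration_large(lp, y, cid)
        assert cal.fixed_intercept == pytest.approx(0.0, abs=0.05)
        assert cal.re_sd_intercept <= 0.01

    def test_single_cluster_equals_plain_offset_model(self):
        rng = np.random.default_rng(22)
        lp = rng.normal(-0.5, 1.0, 300)
        y = (rng.uniform(size=300) < expit(lp + 0.4)).astype(int)
        mixed = fit_mixed_calibration_large(lp, y, np.zeros(300, int))
        plain = fit_standard_logistic(np.empty((300, 0)), y, offset=lp)
        assert mixed.re_sd_intercept <= 0.01
        assert mixed.fixed_intercept == pytest.approx(plain.alpha, abs=1e-3)


class TestMixedCalibrationSlope:
    def test_self_calibration_single_cluster(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(400, 2))
        y = (rng.uniform(size=400) < expit(-0.5 + X @ [0.8, -0.6])).astype(int)
        lp = fit_standard_logistic(X, y).model.decision_function(X)
        cal = fit_mixed_calibration_slope(lp, y, np.zeros(400, int))
        assert cal.fixed_slope == pytest.approx(1.0, abs=0.02)

    def test_halving_lp_doubles_the_slope(self):
        X, y, cid, _ = simulate_clustered(15, 60, 0.4, seed=24)
        lp = fit_standard_logistic(X, y).model.decision_function(X)
        full = fit_mixed_calibration_slope(lp, y, cid)
        half = fit_mixed_calibration_slope(lp / 2, y, cid)
        assert half.fixed_slope == pytest.approx(2 * full.fixed_slope, rel=5e-3)

    def test_constant_lp_rejected(self):
        with pytest.raises(ValueError):
            fit_mixed_calibration_slope(np.ones(50), np.r_[np.ones(25), np.zeros(25)],
                                        np.zeros(50, int))


def test_conditional_prediction_refuses_unseen_cluster():
    X, y, cid, _ = simulate_clustered(8, 40, 0.5, seed=25)
    fit = fit_random_intercept_logistic(X, y, cid, compute_se=False)
    with pytest.raises(ValueError, match="unseen cluster"):
        fit.model.decision_function(X[:3], groups=np.array([99, 99, 99]),
                                    conditional=True)
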