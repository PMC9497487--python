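import numpy as np
import pytest
from scipy import stats

import pliv
from pliv.inference import (
    _covariance_from_parts,
    hessian_V,
    kde_density,
    outer_product_M,
    summarize,
    vcov,
)
from pliv.likelihood import loglik, score
from pliv.model import ParamSpace, ThresholdCounts


class TestOuterProductM:
    def test_zero_scores(self):
        assert np.all(outer_product_M(np.zeros((7, 3))) == 0.0)

    def test_single_observation_is_rank_one(self):
        s = np.array([[1.0, 2.0, -1.0]])
        M = outer_product_M(s)
        assert np.linalg.matrix_rank(M) == 1
        np.testing.assert_allclose(M, np.outer(s[0], s[0]))

    def test_matches_naive_loop(self):
        rng = np.random.default_rng(2)
        s = rng.standard_normal((40, 5))
        loop = sum(np.outer(row, row) for row in s) / 40
        np.testing.assert_allclose(outer_product_M(s), loop, rtol=1e-12)


class TestKdeDensity:
    def test_standard_normal_density_at_zero(self):
        sample = np.random.default_rng(1).standard_normal(100_000)
        assert kde_density(sample, 0.0) == pytest.approx(1 / np.sqrt(2 * np.pi), abs=0.01)

    def test_uniform_density_at_center(self):
        sample = np.random.default_rng(2).uniform(size=100_000)
        assert kde_density(sample, 0.5) == pytest.approx(1.0, abs=0.05)

    def test_positivity_far_from_data(self):
        sample = np.random.default_rng(3).standard_normal(50)
        assert kde_density(sample, 5.0) > 0.0

    def test_degenerate_sample_raises(self):
        with pytest.raises(ValueError):
            kde_density(np.ones(50), 1.0)
        with pytest.raises(ValueError):
            kde_density(np.arange(5.0), 1.0)


class TestHessianV:
    def test_no_thresholds_equals_numerical_hessian(self, linear_iv_data):
        fit = pliv.fit_liml(linear_iv_data, ThresholdCounts(0, 0))
        space = fit.space
        vec = space.pack(fit.theta_hat)
        V = hessian_V(fit.theta_hat, linear_iv_data, space)
        p = space.size
        H = np.empty((p, p))
        h = 1e-4
        for i in range(p):
            for j in range(i, p):
                ei, ej = np.zeros(p), np.zeros(p)
                ei[i] = h * max(1, abs(vec[i]))
                ej[j] = h * max(1, abs(vec[j]))
                H[i, j] = H[j, i] = (
                    loglik(space.unpack(vec + ei + ej), linear_iv_data)
                    - loglik(space.unpack(vec + ei - ej), linear_iv_data)
                    - loglik(space.unpack(vec - ei + ej), linear_iv_data)
                    + loglik(space.unpack(vec - ei - ej), linear_iv_data)
                ) / (4 * ei[i] * ej[j])
        scale = np.sqrt(np.outer(np.abs(np.diag(H)), np.abs(np.diag(H))))
        np.testing.assert_array_less(np.abs(V - H) / scale, 5e-3)

    def test_threshold_diagonal_matches_smoothed_objective(self):
        """V's kink diagonal agrees with the Hessian of a kernel-smoothed criterion.

        Replacing the hinge by its Gaussian smoothing E[(w + hZ)_+] makes the
        objective twice differentiable; as h -> 0 its numerical Hessian must
        approach the density-corrected entries.
        """
        data, truth = pliv.generate_scenario(
            pliv.ScenarioConfig(scenario_id=1, n=5000, rho=0.5, seed=21)
        )
        fit = pliv.fit_liml(data, truth.counts, common_sigma=True)
        space = fit.space
        vec = space.pack(fit.theta_hat)
        V = hessian_V(fit.theta_hat, data, space)

        def smooth_loglik(v, h):
            alpha, beta = v[space.slice_alpha], v[space.slice_beta]
            c, t = v[space.slice_c], v[space.slice_t]
            rho, s2 = v[space.idx_rho], v[space.idx_rho + 1]
            su = sv = np.sqrt(s2)

            def phi_h(w):
                return w * stats.norm.cdf(w / h) + h * stats.norm.pdf(w / h)

            d1 = np.column_stack([np.ones(data.n)] + [phi_h(data.z - ck) for ck in c] + [data.z])
            d2 = np.column_stack([np.ones(data.n)] + [phi_h(data.x - tj) for tj in t] + [data.x])
            uu = data.y - d2 @ beta
            vv = data.x - d1 @ alpha
            q = (uu / su) ** 2 - 2 * rho * (uu / su) * (vv / sv) + (vv / sv) ** 2
            return np.mean(
                -np.log(2 * np.pi) - np.log(su * sv) - 0.5 * np.log(1 - rho**2)
                - q / (2 * (1 - rho**2))
            )

        h_smooth, d = 0.05, 1e-3
        for idx in (space.slice_c.start, space.slice_t.start):
            e = np.zeros(space.size)
            e[idx] = d
            num = (
                smooth_loglik(vec + e, h_smooth)
                - 2 * smooth_loglik(vec, h_smooth)
                + smooth_loglik(vec - e, h_smooth)
            ) / d**2
            assert num == pytest.approx(V[idx, idx], rel=0.15)


class TestVcov:
    def test_toy_covariance_formulas(self):
        M = np.eye(2)
        V = -np.eye(2)
        n = 50
        for mode in ("model_based", "sandwich"):
            cov = _covariance_from_parts(M, V, n, mode)
            np.testing.assert_allclose(cov, np.eye(2) / n)

    def test_model_based_equals_inverse_M(self, scenario1_fit_data):
        data, truth = scenario1_fit_data
        fit = pliv.fit_liml(data, truth.counts, common_sigma=True)
        vc = vcov(fit, data, mode="model_based")
        np.testing.assert_allclose(vc.cov, np.linalg.inv(vc.M) / data.n, rtol=1e-8)
        np.testing.assert_allclose(vc.cov, vc.cov.T)
        assert np.all(np.diag(vc.cov) >= 0)
        # positive semidefinite
        assert np.min(np.linalg.eigvalsh(vc.cov)) > -1e-12

    def test_sandwich_close_to_model_based_when_correctly_specified(self):
        data, truth = pliv.generate_scenario(
            pliv.ScenarioConfig(scenario_id=1, n=5000, rho=0.5, seed=77)
        )
        fit = pliv.fit_liml(data, truth.counts, common_sigma=True)
        se_m = vcov(fit, data, mode="model_based").se
        se_s = vcov(fit, data, mode="sandwich").se
        np.testing.assert_allclose(se_s, se_m, rtol=0.20)


class TestSummarize:
    def _fake_fit(self, estimate, counts=ThresholdCounts(0, 0)):
        space = ParamSpace(counts)
        theta = space.unpack(np.asarray(estimate, dtype=float))
        return pliv.FitResult(
            theta_hat=theta, space=space, loglik_at_opt=0.0, converged=True,
            n_iter=1, init=theta, loglik_at_init=0.0, first_stage_F=1.0,
            grad_norm=0.0, n_obs=10,
        )

    def _fake_vc(self, se, names):
        se = np.asarray(se, dtype=float)
        return pliv.VarianceEstimate(
            M=np.eye(se.size), V=None, cov=np.diag(se**2), se=se,
            mode="model_based", names=names,
        )

    def test_wald_row_matches_published_style_numbers(self):
        """Estimate 0.87 with SE 0.084 gives z ~ 10.4 and CI ~ (0.705, 1.035)."""
        fit = self._fake_fit([0.0, 0.87, 0.0, 0.0, 0.0, 1.0, 1.0])
        vc = self._fake_vc([1.0, 0.084, 1.0, 1.0, 1.0, 1.0, 1.0], fit.space.names)
        row = summarize(fit, vc).iloc[1]
        assert row["z"] == pytest.approx(10.357, abs=0.01)
        assert row["ci_low"] == pytest.approx(0.705, abs=0.002)
        assert row["ci_high"] == pytest.approx(1.035, abs=0.002)

    def test_zero_estimate(self):
        fit = self._fake_fit([0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        vc = self._fake_vc(np.ones(7), fit.space.names)
        row = summarize(fit, vc).iloc[0]
        assert row["z"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_borderline_p_value(self):
        fit = self._fake_fit([1.959964, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
        vc = self._fake_vc(np.ones(7), fit.space.names)
        assert summarize(fit, vc).iloc[0]["p"] == pytest.approx(0.05, abs=1e-6)

    def test_threshold_p_values_suppressed(self, scenario1_fit_data):
        data, truth = scenario1_fit_data
        fit = pliv.fit_liml(data, truth.counts, common_sigma=True)
        table = summarize(fit, vcov(fit, data))
        assert np.isnan(table.set_index("parameter").loc["c1", "p"])
        assert np.isnan(table.set_index("parameter").loc["t1", "p"])
        assert table.set_index("parameter").loc["beta1", "p"] < 0.05
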