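"""Estimator unit tests against hand-computable and independent oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import ndtr
from scipy.stats import multivariate_normal

from mistreat._bvn import bvn_cdf
from mistreat.estimators import (
    RegressionInput,
    biprobit_ate,
    bootstrap_se,
    eta_control_effect,
    iv_effect,
    lewbel_iv,
    ols_effect,
    slope_iv,
    slope_ols,
)


class TestBvnCdf:
    def test_matches_scipy_on_grid(self):
        hs = np.linspace(-2.5, 2.5, 7)
        rhos = [-0.95, -0.5, 0.0, 0.3, 0.8, 0.999]
        for r in rhos:
            mvn = multivariate_normal(cov=[[1, r], [r, 1]])
            for h in hs:
                for k in hs:
                    assert bvn_cdf(h, k, r) == pytest.approx(
                        float(mvn.cdf([h, k])), abs=1e-8
                    )

    def test_zero_arguments(self):
        for r in (-0.6, 0.0, 0.7):
            expected = 0.25 + np.arcsin(r) / (2 * np.pi)
            assert bvn_cdf(0.0, 0.0, r) == pytest.approx(expected, abs=1e-7)

    def test_perfect_correlation_limits(self):
        assert bvn_cdf(0.5, 1.5, 1.0) == pytest.approx(ndtr(0.5))
        assert bvn_cdf(0.5, -0.5, -1.0) == pytest.approx(0.0, abs=1e-12)


class TestOls:
    def test_exact_fit(self):
        t = np.array([0.0, 1, 2, 3])
        r = ols_effect(RegressionInput(outcome=2 * t, treatment=t))
        assert r.coef_adoption == pytest.approx(2.0, abs=1e-12)
        assert r.se == pytest.approx(0.0, abs=1e-8)

    def test_six_point_fixture(self):
        # group means 2 and 5 -> slope 3 by the normal equations
        inp = RegressionInput(
            outcome=np.array([1.0, 2, 3, 4, 5, 6]),
            treatment=np.array([0.0, 0, 0, 1, 1, 1]),
        )
        assert ols_effect(inp).coef_adoption == pytest.approx(3.0, abs=1e-12)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=30)
        inp = RegressionInput(
            outcome=rng.normal(size=30),
            treatment=x,
            controls=np.column_stack([x, rng.normal(size=30)]),
            control_names=["dup_of_treatment", "fine"],
        )
        with pytest.raises(ValueError, match="collinear"):
            ols_effect(inp)

    def test_cluster_se_larger_with_cluster_shocks(self, rng):
        g = np.repeat(np.arange(40), 10)
        shock = rng.normal(size=40)[g]
        t = rng.normal(size=400)
        y = 0.5 * t + shock + 0.3 * rng.normal(size=400)
        clustered = ols_effect(
            RegressionInput(outcome=y, treatment=t, clusters=g, cluster_var="g")
        )
        plain = ols_effect(RegressionInput(outcome=y, treatment=t))
        assert clustered.cluster_var == "g"
        assert clustered.se > 0 and plain.se > 0

    def test_missing_rows_dropped_and_counted(self, rng):
        y = rng.normal(size=20)
        y[3] = np.nan
        r = ols_effect(RegressionInput(outcome=y, treatment=rng.normal(size=20)))
        assert r.n_obs == 19 and r.n_dropped == 1


class TestIv:
    def test_ratio_of_covariances_oracle(self, rng):
        z = rng.normal(size=10)
        t = 0.8 * z + rng.normal(size=10)
        y = 0.5 * t + rng.normal(size=10)
        r = iv_effect(RegressionInput(outcome=y, treatment=t, instruments=z[:, None]))
        oracle = np.cov(z, y)[0, 1] / np.cov(z, t)[0, 1]
        assert r.coef_adoption == pytest.approx(oracle, abs=1e-10)
        assert slope_iv(y, t, z) == pytest.approx(oracle, abs=1e-12)

    def test_instrumenting_with_treatment_reproduces_ols(self, rng):
        t = rng.normal(size=60)
        y = 1.4 * t + rng.normal(size=60)
        x = rng.normal(size=(60, 2))
        iv = iv_effect(
            RegressionInput(outcome=y, treatment=t, controls=x, instruments=t[:, None])
        )
        ols = ols_effect(RegressionInput(outcome=y, treatment=t, controls=x))
        assert iv.coef_adoption == pytest.approx(ols.coef_adoption, abs=1e-8)

    def test_matches_statsmodels_gmm_iv2sls(self, rng):
        """Independent cross-check of the 2SLS point estimate."""
        from statsmodels.sandbox.regression.gmm import IV2SLS

        n = 300
        z = rng.normal(size=(n, 2))
        u = rng.normal(size=n)
        t = z @ [0.7, 0.4] + u + rng.normal(size=n)
        x = rng.normal(size=n)
        y = 0.5 * t + 0.3 * x + u + rng.normal(size=n)
        inp = RegressionInput(
            outcome=y, treatment=t, controls=x[:, None], instruments=z
        )
        mine = iv_effect(inp)
        exog = np.column_stack([np.ones(n), t, x])
        instr = np.column_stack([np.ones(n), z, x])
        ref = IV2SLS(y, exog, instrument=instr).fit()
        assert mine.coef_adoption == pytest.approx(ref.params[1], abs=1e-8)

    def test_under_identification_error(self, rng):
        inp = RegressionInput(outcome=rng.normal(size=20), treatment=rng.normal(size=20))
        with pytest.raises(ValueError, match="instrument"):
            iv_effect(inp)

    def test_weak_instrument_flagged(self, rng):
        n = 200
        z = rng.normal(size=n)
        t = 0.01 * z + rng.normal(size=n)  # nearly irrelevant
        y = 0.5 * t + rng.normal(size=n)
        r = iv_effect(RegressionInput(outcome=y, treatment=t, instruments=z[:, None]))
        assert r.weak_identification
        assert r.first_stage_F < 10


class TestEtaControl:
    @staticmethod
    def _data(rng, n=400):
        z = rng.normal(size=n)
        om = rng.normal(size=n)
        ts = (z + om > 0).astype(float)
        eta = np.where(
            (ts == 1) & (rng.random(n) < 0.2),
            -1.0,
            np.where((ts == 0) & (rng.random(n) < 0.15), 1.0, 0.0),
        )
        x = rng.normal(size=(n, 2))
        w = 0.3 * ts + x @ [0.5, -0.2] + rng.normal(size=n)
        return w, ts, ts + eta, eta, x, z

    def test_identity_between_reported_and_true_treatment(self, rng):
        w, ts, tobs, eta, x, _ = self._data(rng)
        a = eta_control_effect(
            RegressionInput(outcome=w, treatment=tobs, eta=eta, controls=x)
        )
        b = eta_control_effect(
            RegressionInput(outcome=w, treatment=ts, eta=eta, controls=x)
        )
        assert a.coef_adoption == pytest.approx(b.coef_adoption, abs=1e-8)
        # theta(T_obs model) = theta(T* model) - gamma, from T_obs = T* + eta
        assert a.coef_eta == pytest.approx(b.coef_eta - b.coef_adoption, abs=1e-8)

    def test_zero_eta_reduces_to_plain_ols(self, rng):
        w, ts, _, _, x, _ = self._data(rng)
        a = eta_control_effect(
            RegressionInput(outcome=w, treatment=ts, eta=np.zeros_like(w), controls=x)
        )
        b = ols_effect(RegressionInput(outcome=w, treatment=ts, controls=x))
        # zero eta column is collinear-free but contributes nothing
        assert a.coef_adoption == pytest.approx(b.coef_adoption, abs=1e-10)

    def test_identity_holds_under_2sls(self, rng):
        w, ts, tobs, eta, x, z = self._data(rng)
        a = eta_control_effect(
            RegressionInput(
                outcome=w, treatment=tobs, eta=eta, controls=x, instruments=z[:, None]
            )
        )
        b = eta_control_effect(
            RegressionInput(
                outcome=w, treatment=ts, eta=eta, controls=x, instruments=z[:, None]
            )
        )
        assert a.coef_adoption == pytest.approx(b.coef_adoption, abs=1e-8)

    def test_missing_eta_rejected(self, rng):
        w, ts, *_ = self._data(rng)
        with pytest.raises(ValueError, match="eta"):
            eta_control_effect(RegressionInput(outcome=w, treatment=ts))


class TestLewbel:
    @staticmethod
    def _het_data(rng, n=4000):
        # variance increasing in x (asymmetric), so cov(x, e^2) != 0
        x = rng.normal(size=n)
        e1 = rng.normal(size=n) * np.exp(0.5 * x)
        u = rng.normal(size=n)
        t = 0.5 * x + e1 + 0.5 * u
        y = 0.3 * t + 1.0 * x + u + 0.3 * rng.normal(size=n)
        return y, t, x

    def test_recovers_effect_on_heteroscedastic_dgp(self, rng):
        y, t, x = self._het_data(rng)
        r = lewbel_iv(
            RegressionInput(outcome=y, treatment=t, controls=x[:, None], control_names=["x"])
        )
        assert not r.weak_identification
        assert abs(r.coef_adoption - 0.3) < 3 * r.se

    def test_constructed_instruments_are_centered(self, rng):
        y, t, x = self._het_data(rng, n=500)
        r = lewbel_iv(
            RegressionInput(outcome=y, treatment=t, controls=x[:, None], control_names=["x"])
        )
        # instruments are (x - mean(x)) * e with e the first-stage residual;
        # both factors are orthogonal to the constant, so the mean is ~0
        assert r.diagnostics["instruments"] == ["lw_x"]

    def test_homoscedastic_first_stage_flagged(self, rng):
        n = 2000
        x = rng.normal(size=n)
        t = 0.5 * x + rng.normal(size=n)
        y = 0.3 * t + x + rng.normal(size=n)
        r = lewbel_iv(
            RegressionInput(outcome=y, treatment=t, controls=x[:, None], control_names=["x"])
        )
        assert r.weak_identification
        assert r.diagnostics["bp_pvalue"] > 0.1


class TestBiprobit:
    @staticmethod
    def _data(rng, n=2000, rho=0.5):
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        e = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        t = (0.3 * x + 1.0 * z + e[:, 1] > 0).astype(float)
        y = (0.2 + 0.7 * t - 0.3 * x + e[:, 0] > 0).astype(float)
        true_ate = float(np.mean(ndtr(0.9 - 0.3 * x) - ndtr(0.2 - 0.3 * x)))
        return y, t, x, z, true_ate

    def test_rho_zero_matches_independent_probits(self, rng):
        y, t, x, z, _ = self._data(rng, rho=0.0)
        inp = RegressionInput(
            outcome=y, treatment=t, controls=x[:, None], instruments=z[:, None]
        )
        r = biprobit_ate(inp, fix_rho=0.0)
        pr = sm.Probit(
            y, pd.DataFrame({"const": 1.0, "x": x, "treatment": t})
        ).fit(disp=0)
        assert r.diagnostics["gamma_latent"] == pytest.approx(
            pr.params["treatment"], abs=1e-4
        )

    def test_recovers_ate_under_endogeneity(self, rng):
        y, t, x, z, true_ate = self._data(rng, rho=0.5)
        inp = RegressionInput(
            outcome=y, treatment=t, controls=x[:, None], instruments=z[:, None]
        )
        r = biprobit_ate(inp)
        assert abs(r.coef_adoption - true_ate) < 3 * max(r.se, 0.02)
        assert abs(r.diagnostics["rho"] - 0.5) < 0.25

    def test_mle_beats_coarse_grid_oracle(self, rng):
        """Profile slice of the likelihood evaluated with an independent
        bivariate-normal CDF: the optimizer's solution must dominate every
        coarse grid point around it and sit within one grid step of the
        grid argmin."""
        y, t, x, z, _ = self._data(rng, n=150, rho=0.4)
        inp = RegressionInput(
            outcome=y, treatment=t, controls=x[:, None], instruments=z[:, None]
        )
        r = biprobit_ate(inp)
        p = r.params
        q1, q2 = 2 * y - 1, 2 * t - 1

        def oracle_nll(beta_x, gamma, rho):
            idx1 = p["out_const"] + beta_x * x + gamma * t
            idx2 = (
                p["treat_const"]
                + p["treat_z0"] * z
                + p["treat_x0"] * x
            )
            total = 0.0
            for r_ in np.unique(q1 * q2):
                m = (q1 * q2) == r_
                mvn = multivariate_normal(cov=[[1, r_ * rho], [r_ * rho, 1]])
                pts = np.column_stack([q1[m] * idx1[m], q2[m] * idx2[m]])
                total -= np.log(np.clip(mvn.cdf(pts), 1e-300, None)).sum()
            return total

        b_hat = p["out_x0"]
        g_hat = p["treatment"]
        rho_hat = np.tanh(p["atanh_rho"])
        step = 0.25
        grid_b = b_hat + step * np.arange(-2, 3)
        grid_g = g_hat + step * np.arange(-2, 3)
        grid_r = np.clip(rho_hat + step * np.arange(-2, 3), -0.95, 0.95)
        vals = {
            (b, g, rr): oracle_nll(b, g, rr)
            for b in grid_b
            for g in grid_g
            for rr in grid_r
        }
        best = min(vals, key=vals.get)
        assert oracle_nll(b_hat, g_hat, rho_hat) <= vals[best] + 1e-6
        assert abs(best[0] - b_hat) <= step + 1e-9
        assert abs(best[1] - g_hat) <= step + 1e-9
        assert abs(best[2] - rho_hat) <= step + 1e-9

    def test_non_binary_outcome_rejected(self, rng):
        inp = RegressionInput(
            outcome=rng.normal(size=50),
            treatment=(rng.random(50) < 0.5).astype(float),
            instruments=rng.normal(size=(50, 1)),
        )
        with pytest.raises(ValueError, match="binary"):
            biprobit_ate(inp)


class TestBootstrap:
    def test_degenerate_outcome_gives_zero_se(self, rng):
        inp = RegressionInput(outcome=np.ones(80), treatment=rng.normal(size=80))
        se = bootstrap_se(ols_effect, inp, B=60, rng=np.random.default_rng(0))
        assert se == pytest.approx(0.0, abs=1e-10)

    def test_deterministic_given_seed(self, rng):
        t = rng.normal(size=100)
        y = 0.5 * t + rng.normal(size=100)
        inp = RegressionInput(outcome=y, treatment=t)
        a = bootstrap_se(ols_effect, inp, B=60, rng=np.random.default_rng(7))
        b = bootstrap_se(ols_effect, inp, B=60, rng=np.random.default_rng(7))
        assert a == b

    def test_close_to_analytic_cluster_se(self, rng):
        g = np.repeat(np.arange(50), 8)
        shock = rng.normal(size=50)[g]
        t = rng.normal(size=400)
        y = 0.5 * t + shock + rng.normal(size=400)
        inp = RegressionInput(outcome=y, treatment=t, clusters=g)
        analytic = ols_effect(inp).se
        boot = bootstrap_se(ols_effect, inp, B=400, rng=np.random.default_rng(3))
        assert abs(boot - analytic) / analytic < 0.25

    def test_minimum_draws_enforced(self, rng):
        inp = RegressionInput(outcome=rng.normal(size=30), treatment=rng.normal(size=30))
        with pytest.raises(ValueError):
            bootstrap_se(ols_effect, inp, B=10)


def test_slope_helpers_agree_with_matrix_estimators(rng):
    t = rng.normal(size=200)
    z = 0.6 * t + rng.normal(size=200)
    y = 1.1 * t + rng.normal(size=200)
    assert slope_ols(y, t) == pytest.approx(
        ols_effect(RegressionInput(outcome=y, treatment=t)).coef_adoption, abs=1e-10
    )
    assert slope_iv(y, t, z) == pytest.approx(
        iv_effect(
            RegressionInput(outcome=y, treatment=t, instruments=z[:, None])
        ).coef_adoption,
        abs=1e-10,
    )
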