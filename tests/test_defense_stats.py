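"""Centred-predictor logistic GLM/GLMM and the gamma log-link volume model."""

import subprocess
import sys
import textwrap

import numpy as np
import pytest
from scipy import optimize, special

from preyjnd.defense_stats import (
    behavior_analysis,
    center,
    fit_gamma_log,
    fit_logistic,
    replace_zeros,
)
from preyjnd.synthetic_data import BehaviorParams, gen_behavior


class TestCenter:
    def test_simple_arithmetic(self):
        assert center([1.0, 2.0, 3.0]).tolist() == [-1.0, 0.0, 1.0]

    def test_constant_vector_all_zero(self):
        assert np.allclose(center(np.full(7, 4.2)), 0.0, atol=1e-12)

    def test_output_mean_zero(self, rng):
        x = rng.lognormal(1.5, 0.4, 200)
        assert abs(center(x).mean()) < 1e-12

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            center([])


class TestReplaceZeros:
    def test_zeros_become_epsilon(self):
        assert replace_zeros([0.0, 0.4, 0.0]).tolist() == [0.001, 0.4, 0.001]

    def test_positives_untouched(self):
        v = np.array([0.2, 1.5, 0.001])
        assert replace_zeros(v).tolist() == v.tolist()

    def test_all_zero_vector(self):
        assert np.allclose(replace_zeros(np.zeros(4)), 0.001)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            replace_zeros([-0.1, 0.2])


@pytest.fixture(scope="module")
def logistic_data():
    rng = np.random.default_rng(42)
    n = 120
    x = center(rng.lognormal(np.log(5), 0.4, n))
    eta = 0.8 + 0.35 * x
    y = (rng.random(n) < special.expit(eta)).astype(float)
    fam = np.repeat(np.arange(12), 10)
    return y, x, fam


class TestLogisticGlm:
    def test_score_equations_hold_at_optimum(self, logistic_data):
        y, x, _ = logistic_data
        fit = fit_logistic(y, x)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.array([fit.estimates["intercept"], fit.estimates["slope"]])
        p = special.expit(X @ beta)
        assert np.all((p > 0) & (p < 1))
        assert np.max(np.abs(X.T @ (y - p))) < 1e-8

    def test_centering_identity(self, logistic_data):
        # slope invariant; intercept shifts by slope * mean
        y, x, _ = logistic_data
        shift = 3.7
        fit_c = fit_logistic(y, x)
        fit_u = fit_logistic(y, x + shift)
        assert fit_u.estimates["slope"] == pytest.approx(fit_c.estimates["slope"],
                                                         abs=1e-8)
        assert fit_u.estimates["intercept"] == pytest.approx(
            fit_c.estimates["intercept"] - fit_c.estimates["slope"] * shift, abs=1e-7)

    def test_binary_response_required(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(10), np.arange(10.0))


def laplace_nll_oracle(theta, y, X, groups):
    """Independent Laplace-approximation marginal negative log likelihood."""
    beta, sigma = theta[:-1], np.exp(theta[-1])
    total = 0.0
    for g in np.unique(groups):
        yg, Xg = y[groups == g], X[groups == g]

        def neg_h(u):
            eta = Xg @ beta + sigma * u
            return -(-0.5 * u * u - 0.5 * np.log(2 * np.pi)
                     + yg @ eta - np.logaddexp(0, eta).sum())

        res = optimize.minimize_scalar(neg_h, bounds=(-12, 12), method="bounded",
                                       options={"xatol": 1e-10})
        u_hat = res.x
        for _ in range(4):  # polish the mode so log-curvature noise ~ 1e-14
            p = special.expit(Xg @ beta + sigma * u_hat)
            grad = -u_hat + sigma * (yg - p).sum()
            curv = 1.0 + sigma ** 2 * (p * (1 - p)).sum()
            u_hat += grad / curv
        p = special.expit(Xg @ beta + sigma * u_hat)
        curv = 1.0 + sigma ** 2 * (p * (1 - p)).sum()
        total -= (-neg_h(u_hat)) + 0.5 * np.log(2 * np.pi) - 0.5 * np.log(curv)
    return total


class TestLogisticGlmm:
    def test_sigma_zero_reduces_to_glm(self, logistic_data):
        y, x, fam = logistic_data
        glm = fit_logistic(y, x)
        mixed0 = fit_logistic(y, x, family_id=fam, fix_sigma=0.0)
        assert mixed0.estimates["intercept"] == pytest.approx(
            glm.estimates["intercept"], abs=1e-6)
        assert mixed0.estimates["slope"] == pytest.approx(
            glm.estimates["slope"], abs=1e-6)

    def test_one_node_equals_laplace_oracle(self):
        p = BehaviorParams(uposture_slope_color=0.0, uposture_slope_luminance=0.3,
                           family_sd=0.8)
        d = gen_behavior(params=p, seed=77)
        x = center(d.ventral_luminance_jnd.to_numpy())
        y = d.u_posture.to_numpy(float)
        fam_codes = d.family_id.astype("category").cat.codes.to_numpy()
        fit1 = fit_logistic(y, x, family_id=fam_codes, quadrature_nodes=1)
        X = np.column_stack([np.ones_like(x), x])
        res = optimize.minimize(laplace_nll_oracle, np.array([1.0, 0.0, -0.5]),
                                args=(y, X, fam_codes), method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12,
                                         "maxiter": 3000})
        # Powell polish: the marginal surface is flat enough near the optimum
        # that a lone simplex stalls above the comparison tolerance
        res = optimize.minimize(laplace_nll_oracle, res.x, args=(y, X, fam_codes),
                                method="Powell",
                                options={"xtol": 1e-12, "ftol": 1e-14,
                                         "maxiter": 10000})
        assert fit1.estimates["intercept"] == pytest.approx(res.x[0], abs=1e-6)
        assert fit1.estimates["slope"] == pytest.approx(res.x[1], abs=1e-6)
        assert fit1.random_intercept_sd == pytest.approx(np.exp(res.x[2]), abs=1e-5)

    def test_quadrature_converged_beyond_15_nodes(self):
        p = BehaviorParams(uposture_slope_luminance=0.3, family_sd=0.8)
        d = gen_behavior(params=p, seed=78)
        x = center(d.ventral_luminance_jnd.to_numpy())
        y = d.u_posture.to_numpy(float)
        fam = d.family_id.to_numpy()
        f15 = fit_logistic(y, x, family_id=fam, quadrature_nodes=15)
        f30 = fit_logistic(y, x, family_id=fam, quadrature_nodes=30)
        for t in f15.terms:
            assert f15.estimates[t] == pytest.approx(f30.estimates[t], abs=1e-6)

    def test_matches_lme4_glmer_cross_check(self, tmp_path):
        # external mixed-model oracle fitted by a different code base
        p = BehaviorParams(uposture_slope_color=0.0, uposture_slope_luminance=0.3,
                           family_sd=0.8)
        d = gen_behavior(params=p, seed=1007)
        x = center(d.ventral_luminance_jnd.to_numpy())
        d = d.assign(xc=x, y=d.u_posture.astype(int))
        csv = tmp_path / "g.csv"
        d[["y", "xc", "family_id"]].to_csv(csv, index=False)
        fit = fit_logistic(d.y.to_numpy(float), x, family_id=d.family_id.to_numpy())
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ xc + (1|family_id), data=d, family=binomial, nAGQ=15)
            co <- summary(m)$coefficients
            cat(co[1,1], co[2,1], co[1,2], co[2,2],
                sqrt(unlist(VarCorr(m)))[1], sep="\\n")
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        b0, b1, se0, se1, sd = map(float, out.stdout.strip().splitlines())
        assert fit.estimates["intercept"] == pytest.approx(b0, abs=2e-4)
        assert fit.estimates["slope"] == pytest.approx(b1, abs=2e-4)
        assert fit.standard_errors["intercept"] == pytest.approx(se0, abs=2e-3)
        assert fit.standard_errors["slope"] == pytest.approx(se1, abs=2e-3)
        assert fit.random_intercept_sd == pytest.approx(sd, abs=2e-3)

    def test_single_group_falls_back_to_glm(self, logistic_data):
        y, x, _ = logistic_data
        fit = fit_logistic(y, x, family_id=np.zeros(len(y)))
        assert any("plain GLM" in n for n in fit.notes)


def gamma_nll_oracle(theta, y, X):
    """Joint ML of a log-link gamma regression (beta and shape together)."""
    beta, log_k = theta[:-1], theta[-1]
    k = np.exp(log_k)
    mu = np.exp(X @ beta)
    from scipy.special import gammaln
    ll = np.sum(k * np.log(k * y / mu) - k * y / mu - np.log(y) - gammaln(k))
    return -ll


class TestGammaLogLink:
    def test_constant_response_intercept_log_c(self):
        y = np.full(30, 2.5)
        x = center(np.linspace(0, 1, 30))
        fit = fit_gamma_log(y, x, length=np.linspace(18, 26, 30))
        assert fit.estimates["intercept"] == pytest.approx(np.log(2.5), abs=1e-6)
        assert abs(fit.estimates["contrast"]) < 1e-6
        assert abs(fit.estimates["length"]) < 1e-6

    def test_matches_joint_ml_oracle_on_20_rows(self, rng):
        n = 20
        x = center(rng.lognormal(np.log(5), 0.3, n))
        length = rng.normal(22, 2, n)
        mu = np.exp(0.5 + 0.12 * x + 0.04 * (length - 22))
        y = rng.gamma(2.0, mu / 2.0)
        fit = fit_gamma_log(y, x, length=length - 22)
        X = np.column_stack([np.ones(n), x, length - 22])
        res = optimize.minimize(gamma_nll_oracle, np.array([0.5, 0.1, 0.0, 0.7]),
                                args=(y, X), method="Nelder-Mead",
                                options={"xatol": 1e-12, "fatol": 1e-12,
                                         "maxiter": 20000})
        assert res.success
        for est, oracle in zip(
                [fit.estimates["intercept"], fit.estimates["contrast"],
                 fit.estimates["length"]], res.x[:3]):
            assert est == pytest.approx(oracle, abs=1e-5)

    def test_nonpositive_response_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_log(np.array([0.0, 1.0]), np.array([0.1, -0.1]))


class TestBehaviorBattery:
    def test_battery_model_count_and_kinds(self):
        d = gen_behavior(seed=21)
        fits = behavior_analysis(d)
        assert set(fits) == {
            "uposture~ventral_color", "uposture~ventral_luminance",
            "fluid~ventral_color", "fluid~ventral_luminance",
            "volume~ventral_color+length", "volume~ventral_luminance+length",
        }
        assert fits["volume~ventral_color+length"].family == "gamma"
        assert "length" in fits["volume~ventral_color+length"].terms

    def test_dorsal_color_uposture_is_plain_glm(self):
        d = gen_behavior(seed=22)
        fits = behavior_analysis(d, include_dorsal=True)
        assert fits["uposture~dorsal_color"].random_intercept_sd is None
        assert fits["uposture~ventral_color"].n_groups == 12

    def test_null_generator_gives_no_systematic_slope(self):
        p = BehaviorParams(uposture_slope_color=0.0, uposture_slope_luminance=0.0,
                           fluid_slope_color=0.0, fluid_slope_luminance=0.0,
                           family_sd=0.0)
        zs = []
        for r in range(20):
            d = gen_behavior(params=p, seed=3000 + r)
            f = behavior_analysis(d)["uposture~ventral_color"]
            if f.converged and f.estimates:
                zs.append(f.z_values["ventral_color_contrast"])
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.6  # ~2.7 SE of a standard-normal mean at n=20

    def test_sign_recovery_matches_generator(self):
        # negative colour-contrast slope, positive luminance slope on a
        # larger-than-field sample so the signs are stable
        p = BehaviorParams(uposture_slope_color=-0.5, uposture_slope_luminance=0.5)
        d = gen_behavior(n_families=40, per_family=(5, 5), params=p, seed=23,
                         total_target=None)
        fits = behavior_analysis(d)
        assert fits["uposture~ventral_color"].estimates["ventral_color_contrast"] < 0
        assert fits["uposture~ventral_luminance"].estimates[
            "ventral_luminance_contrast"] > 0
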