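import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import check_grad
from scipy.special import ndtr
from scipy.stats import chi2, multivariate_normal

from espccd.esp_probit import (
    ATTReport,
    ESPData,
    ESPEstimate,
    _att_point,
    att_esp,
    bvn_cdf,
    esp_loglik,
    esp_score_obs,
    fit_esp,
    relative_change,
    render_att,
    render_estimates,
    wald_independence_test,
)
from espccd.synthetic_data import SyntheticConfig, generate_population

from conftest import make_model_data


# ---------------------------------------------------------------------------
# bivariate normal CDF
# ---------------------------------------------------------------------------

class TestBvnCdf:
    def test_origin_independence(self):
        assert bvn_cdf(0.0, 0.0, 0.0) == pytest.approx(0.25, abs=1e-12)

    @pytest.mark.parametrize("rho", [-0.95, -0.5, 0.0, 0.3, 0.5, 0.9])
    def test_origin_closed_form(self, rho):
        # Phi2(0, 0; rho) = 1/4 + arcsin(rho)/(2 pi)
        expected = 0.25 + np.arcsin(rho) / (2.0 * np.pi)
        assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(expected, abs=1e-10)

    @pytest.mark.parametrize("b", [-2.0, 0.0, 1.3])
    def test_marginal_limit(self, b):
        assert bvn_cdf(8.0, b, 0.6) == pytest.approx(ndtr(b), abs=1e-8)

    def test_symmetry_in_arguments(self, rng):
        a, b = rng.normal(size=50), rng.normal(size=50)
        assert np.allclose(bvn_cdf(a, b, 0.4), bvn_cdf(b, a, 0.4), atol=1e-12)

    def test_degenerate_correlations(self):
        assert bvn_cdf(0.5, 1.5, 1.0) == pytest.approx(ndtr(0.5), abs=1e-12)
        assert bvn_cdf(0.5, -0.5, -1.0) == pytest.approx(
            max(0.0, ndtr(0.5) + ndtr(-0.5) - 1.0), abs=1e-12
        )

    def test_matches_scipy_multivariate_normal(self, rng):
        # independent library oracle on random points
        for _ in range(60):
            a, b = rng.normal(scale=2, size=2)
            rho = rng.uniform(-0.98, 0.98)
            ref = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]]).cdf([a, b])
            assert bvn_cdf(a, b, rho) == pytest.approx(ref, abs=1e-8)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bvn_cdf(np.nan, 0.0, 0.0)
        with pytest.raises(ValueError):
            bvn_cdf(0.0, 0.0, 1.5)


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _toy_data(n=60, seed=0, kx=2):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(n), rng.normal(size=(n, kx - 1))])
    Z = np.column_stack([X, rng.uniform(0, 1, n)])
    treat = rng.integers(0, 2, n)
    treat[:2] = [0, 1]  # both arms non-empty
    y = rng.integers(0, 2, n)
    cluster = rng.integers(0, 6, n)
    return ESPData(y=y, treat=treat, X=X, Z=Z, cluster=cluster)


def test_loglik_closed_form_cells():
    # two farmers with all linear indices zero:
    # treated y=1 at rho1=0 -> 1/4; untreated y=0 at rho0=0.5 -> 1/3
    X = np.ones((2, 1))
    Z = np.column_stack([X, [0.0, 1.0]])
    data = ESPData(y=[1, 0], treat=[1, 0], X=X, Z=Z, cluster=[0, 1])
    params = np.array([0.0, 0.0, 0.0, 0.0, 0.0, np.arctanh(0.5)])
    assert esp_loglik(params, data) == pytest.approx(
        np.log(0.25) + np.log(1.0 / 3.0), abs=1e-10
    )


@given(
    seed=st.integers(0, 10_000),
    rho1=st.floats(-0.9, 0.9),
    rho0=st.floats(-0.9, 0.9),
)
def test_cell_probabilities_sum_to_one(seed, rho1, rho0):
    """The four (treat, y) likelihood cells partition the sample space."""
    rng = np.random.default_rng(seed)
    zi, xb1, xb0 = rng.normal(scale=1.5, size=3)
    cells = [
        bvn_cdf(zi, xb1, rho1),
        bvn_cdf(zi, -xb1, -rho1),
        bvn_cdf(-zi, xb0, -rho0),
        bvn_cdf(-zi, -xb0, rho0),
    ]
    assert sum(cells) == pytest.approx(1.0, abs=1e-10)


def test_zero_rho_factorizes_into_three_probits():
    data = _toy_data(n=200, seed=1)
    rng = np.random.default_rng(2)
    gamma = rng.normal(scale=0.5, size=data.Z.shape[1])
    b1 = rng.normal(scale=0.5, size=data.X.shape[1])
    b0 = rng.normal(scale=0.5, size=data.X.shape[1])
    params = np.concatenate([gamma, b1, b0, [0.0, 0.0]])
    t = data.treat == 1
    expected = (
        sm.Probit(data.treat, data.Z).loglike(gamma)
        + sm.Probit(data.y[t], data.X[t]).loglike(b1)
        + sm.Probit(data.y[~t], data.X[~t]).loglike(b0)
    )
    assert esp_loglik(params, data) == pytest.approx(expected, abs=1e-10)


def test_analytic_score_matches_numerical_gradient():
    data = _toy_data(n=80, seed=3)
    rng = np.random.default_rng(4)
    params = rng.normal(scale=0.3, size=data.Z.shape[1] + 2 * data.X.shape[1] + 2)
    err = check_grad(
        lambda p: esp_loglik(p, data),
        lambda p: esp_score_obs(p, data).sum(axis=0),
        params,
    )
    assert err < 1e-5


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def test_fit_with_zero_rho_matches_separate_probits():
    config = SyntheticConfig(
        n_villages=150, village_size_range=(10, 16), mode="model",
        rho1=0.0, rho0=0.0, seed=11,
    )
    table, _ = generate_population(config)
    data = make_model_data(table, config)
    # with rho pinned at zero the likelihood factorizes, so the joint
    # MLE must coincide with the three separate probits
    est0 = fit_esp(data, fix_rho_zero=True, compute_vcov=False)
    assert est0.converged
    t = data.treat == 1
    b1_ref = sm.Probit(data.y[t], data.X[t]).fit(disp=0).params
    b0_ref = sm.Probit(data.y[~t], data.X[~t]).fit(disp=0).params
    assert np.allclose(est0.beta1, b1_ref, atol=1e-3)
    assert np.allclose(est0.beta0, b0_ref, atol=1e-3)
    # the unconstrained fit finds correlations near zero
    est = fit_esp(data, compute_vcov=False)
    assert est.converged
    assert abs(est.rho1) < 0.12 and abs(est.rho0) < 0.12


def test_all_treated_rejected():
    X = np.ones((10, 1))
    Z = np.column_stack([X, np.arange(10.0)])
    with pytest.raises(ValueError, match="control"):
        ESPData(y=np.ones(10), treat=np.ones(10), X=X, Z=Z, cluster=np.zeros(10))


def test_collinear_covariates_rejected(rng):
    n = 40
    x = rng.normal(size=n)
    X = np.column_stack([np.ones(n), x, 2 * x])  # perfect collinearity
    Z = np.column_stack([X, rng.uniform(size=n)])
    treat = rng.integers(0, 2, n)
    treat[:2] = [0, 1]
    with pytest.raises(ValueError, match="collinear"):
        ESPData(y=rng.integers(0, 2, n), treat=treat, X=X, Z=Z, cluster=np.zeros(n))


def test_missing_instrument_rejected(rng):
    n = 30
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    treat = rng.integers(0, 2, n)
    treat[:2] = [0, 1]
    with pytest.raises(ValueError, match="instrument"):
        ESPData(y=rng.integers(0, 2, n), treat=treat, X=X, Z=X.copy(), cluster=np.zeros(n))


def test_recovery_on_shared_population(model_fit):
    """Point estimates land near the generating parameters at n ~ 5,000."""
    config, _, _, _, est = model_fit
    assert est.converged
    assert est.rho1 == pytest.approx(config.rho1, abs=0.15)
    assert est.rho0 == pytest.approx(config.rho0, abs=0.15)
    true_gamma = np.array(list(config.gamma.values()))
    assert np.allclose(est.gamma, true_gamma, atol=4 * est.se()[: est.kz] + 0.05)


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def test_wald_zero_at_zero_rho():
    est = ESPEstimate(
        params=np.array([0.1, 0.2, 0.3, 0.0, 0.0]),
        vcov=np.eye(5) * 0.01,
        loglik=-10.0,
        converged=True,
        n=100,
        n_treated=50,
        n_clusters=10,
        x_names=["const"],
        z_names=["const", "iv"],
    )
    w = wald_independence_test(est)
    assert w.statistic == pytest.approx(0.0, abs=1e-12)
    assert w.df == 2
    assert w.p_value == pytest.approx(1.0)


def test_wald_agrees_with_likelihood_ratio(model_fit):
    """Wald and LR tests of rho1 = rho0 = 0 agree to asymptotic order.

    Under rho = 0 the likelihood factorizes, so the constrained MLE is
    exactly the three separate probits: the LR statistic needs no
    second constrained optimization.
    """
    config, _, _, data, est = model_fit
    w = wald_independence_test(est)
    t = data.treat == 1
    ll0 = (
        sm.Probit(data.treat, data.Z).fit(disp=0).llf
        + sm.Probit(data.y[t], data.X[t]).fit(disp=0).llf
        + sm.Probit(data.y[~t], data.X[~t]).fit(disp=0).llf
    )
    lr = 2.0 * (est.loglik - ll0)
    assert lr >= -1e-6
    # same order of magnitude and same 10%-level decision
    assert w.statistic == pytest.approx(lr, rel=0.6, abs=2.0)
    assert (w.p_value < 0.10) == (chi2.sf(lr, 2) < 0.10)


def test_wald_power_against_strong_correlation():
    config = SyntheticConfig(
        n_villages=120, village_size_range=(20, 30), mode="model",
        rho1=0.6, rho0=0.0, seed=21,
    )
    table, _ = generate_population(config)
    est = fit_esp(make_model_data(table, config))
    assert wald_independence_test(est).p_value < 0.05


# ---------------------------------------------------------------------------
# ATT
# ---------------------------------------------------------------------------

def test_att_zero_when_regimes_identical():
    data = _toy_data(n=150, seed=5)
    rng = np.random.default_rng(6)
    gamma = rng.normal(scale=0.4, size=data.Z.shape[1])
    beta = rng.normal(scale=0.4, size=data.X.shape[1])
    params = np.concatenate([gamma, beta, beta, [0.3, 0.3]])
    att, p1, p0 = _att_point(params, data)
    assert att == pytest.approx(0.0, abs=1e-14)
    assert p1 == pytest.approx(p0, abs=1e-14)


def test_att_report_invariant_enforced():
    with pytest.raises(ValueError):
        ATTReport(att=0.5, se=0.1, p_treated=0.2, p_counterfactual=0.1,
                  change_pct=50.0, method="ESP")


@pytest.mark.parametrize(
    "att, p_treated, expected",
    [(-0.011, 0.129, 8.527), (-0.025, 0.128, 19.531), (0.0, 0.4, 0.0)],
)
def test_relative_change_values(att, p_treated, expected):
    assert relative_change(att, p_treated) == pytest.approx(expected, abs=5e-4)


def test_relative_change_rejects_zero_denominator():
    with pytest.raises(ValueError):
        relative_change(0.1, 0.0)


def test_att_bootstrap_se_and_renderings(model_fit):
    config, table, truth, data, est = model_fit
    rep = att_esp(est, data, bootstrap_reps=15, seed=9)
    assert np.isfinite(rep.se) and rep.se > 0
    assert rep.att == pytest.approx(rep.p_treated - rep.p_counterfactual, abs=1e-12)
    text = render_att(rep)
    assert "ATT" in text and "Change" in text
    table5 = render_estimates(est, wald_independence_test(est))
    assert "rho1" in table5 and "Wald" in table5
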