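"""Regression fits and epidemiological statistics against independent oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats as sps

from prsjoint import (
    InputError,
    NoEventsError,
    RegressionFit,
    SeparationError,
    auc,
    cochran_armitage_trend,
    fit_cox,
    fit_logistic,
    rcs_basis,
    reri_ap,
    snp_lifestyle_scan,
)
from prsjoint.errors import AliasedColumnWarning

from conftest import make_panel


def expand_2x2(a, b, c, d):
    """Rows for (exposed case, exposed control, unexposed case, unexposed control)."""
    x = np.array([1.0] * (a + b) + [0.0] * (c + d))
    y = np.array([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
    return pd.DataFrame({"exposed": x}), y


# ----------------------------------------------------------------------
# logistic regression
# ----------------------------------------------------------------------

def test_logistic_saturated_2x2_equals_cross_product_ratio():
    X, y = expand_2x2(20, 80, 10, 90)
    fit = fit_logistic(X, y)
    assert math.exp(fit["exposed"]) == pytest.approx(2.25, abs=1e-6)


def test_logistic_intercept_only_closed_form():
    y = np.array([1.0] * 30 + [0.0] * 70)
    fit = fit_logistic(pd.DataFrame(index=range(100)), y)
    assert fit["const"] == pytest.approx(math.log(0.3 / 0.7), abs=1e-8)


def test_logistic_matches_generic_optimizer_deviance():
    rng = np.random.default_rng(17)
    n = 400
    X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.4, n)})
    eta = -1.0 + 0.8 * X["x1"] - 0.5 * X["x2"]
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    fit = fit_logistic(X, y)

    design = np.column_stack([np.ones(n), X.to_numpy()])

    def nll(beta):
        lp = design @ beta
        return float(np.sum(np.log1p(np.exp(lp))) - y @ lp)

    res = optimize.minimize(nll, np.zeros(3), method="BFGS", options={"gtol": 1e-10})
    assert -fit.llf == pytest.approx(res.fun, abs=1e-6)


def test_logistic_detects_perfect_separation():
    X = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
    y = np.r_[np.zeros(20), np.ones(20)]
    with pytest.raises(SeparationError):
        fit_logistic(X, y)


def test_logistic_drops_aliased_columns_with_warning():
    rng = np.random.default_rng(18)
    x = rng.normal(size=200)
    y = (rng.random(200) < 0.3).astype(float)
    X = pd.DataFrame({"x": x, "x_copy": x})
    with pytest.warns(AliasedColumnWarning):
        fit = fit_logistic(X, y)
    assert "x_copy" not in fit.terms


def test_logistic_wald_table_consistency():
    X, y = expand_2x2(25, 75, 15, 85)
    fit = fit_logistic(X, y)
    t = fit.table().set_index("term").loc["exposed"]
    assert t["ci_low"] < t["estimate"] < t["ci_high"]
    z975 = sps.norm.ppf(0.975)
    assert t["ci_low"] == pytest.approx(math.exp(t["beta"] - z975 * t["se"]), rel=1e-12)


# ----------------------------------------------------------------------
# Cox regression
# ----------------------------------------------------------------------

def _six_subject_data():
    # no ties, single binary covariate
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    event = np.array([1, 1, 0, 1, 1, 1])
    x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0])
    return time, event, x


def brute_force_cox_beta(time, event, x):
    """Maximise the written-out partial likelihood numerically."""
    order = np.argsort(time)
    t, e, xx = time[order], event[order], x[order]

    def neg_log_pl(beta):
        out = 0.0
        for i in range(len(t)):
            if e[i] == 1:
                risk = xx[i:]  # later or equal times (no ties)
                out -= beta * xx[i] - math.log(np.sum(np.exp(beta * risk)))
        return out

    res = optimize.minimize_scalar(neg_log_pl, bounds=(-10, 10), method="bounded",
                                   options={"xatol": 1e-12})
    return res.x


def test_cox_six_subject_matches_partial_likelihood_oracle():
    time, event, x = _six_subject_data()
    fit = fit_cox(time, event, pd.DataFrame({"x": x}))
    assert fit["x"] == pytest.approx(brute_force_cox_beta(time, event, x), abs=1e-6)


def test_cox_time_scale_invariance():
    time, event, x = _six_subject_data()
    f1 = fit_cox(time, event, pd.DataFrame({"x": x}))
    f2 = fit_cox(2.0 * time, event, pd.DataFrame({"x": x}))
    assert f1["x"] == pytest.approx(f2["x"], abs=1e-8)


def test_cox_zero_information_and_no_events_errors():
    time, event, x = _six_subject_data()
    with pytest.raises(InputError):
        fit_cox(time, event, pd.DataFrame({"c": np.ones(6)}))
    with pytest.raises(NoEventsError):
        fit_cox(time, np.zeros(6), pd.DataFrame({"x": x}))


def test_rare_disease_or_approximates_hr():
    # logistic OR and Cox HR agree within 15% at incidence <= 1%
    rng = np.random.default_rng(19)
    n = 200_000
    x = rng.binomial(1, 0.3, n).astype(float)
    beta = math.log(1.5)
    h = 8e-4 * np.exp(beta * x)
    onset = rng.exponential(1.0 / h)
    censor = rng.uniform(8, 12, n)
    event = (onset <= censor).astype(float)
    time = np.minimum(onset, censor)
    assert event.mean() <= 0.01
    X = pd.DataFrame({"x": x})
    or_ = math.exp(fit_logistic(X, event)["x"])
    hr = math.exp(fit_cox(time, event, X)["x"])
    assert abs(math.log(or_ / hr)) < math.log(1.15)


# ----------------------------------------------------------------------
# AUC
# ----------------------------------------------------------------------

def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    cases, ctrls = s[y == 1], s[y == 0]
    total = 0.0
    for c in cases:
        total += np.sum(c > ctrls) + 0.5 * np.sum(c == ctrls)
    return total / (len(cases) * len(ctrls))


def test_auc_examples():
    assert auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5
    assert auc([0.2, 0.8, 0.4, 0.9], [0, 0, 1, 1]) == pytest.approx(0.75)


def test_auc_equals_bruteforce_exactly():
    rng = np.random.default_rng(20)
    for _ in range(20):
        n = int(rng.integers(10, 300))
        ties = rng.random() < 0.5
        s = rng.integers(0, 10, n).astype(float) if ties else rng.normal(size=n)
        y = rng.binomial(1, 0.4, n)
        if y.sum() in (0, n):
            continue
        assert auc(s, y) == brute_force_auc(s, y)


def test_auc_agrees_with_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(21)
    s = rng.normal(size=500)
    y = rng.binomial(1, 0.3, 500)
    assert auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_auc_single_class_errors():
    with pytest.raises(InputError):
        auc([1.0, 2.0], [1, 1])


# ----------------------------------------------------------------------
# restricted cubic splines
# ----------------------------------------------------------------------

def test_rcs_linear_below_first_knot():
    knots = np.array([0.0, 1.0, 2.0, 3.0])
    x = np.linspace(-5, -0.1, 50)
    basis = rcs_basis(x, knots=knots)
    assert basis.basis.shape == (50, 3)
    np.testing.assert_allclose(basis.basis[:, 1:], 0.0, atol=1e-12)


def test_rcs_linear_beyond_boundary_knots():
    rng = np.random.default_rng(22)
    x = rng.normal(size=2000)
    basis = rcs_basis(x, n_knots=4)
    hi = basis.knots[-1]
    grid = np.linspace(hi + 0.5, hi + 5.0, 200)
    B = basis.transform(grid)
    # second differences vanish where the spline is constrained linear
    second = np.diff(B, n=2, axis=0)
    np.testing.assert_allclose(second, 0.0, atol=1e-8)


def test_rcs_affine_invariance_of_fitted_predictions():
    rng = np.random.default_rng(23)
    x = rng.normal(size=500)
    y = np.sin(x) + 0.1 * rng.normal(size=500)
    for a, b in [(2.0, 3.0), (-1.5, 0.7)]:
        B1 = rcs_basis(x, n_knots=4).basis
        B2 = rcs_basis(a + b * x, n_knots=4).basis
        D1 = np.column_stack([np.ones(500), B1])
        D2 = np.column_stack([np.ones(500), B2])
        p1 = D1 @ np.linalg.lstsq(D1, y, rcond=None)[0]
        p2 = D2 @ np.linalg.lstsq(D2, y, rcond=None)[0]
        np.testing.assert_allclose(p1, p2, atol=1e-8)


def test_rcs_rejects_bad_knots():
    with pytest.raises(InputError):
        rcs_basis(np.arange(10.0), knots=np.array([1.0, 1.0, 2.0]))
    with pytest.raises(InputError):
        rcs_basis(np.arange(10.0), n_knots=7)


# ----------------------------------------------------------------------
# Cochran-Armitage trend
# ----------------------------------------------------------------------

def test_trend_null_when_proportions_equal():
    z, p = cochran_armitage_trend([10, 20, 30], [90, 180, 270])
    assert z == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_trend_two_groups_equals_chisquare():
    table = np.array([[15, 85], [40, 60]])
    z, _ = cochran_armitage_trend(table[:, 0], table[:, 1])
    chi2 = sps.chi2_contingency(table, correction=False).statistic
    assert z**2 == pytest.approx(chi2, abs=1e-10)


def test_trend_sign_convention_and_errors():
    z, p = cochran_armitage_trend([5, 15, 40], [95, 85, 60])
    assert z > 0 and p < 1e-6
    with pytest.raises(InputError):
        cochran_armitage_trend([0, 0], [0, 10])
    with pytest.raises(InputError):
        cochran_armitage_trend([5], [95])


# ----------------------------------------------------------------------
# RERI / AP
# ----------------------------------------------------------------------

def _fake_fit(or_g, or_l, or_gl, var=1e-4):
    terms = ["g_only", "l_only", "g_and_l"]
    coef = np.log([or_g, or_l, or_gl])
    return RegressionFit(
        terms=terms, coef=coef, cov=np.eye(3) * var,
        effect_scale="odds-ratio", n_used=1000, converged=True,
    )


def test_reri_ap_formula_arithmetic():
    est = reri_ap(_fake_fit(1.5, 1.5, 2.5), "g_only", "l_only", "g_and_l")
    assert est.reri == pytest.approx(0.5, abs=1e-12)
    assert est.ap == pytest.approx(0.2, abs=1e-12)


def test_reri_ap_null():
    est = reri_ap(_fake_fit(1.0, 1.0, 1.0), "g_only", "l_only", "g_and_l")
    assert est.reri == pytest.approx(0.0, abs=1e-12)
    assert est.ap == pytest.approx(0.0, abs=1e-12)


def test_ap_equals_reri_over_joint_rr():
    est = reri_ap(_fake_fit(1.3, 0.8, 2.1), "g_only", "l_only", "g_and_l")
    assert est.ap == pytest.approx(est.reri / 2.1, abs=1e-10)
    assert est.ap <= 1.0


def test_reri_saturated_model_matches_contingency_closed_form():
    # counts for the 2x2x2 table: (G, L) -> (cases, controls)
    counts = {
        (0, 0): (30, 970),
        (1, 0): (55, 945),
        (0, 1): (45, 955),
        (1, 1): (120, 880),
    }
    rows_X, rows_y = [], []
    for (g, l), (a, b) in counts.items():
        for y, k in ((1.0, a), (0.0, b)):
            rows_X.extend([[g * (1 - l), l * (1 - g), g * l]] * k)
            rows_y.extend([y] * k)
    X = pd.DataFrame(rows_X, columns=["g_only", "l_only", "g_and_l"])
    fit = fit_logistic(X, np.array(rows_y))
    est = reri_ap(fit, "g_only", "l_only", "g_and_l")

    def odds(c):
        a, b = counts[c]
        return a / b

    or10 = odds((1, 0)) / odds((0, 0))
    or01 = odds((0, 1)) / odds((0, 0))
    or11 = odds((1, 1)) / odds((0, 0))
    assert est.reri == pytest.approx(or11 - or10 - or01 + 1, abs=1e-8)
    assert est.ap == pytest.approx((or11 - or10 - or01 + 1) / or11, abs=1e-8)


def test_reri_bootstrap_ci_close_to_delta():
    fit = _fake_fit(1.4, 1.2, 2.0, var=1e-3)
    delta = reri_ap(fit, "g_only", "l_only", "g_and_l", method="delta")
    boot = reri_ap(fit, "g_only", "l_only", "g_and_l", method="bootstrap", seed=5)
    assert boot.reri_ci[0] == pytest.approx(delta.reri_ci[0], abs=0.05)
    assert boot.reri_ci[1] == pytest.approx(delta.reri_ci[1], abs=0.05)


# ----------------------------------------------------------------------
# SNP x lifestyle scan
# ----------------------------------------------------------------------

def test_scan_returns_one_row_per_variant_sorted_by_p():
    rng = np.random.default_rng(24)
    n, m = 800, 12
    panel = make_panel(rng.binomial(2, 0.3, size=(n, m)).astype(float))
    L = rng.binomial(1, 0.3, n).astype(float)
    y = (rng.random(n) < 0.2).astype(float)
    out = snp_lifestyle_scan(panel, L, y)
    assert len(out) == m
    p = out["p"].dropna().to_numpy()
    assert (np.diff(p) >= 0).all()


def test_scan_flags_degenerate_designs_instead_of_crashing():
    rng = np.random.default_rng(25)
    n = 300
    panel = make_panel(rng.binomial(2, 0.3, size=(n, 2)).astype(float))
    L = np.zeros(n)  # product term aliased with zero column
    y = (rng.random(n) < 0.3).astype(float)
    out = snp_lifestyle_scan(panel, L, y)
    assert len(out) == 2
    assert out["p"].isna().all()
    assert (~out["converged"]).all()


def test_scan_null_interaction_p_uniform():
    rng = np.random.default_rng(26)
    n, m = 1500, 60
    panel = make_panel(rng.binomial(2, 0.3, size=(n, m)).astype(float))
    L = rng.binomial(1, 0.4, n).astype(float)
    # outcome depends on main effects only — product terms are null
    eta = -2.0 + 0.3 * L
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    out = snp_lifestyle_scan(panel, L, y)
    ks = sps.kstest(out["p"].dropna(), "uniform")
    assert ks.pvalue > 0.01
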