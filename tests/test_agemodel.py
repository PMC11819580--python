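import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pedmut import agemodel
from pedmut.agemodel import (
    AgeModelFit,
    FitError,
    build_design,
    effect_per_year,
    fit_identity_poisson,
    fit_intercept_only,
    fit_phased_regression,
    fit_total_regression,
    lrt_pvalue,
    predict_fig2_lines,
    solve_equal_age_alpha,
)
from pedmut.datasets import aye_aye_trios
from pedmut.simulate import simulate_count_cohort


def nelder_mead_ml(y, X, n_starts=40, seed=0):
    """Independent brute-force likelihood maximisation (derivative-free)."""
    rng = np.random.default_rng(seed)
    scale = np.abs(X).max(axis=0)
    Xs = X / scale

    def nll(b):
        mu = Xs @ b
        if np.any(mu <= 0):
            return 1e12
        return float(np.sum(mu - y * np.log(mu)))

    best = None
    for _ in range(n_starts):
        b0 = rng.uniform(-1, 1, X.shape[1]) * y.mean()
        b0[0] = y.mean()
        res = optimize.minimize(nll, b0, method="Nelder-Mead",
                                options={"maxiter": 50000, "xatol": 1e-13,
                                         "fatol": 1e-13})
        if best is None or res.fun < best.fun:
            best = res
    return best.x / scale


@pytest.fixture(scope="module")
def design():
    return build_design(aye_aye_trios())


def test_total_fit_matches_bruteforce_ml(design):
    """Constrained identity-link ML equals derivative-free maximisation."""
    fit = fit_total_regression(design)
    Lg = design["L"].to_numpy() / 1e9
    X = np.column_stack([
        np.ones(len(design)),
        Lg * design["paternal_age"],
        Lg * design["maternal_age"],
    ])
    y = design["n_mutations"].to_numpy(dtype=float)
    oracle = nelder_mead_ml(y, X) * np.array([1.0, 1e-9, 1e-9])
    assert np.allclose(fit.params, oracle, rtol=1e-4)


def test_phased_fits_match_bruteforce_ml(design):
    for parent in ("paternal", "maternal"):
        fit = fit_phased_regression(design, parent)
        col_n = "n_paternal" if parent == "paternal" else "n_maternal"
        col_age = f"{parent}_age"
        zeta = (design["L"] / 1e9 * design["n_mutations"] * design[col_age]).to_numpy()
        X = np.column_stack([np.ones_like(zeta), zeta])
        y = design[col_n].to_numpy(dtype=float) + 1
        oracle = nelder_mead_ml(y, X, seed=3)
        assert np.allclose(fit.params, oracle, rtol=1e-4)


def test_loglik_not_below_statsmodels_irls(design):
    """Our constrained ML is at least as good as statsmodels' IRLS fit."""
    import warnings

    import statsmodels.api as sm

    Lg = design["L"].to_numpy() / 1e9
    X = np.column_stack([
        np.ones(len(design)),
        Lg * design["paternal_age"],
        Lg * design["maternal_age"],
    ])
    y = design["n_mutations"].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm = sm.GLM(y, X, family=sm.families.Poisson(
            sm.families.links.Identity())).fit(maxiter=500)
    ours = fit_total_regression(design)
    ll_sm = agemodel.poisson_identity_loglik(glm.params, y, X)
    assert ours.loglik >= ll_sm - 1e-6


def test_paternal_age_not_significant_maternal_is(design):
    fp = fit_phased_regression(design, "paternal")
    fm = fit_phased_regression(design, "maternal")
    assert fp.pvalues[1] > 0.05  # no paternal age effect detectable
    assert fm.pvalues[1] < 0.01  # strong maternal age effect
    assert fm.params[1] > 0


def test_total_fit_signs_match_phased_story(design):
    fit = fit_total_regression(design)
    assert fit.params[2] > 0  # maternal
    assert fit.pvalues[2] < 1e-9
    assert fit.pvalues[1] > 0.5  # paternal indistinguishable from zero


def test_effect_per_year_linearity(design):
    fit = fit_total_regression(design)
    e1 = effect_per_year(fit, "maternal", L_ref=2e9)
    e2 = effect_per_year(fit, "maternal", L_ref=4e9)
    assert e2["effect"] == pytest.approx(2 * e1["effect"])
    zero = AgeModelFit("total", ["beta0", "betaP", "betaM"],
                       np.array([10.0, 1e-9, 0.0]), np.eye(3) * 1e-22, 0.0,
                       True, 5, meta={"L_mean": 1e9})
    assert effect_per_year(zero, "maternal")["effect"] == 0.0


def test_degenerate_design_zero_slope():
    df = build_design(pd.DataFrame({
        "child_id": list("abcd"),
        "paternal_age": [10.0] * 4,
        "maternal_age": [10.0] * 4,
        "n_mutations": [20] * 4,
        "n_paternal": [5] * 4,
        "n_maternal": [5] * 4,
        "callable_gb": [1.8] * 4,
    }))
    fit = fit_phased_regression(df, "maternal")
    assert fit.params[1] == 0.0


def test_parameter_recovery_within_3se():
    rng = np.random.default_rng(12)
    L = 3.67e9
    b0, bP, bM = 5.0, 0.3 / L, 4.0 / L
    d = simulate_count_cohort(100, L, b0, bP, bM, rng)
    fit = fit_total_regression(build_design(d))
    k = fit.names.index("betaM")
    assert abs(fit.params[k] - bM) < 3 * fit.bse[k]


def test_null_coefficient_ci_coverage_quick():
    """With beta_parent = 0 and an exogenous covariate, the 95% CI covers zero.

    The trio totals are held fixed so the phased-model covariate
    zeta = L*S*X does not share noise with the response.
    """
    rng = np.random.default_rng(99)
    cover = 0
    n_rep = 60
    for _ in range(n_rep):
        n = 40
        d = build_design(pd.DataFrame({
            "child_id": [f"t{i}" for i in range(n)],
            "paternal_age": rng.uniform(6.7, 30.5, n),
            "maternal_age": rng.uniform(6.7, 30.5, n),
            "n_mutations": np.full(n, 50),
            "n_paternal": rng.poisson(5.0, n),
            "n_maternal": rng.poisson(5.0, n),
            "callable_gb": np.full(n, 1.83),
        }))
        fit = fit_phased_regression(d, "paternal")
        lo, hi = fit.conf_int()[1]
        cover += lo <= 0 <= hi
    assert cover >= int(0.85 * n_rep)


def test_lrt_prefers_intercept_only_under_null():
    rng = np.random.default_rng(5)
    L = 3.67e9
    rejections = 0
    n_rep = 60
    for _ in range(n_rep):
        d = simulate_count_cohort(30, L, 25.0, 0.0, 0.0, rng)
        design = build_design(d)
        full = fit_total_regression(design)
        reduced = fit_intercept_only(design)
        if lrt_pvalue(full, reduced) < 0.05:
            rejections += 1
    # nominal 5% level, allow Monte-Carlo slack
    assert rejections <= int(0.15 * n_rep)


def test_fig2_lines_basics(design):
    fit = fit_phased_regression(design, "maternal", phased_scale="fraction")
    ages = np.array([8.0, 13.0, 18.0, 23.0])
    lines = predict_fig2_lines(fit, ages)
    # prediction at a design point equals the fitted mean there (minus the
    # pseudocount used during fitting)
    mu = fit.params[0] + fit.params[1] * fit.meta["L_mean_gb9"] * fit.meta["S_mean"] * ages
    assert np.allclose(lines["predicted"], mu - 1)
    # bands widen monotonically away from the covariate mean
    width = (lines["hi"] - lines["lo"]).to_numpy()
    centre = np.argmin(np.abs(ages - fit.meta["age_mean"]))
    assert width[0] >= width[centre] and width[-1] >= width[centre]
    # zero-slope fit gives a flat line
    flat = AgeModelFit("phased_maternal", ["beta0", "beta"],
                       np.array([5.0, 0.0]), np.eye(2) * 1e-8, 0.0, True, 12,
                       pseudocount=1.0, phased_scale="fraction",
                       meta={"L_mean_gb9": 3.7, "S_mean": 0.3, "age_mean": 15.0})
    line = predict_fig2_lines(flat, ages)
    assert line["predicted"].nunique() == 1


def test_equal_age_solver_closed_form():
    """Against an analytic root for hand-built linear phased models."""
    # paternal: 2 + 1*zeta, maternal: -1 + 2*zeta with zeta = a (unit scale)
    meta = {"L_mean_gb9": 1.0, "S_mean": 1.0, "age_mean": 10.0}
    fp = AgeModelFit("phased_paternal", ["b0", "b"], np.array([2.0, 1.0]),
                     np.eye(2) * 1e-8, 0.0, True, 10, pseudocount=0.0,
                     phased_scale="fraction", meta=meta)
    fm = AgeModelFit("phased_maternal", ["b0", "b"], np.array([-1.0, 2.0]),
                     np.eye(2) * 1e-8, 0.0, True, 10, pseudocount=0.0,
                     phased_scale="fraction", meta=meta)
    target = 1.5
    # (2 + a) / (-1 + 2a) = 1.5  ->  2 + a = -1.5 + 3a  ->  a = 1.75
    sol = solve_equal_age_alpha(fp, fm, target)
    assert sol.age == pytest.approx(1.75, abs=1e-9)


def test_equal_age_solver_symmetric_flagged():
    meta = {"L_mean_gb9": 1.0, "S_mean": 1.0, "age_mean": 10.0}
    f = AgeModelFit("phased_paternal", ["b0", "b"], np.array([1.0, 1.0]),
                    np.eye(2) * 1e-8, 0.0, True, 10, pseudocount=0.0,
                    phased_scale="fraction", meta=meta)
    sol = solve_equal_age_alpha(f, f, 1.0)
    assert sol.age is not None
    assert any("degenerate" in fl for fl in sol.flags)


def test_equal_age_solver_no_root():
    meta = {"L_mean_gb9": 1.0, "S_mean": 1.0, "age_mean": 10.0}
    fp = AgeModelFit("phased_paternal", ["b0", "b"], np.array([1.0, 1.0]),
                     np.eye(2) * 1e-8, 0.0, True, 10, pseudocount=0.0,
                     phased_scale="fraction", meta=meta)
    fm = AgeModelFit("phased_maternal", ["b0", "b"], np.array([1.0, 1.0]),
                     np.eye(2) * 1e-8, 0.0, True, 10, pseudocount=0.0,
                     phased_scale="fraction", meta=meta)
    sol = solve_equal_age_alpha(fp, fm, 5.0)  # ratio is identically 1
    assert sol.age is None


def test_too_few_trios_raise(design):
    with pytest.raises(FitError):
        fit_phased_regression(design.head(2), "maternal")
    with pytest.raises(FitError):
        fit_total_regression(design.head(3))


def test_collinear_ages_flagged():
    df = build_design(pd.DataFrame({
        "child_id": list("abcde"),
        "paternal_age": [8.0, 12, 16, 20, 24],
        "maternal_age": [8.0, 12, 16, 20, 24],
        "n_mutations": [30, 45, 60, 75, 90],
        "n_paternal": [5, 7, 9, 11, 13],
        "n_maternal": [5, 8, 11, 14, 17],
        "callable_gb": [1.8] * 5,
    }))
    fit = fit_total_regression(df)
    assert any("collinear" in f for f in fit.flags)
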