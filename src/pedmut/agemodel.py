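"""Identity-link Poisson regressions of mutation counts on parental age.

Two model families, both with an *identity* (not log) link so that
coefficients are additive mutation counts:

* phased models — the paternally (or maternally) phased count of trio *i*
  is Poisson with mean ``b0 + b * zeta_i`` where ``zeta_i = L_i * S_i * X_i``
  combines the diploid callable genome size ``L_i``, a per-trio scale
  factor ``S_i`` and the parental age ``X_i``.  ``S_i`` is the trio's
  total mutation count by default (``phased_scale="total"``); the
  fraction of mutations phased is available as an alternative
  (``phased_scale="fraction"``).  A pseudocount (default 1) is added to
  the response to keep the identity-link means positive.

* total model — the trio's total DNM count is Poisson with mean
  ``b0 + bP * L_i * XP_i + bM * L_i * XM_i``.

Fitting is by maximum likelihood with the non-negativity of every fitted
mean enforced by constrained optimisation (the link is never switched).
Standard errors use the expected (Fisher) information; Wald tests are
two-sided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

log = logging.getLogger(__name__)

_MU_FLOOR = 1e-9


class FitError(RuntimeError):
    pass


def build_design(df: pd.DataFrame) -> pd.DataFrame:
    """Attach the diploid callable size L (bp) to a per-trio summary table."""
    out = df.copy()
    out["L"] = 2.0 * out["callable_gb"] * 1e9
    if "n_phased" not in out and {"n_paternal", "n_maternal"} <= set(out.columns):
        out["n_phased"] = out["n_paternal"] + out["n_maternal"]
    if "n_phased" in out:
        out["phased_fraction"] = out["n_phased"] / out["n_mutations"]
    return out


@dataclass
class AgeModelFit:
    model: str
    names: list[str]
    params: np.ndarray  # natural scale (intercept in counts, slopes per covariate unit)
    cov: np.ndarray
    loglik: float
    converged: bool
    n_obs: int
    pseudocount: float = 0.0
    phased_scale: str | None = None
    meta: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * stats.norm.sf(np.abs(z))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = stats.norm.ppf(1 - alpha / 2)
        se = self.bse
        return np.column_stack([self.params - z * se, self.params + z * se])


def poisson_identity_loglik(beta: np.ndarray, y: np.ndarray, X: np.ndarray) -> float:
    mu = X @ beta
    if np.any(mu <= 0):
        return -np.inf
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))


def fit_identity_poisson(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Constrained ML for a Poisson GLM with identity link.

    Covariate columns are rescaled internally to unit magnitude for
    optimiser stability; results are returned on the natural scale.
    Covariance is the inverse expected information.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    col_scale = np.maximum(np.abs(X).max(axis=0), 1e-300)
    Xs = X / col_scale

    def nll(b: np.ndarray) -> float:
        mu = Xs @ b
        if np.any(mu <= 0):
            return np.inf
        return float(np.sum(mu - y * np.log(mu)))

    def grad(b: np.ndarray) -> np.ndarray:
        mu = np.clip(Xs @ b, _MU_FLOOR, None)
        return Xs.T @ (1.0 - y / mu)

    # feasible start: least squares pulled toward the mean if infeasible
    b0, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    if np.any(Xs @ b0 <= 0):
        b_mean = np.zeros(p)
        # put the mean on whichever column is closest to constant
        const_col = int(np.argmin(Xs.std(axis=0)))
        b_mean[const_col] = max(y.mean(), 1.0) / max(Xs[:, const_col].mean(), 1e-12)
        for w in np.linspace(0, 1, 21):
            cand = (1 - w) * b0 + w * b_mean
            if np.all(Xs @ cand > 0):
                b0 = cand
                break
        else:
            b0 = b_mean

    cons = optimize.LinearConstraint(Xs, lb=_MU_FLOOR, ub=np.inf)
    best = None
    for method in ("SLSQP", "trust-constr"):
        try:
            res = optimize.minimize(
                nll,
                b0,
                jac=grad,
                method=method,
                constraints=[cons]
                if method == "trust-constr"
                else [{"type": "ineq", "fun": lambda b: Xs @ b - _MU_FLOOR}],
                options={"maxiter": 2000},
            )
        except Exception:  # pragma: no cover - optimiser edge cases
            continue
        if np.isfinite(res.fun) and (best is None or res.fun < best.fun - 1e-12):
            best = res
        if best is not None and method == "SLSQP" and res.success:
            break
    if best is None:
        raise FitError("identity-link Poisson fit failed")
    beta_s = best.x
    # Newton polish: the optimum is interior whenever all fitted means are
    # positive, so damped Newton steps sharpen SLSQP's loose tolerance
    for _ in range(50):
        mu = Xs @ beta_s
        if np.any(mu <= 0):
            break
        g = Xs.T @ (y / mu - 1.0)
        if np.max(np.abs(g)) < 1e-10:
            break
        H = Xs.T @ (Xs * (y / mu**2)[:, None])
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        t = 1.0
        f0 = nll(beta_s)
        while t > 1e-8:
            cand = beta_s + t * step
            if np.all(Xs @ cand > 0) and nll(cand) <= f0:
                beta_s = cand
                break
            t /= 2
        else:
            break
    mu = np.clip(Xs @ beta_s, _MU_FLOOR, None)
    # expected information on the scaled parameterisation
    info = Xs.T @ (Xs / mu[:, None])
    try:
        cov_s = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov_s = np.linalg.pinv(info)
    beta = beta_s / col_scale
    cov = cov_s / np.outer(col_scale, col_scale)
    ll = poisson_identity_loglik(beta, y, X)
    converged = bool(best.success) and np.all(X @ beta > 0)
    return beta, cov, ll, converged


def _phased_inputs(
    design: pd.DataFrame, parent: str, phased_scale: str
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    col_age = "paternal_age" if parent == "paternal" else "maternal_age"
    col_n = "n_paternal" if parent == "paternal" else "n_maternal"
    d = design.dropna(subset=[col_age]).copy()
    if phased_scale == "total":
        S = d["n_mutations"].to_numpy(dtype=float)
    elif phased_scale == "fraction":
        S = (d["n_phased"] / d["n_mutations"]).to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown phased_scale {phased_scale!r}")
    # internal units: L in 1e9 bp for optimiser stability
    zeta = (d["L"].to_numpy() / 1e9) * S * d[col_age].to_numpy()
    y = d[col_n].to_numpy(dtype=float)
    return y, zeta, d


def fit_phased_regression(
    design: pd.DataFrame,
    parent: str,
    phased_scale: str = "total",
    pseudocount: float = 1.0,
) -> AgeModelFit:
    """Fit the phased-count age model for one parent.

    ``design`` is a :func:`build_design` table.  The response is the
    parent's phased count plus ``pseudocount``.
    """
    if parent not in ("paternal", "maternal"):
        raise ValueError("parent must be 'paternal' or 'maternal'")
    y, zeta, d = _phased_inputs(design, parent, phased_scale)
    if len(y) < 3:
        raise FitError("need at least 3 trios with ages for the phased model")
    X = np.column_stack([np.ones_like(zeta), zeta])
    if np.ptp(zeta) == 0:
        # degenerate design: the covariate carries no information, so the
        # ML solution is the intercept-only fit with zero slope
        mean = float(np.mean(y + pseudocount))
        beta = np.array([mean, 0.0])
        cov = np.array([[mean / len(y), 0.0], [0.0, np.inf]])
        ll = poisson_identity_loglik(beta, y + pseudocount, X)
        conv = True
    else:
        beta, cov, ll, conv = fit_identity_poisson(y + pseudocount, X)
    col_age = "paternal_age" if parent == "paternal" else "maternal_age"
    fit = AgeModelFit(
        model=f"phased_{parent}",
        names=["beta0", f"beta_{parent}"],
        params=beta,
        cov=cov,
        loglik=ll,
        converged=conv,
        n_obs=len(y),
        pseudocount=pseudocount,
        phased_scale=phased_scale,
        meta={
            "L_mean_gb9": float(d["L"].mean() / 1e9),
            "S_mean": float(
                d["n_mutations"].mean()
                if phased_scale == "total"
                else (d["n_phased"] / d["n_mutations"]).mean()
            ),
            "zeta_mean": float(zeta.mean()),
            "age_mean": float(d[col_age].mean()),
        },
    )
    if not conv:
        fit.flags.append("non-convergence or boundary fit")
    return fit


def fit_total_regression(design: pd.DataFrame) -> AgeModelFit:
    """Fit total counts ~ b0 + bP*L*XP + bM*L*XM (identity link).

    Trios missing either age are dropped.  Slope coefficients are
    reported per (bp * year); use :func:`effect_per_year` for the
    mutations-per-year scale.
    """
    d = design.dropna(subset=["paternal_age", "maternal_age"]).copy()
    if len(d) < 4:
        raise FitError("need at least 4 trios with both ages")
    Lg = d["L"].to_numpy() / 1e9
    zp = Lg * d["paternal_age"].to_numpy()
    zm = Lg * d["maternal_age"].to_numpy()
    y = d["n_mutations"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(zp), zp, zm])
    beta, cov, ll, conv = fit_identity_poisson(y, X)
    # back to per-bp units
    scale = np.array([1.0, 1e-9, 1e-9])
    fit = AgeModelFit(
        model="total",
        names=["beta0", "betaP", "betaM"],
        params=beta * scale,
        cov=cov * np.outer(scale, scale),
        loglik=ll,
        converged=conv,
        n_obs=len(d),
        meta={"L_mean": float(d["L"].mean())},
    )
    if np.allclose(d["paternal_age"], d["maternal_age"]):
        fit.flags.append("collinear ages (paternal == maternal)")
    if not conv:
        fit.flags.append("non-convergence or boundary fit")
    return fit


def fit_intercept_only(design: pd.DataFrame) -> AgeModelFit:
    """Intercept-only Poisson fit of total counts (for likelihood-ratio tests)."""
    d = design.dropna(subset=["paternal_age", "maternal_age"])
    y = d["n_mutations"].to_numpy(dtype=float)
    X = np.ones((len(y), 1))
    beta, cov, ll, conv = fit_identity_poisson(y, X)
    return AgeModelFit("intercept_only", ["beta0"], beta, cov, ll, conv, len(y))


def lrt_pvalue(full: AgeModelFit, reduced: AgeModelFit) -> float:
    """Likelihood-ratio test p-value between nested identity-link fits."""
    df = len(full.params) - len(reduced.params)
    lr = 2 * (full.loglik - reduced.loglik)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def effect_per_year(
    fit: AgeModelFit, parent: str, L_ref: float | None = None
) -> dict[str, float]:
    """Age-coefficient effect in mutations per year at reference size ``L_ref``.

    For the total model this is ``beta_parent * L_ref`` with a delta-method
    (here: exact, linear) confidence interval; ``L_ref`` defaults to the
    cohort mean diploid callable size used in the fit.
    """
    if fit.model != "total":
        raise ValueError("effect_per_year applies to the total-count model")
    if L_ref is None:
        L_ref = fit.meta["L_mean"]
    k = fit.names.index("betaP" if parent == "paternal" else "betaM")
    eff = fit.params[k] * L_ref
    se = fit.bse[k] * L_ref
    z = stats.norm.ppf(0.975)
    return {
        "effect": float(eff),
        "se": float(se),
        "ci_low": float(eff - z * se),
        "ci_high": float(eff + z * se),
        "L_ref": float(L_ref),
    }


def predict_phased(
    fit: AgeModelFit, age: np.ndarray | float, total_at_age=None
) -> np.ndarray:
    """Predicted phased count (pseudocount included) at the given age(s).

    The covariate is rebuilt at the cohort-mean L and the model's scale
    factor: for ``phased_scale="total"`` the per-trio total is taken from
    ``total_at_age`` (a callable age -> expected total count) or, when
    absent, the cohort-mean total; for ``"fraction"`` the cohort-mean
    phased fraction is used.
    """
    age = np.asarray(age, dtype=float)
    Lg = fit.meta["L_mean_gb9"]
    if fit.phased_scale == "total" and total_at_age is not None:
        S = np.asarray(total_at_age(age), dtype=float)
    else:
        S = fit.meta["S_mean"]
    zeta = Lg * S * age
    return fit.params[0] + fit.params[1] * zeta


def predict_fig2_lines(
    fit: AgeModelFit, ages: np.ndarray, total_at_age=None
) -> pd.DataFrame:
    """Regression line and pointwise 95% band on the phased-count scale.

    The pseudocount used during fitting is subtracted so the line is on
    the observed-count scale.
    """
    ages = np.asarray(ages, dtype=float)
    Lg = fit.meta["L_mean_gb9"]
    if fit.phased_scale == "total" and total_at_age is not None:
        S = np.asarray(total_at_age(ages), dtype=float)
    else:
        S = np.full_like(ages, fit.meta["S_mean"])
    zeta = Lg * S * ages
    X = np.column_stack([np.ones_like(zeta), zeta])
    mu = X @ fit.params
    var = np.einsum("ij,jk,ik->i", X, fit.cov, X)
    se = np.sqrt(np.maximum(var, 0))
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "age": ages,
            "predicted": mu - fit.pseudocount,
            "lo": mu - fit.pseudocount - z * se,
            "hi": mu - fit.pseudocount + z * se,
        }
    )


@dataclass
class EqualAgeSolution:
    age: float | None
    target_alpha: float
    flags: list[str] = field(default_factory=list)


def solve_equal_age_alpha(
    fit_pat: AgeModelFit,
    fit_mat: AgeModelFit,
    target_alpha: float,
    total_fit: AgeModelFit | None = None,
    age_range: tuple[float, float] = (0.0, 50.0),
) -> EqualAgeSolution:
    """Equal-sex age at which predicted paternal/maternal mutations = target.

    Both parents are assumed to be the same age ``a``.  Predicted phased
    counts come from the two phased fits with the covariate rebuilt at
    the cohort-mean callable size; under the default ``phased_scale=
    "total"`` the per-trio total entering the covariate is itself
    predicted from the total-count model at equal ages, keeping the
    construction self-consistent.  Fitting pseudocounts are subtracted
    before taking the ratio, and roots are searched on the branch where
    both predicted counts are positive.
    """
    if target_alpha <= 0:
        raise ValueError("target_alpha must be positive")
    flags: list[str] = []
    if fit_pat.phased_scale == "total" or fit_mat.phased_scale == "total":
        if total_fit is None:
            raise ValueError("total_fit required when phased_scale='total'")
        L = total_fit.meta["L_mean"]

        def total_at_age(a):
            b0, bP, bM = total_fit.params
            return b0 + (bP + bM) * L * np.asarray(a, dtype=float)

    else:
        total_at_age = None

    def counts(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p = predict_phased(fit_pat, a, total_at_age) - fit_pat.pseudocount
        m = predict_phased(fit_mat, a, total_at_age) - fit_mat.pseudocount
        return p, m

    lo = max(age_range[0], 1e-6)
    grid = np.linspace(lo, age_range[1], 4000)
    p, m = counts(grid)
    valid = (p > 0) & (m > 0)
    f = np.where(valid, p / np.where(m > 0, m, np.nan) - target_alpha, np.nan)

    if np.allclose(fit_pat.params, fit_mat.params) and abs(target_alpha - 1) < 1e-12:
        idx = np.flatnonzero(valid)
        age = float(grid[idx[0]]) if len(idx) else None
        return EqualAgeSolution(age, target_alpha, ["degenerate: ratio is 1 at all ages"])

    roots = []
    for i in range(len(grid) - 1):
        if not (valid[i] and valid[i + 1]):
            continue
        if np.isnan(f[i]) or np.isnan(f[i + 1]):
            continue
        if f[i] == 0:
            roots.append(float(grid[i]))
        elif f[i] * f[i + 1] < 0:
            r = optimize.brentq(
                lambda a: counts(np.array([a]))[0][0] / counts(np.array([a]))[1][0]
                - target_alpha,
                grid[i],
                grid[i + 1],
            )
            roots.append(float(r))
    if not roots:
        return EqualAgeSolution(None, target_alpha, ["no root in range"])
    if len(roots) > 1:
        flags.append(f"multiple roots: {[round(r, 3) for r in roots]}; largest reported")
    return EqualAgeSolution(roots[-1], target_alpha, flags)
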