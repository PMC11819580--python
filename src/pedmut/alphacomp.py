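"""Long-term sex-biased mutation from X versus autosome substitution rates.

Because the X chromosome spends two thirds of its time in females and
autosomes half, the ratio of X to autosomal branch lengths reflects the
male-to-female mutation rate ratio alpha:

    alpha = (4 - 3*(X/A)) / (3*(X/A) - 2)

Male-biased mutation gives X/A below 1 and alpha above 1; the ratio is
only informative on (2/3, 4/3), the all-male and all-female limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

X_OVER_A_MIN, X_OVER_A_MAX = 2.0 / 3.0, 4.0 / 3.0


def alpha_from_branch_lengths(x_len: float, a_len: float) -> float:
    """Male-to-female rate ratio from X and autosomal branch lengths.

    Returns ``inf`` at or below the all-male limit X/A = 2/3 and ``nan``
    at or beyond the all-female limit X/A = 4/3 (where the formula turns
    negative), with a warning in both cases.
    """
    if a_len <= 0:
        raise ValueError("autosomal branch length must be positive")
    r = x_len / a_len
    if r <= X_OVER_A_MIN:
        log.warning("X/A = %.4f at or below 2/3: alpha unbounded (all-male limit)", r)
        return float("inf")
    if r > X_OVER_A_MAX:
        log.warning("X/A = %.4f beyond 4/3: alpha undefined (negative)", r)
        return float("nan")
    return (4 - 3 * r) / (3 * r - 2)


def x_over_a_from_alpha(alpha: float) -> float:
    """Inverse map: expected X/A branch-length ratio for a given alpha."""
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    return (4 + 2 * alpha) / (3 + 3 * alpha)


@dataclass
class AlphaEstimate:
    branch: str
    alpha: float
    x_over_a: float
    ci_low: float
    ci_high: float
    n_autosomes: int
    excluded: list[str] = field(default_factory=list)


def alpha_with_ci(
    table: pd.DataFrame,
    branch: str | None = None,
    ci_method: str = "t",
) -> AlphaEstimate:
    """Point estimate and 95% CI of alpha from a branch-length table.

    Columns: branch, chromosome, is_X, branch_length.  The point estimate
    uses the mean autosomal length; the CI comes from per-autosome alpha
    values (chromosomes whose X/A falls outside the valid interval are
    excluded and logged).  ``ci_method`` is Student-t (default) or "z".
    """
    df = table if branch is None else table[table["branch"] == branch]
    if branch is None:
        branch = str(df["branch"].iloc[0]) if "branch" in df and len(df) else "all"
    x_rows = df[df["is_X"]]
    if len(x_rows) != 1:
        raise ValueError(f"expected exactly one X entry for branch {branch!r}")
    x_len = float(x_rows["branch_length"].iloc[0])
    autos = df[~df["is_X"]]
    if len(autos) < 3:
        raise ValueError("need at least 3 autosomes")
    per_chrom = []
    excluded = []
    for r in autos.itertuples(index=False):
        ratio = x_len / r.branch_length if r.branch_length > 0 else np.inf
        if not (X_OVER_A_MIN < ratio < X_OVER_A_MAX):
            excluded.append(str(r.chromosome))
            continue
        per_chrom.append(alpha_from_branch_lengths(x_len, float(r.branch_length)))
    if excluded:
        log.info("excluded %d chromosome(s) with X/A outside (2/3, 4/3): %s",
                 len(excluded), excluded)
    if len(per_chrom) < 3:
        raise ValueError("fewer than 3 autosomes with valid X/A ratios")
    kept = autos[~autos["chromosome"].astype(str).isin(excluded)]
    a_mean = float(kept["branch_length"].mean())
    point = alpha_from_branch_lengths(x_len, a_mean)
    vals = np.array(per_chrom)
    se = vals.std(ddof=1) / np.sqrt(len(vals))
    if ci_method == "t":
        crit = stats.t.ppf(0.975, len(vals) - 1)
    else:
        crit = stats.norm.ppf(0.975)
    mean_alpha = vals.mean()
    return AlphaEstimate(
        branch=branch,
        alpha=point,
        x_over_a=x_len / a_mean,
        ci_low=float(mean_alpha - crit * se),
        ci_high=float(mean_alpha + crit * se),
        n_autosomes=len(vals),
        excluded=excluded,
    )


def read_branch_lengths(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["is_X"] = df["is_X"].astype(bool)
    return df


def reconcile_with_pedigree(
    alpha_phylo: float,
    solver_result,
    pedigree_alpha_all: float,
    pedigree_alpha_no_outliers: float | None = None,
    phylo_ci: tuple[float, float] | None = None,
) -> dict:
    """Report comparing the phylogenetic alpha with pedigree-based estimates.

    Wraps the equal-age solver output and states whether the pedigree
    ratio (optionally excluding flagged offspring) lies inside the
    phylogenetic confidence interval.
    """
    report = {
        "alpha_phylo": alpha_phylo,
        "implied_equal_sex_age": solver_result.age,
        "solver_flags": list(solver_result.flags),
        "pedigree_alpha": pedigree_alpha_all,
    }
    if pedigree_alpha_no_outliers is not None:
        report["pedigree_alpha_no_outliers"] = pedigree_alpha_no_outliers
        if phylo_ci is not None:
            lo, hi = phylo_ci
            report["no_outlier_alpha_inside_phylo_ci"] = bool(
                lo <= pedigree_alpha_no_outliers <= hi
            )
    return report
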