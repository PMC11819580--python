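"""Sex-specific parental-age effects via identity-link Poisson regression.

Fits the total-count model (DNMs ~ b0 + bP*L*ageP + bM*L*ageM) and the
two phased-count models to the 12 aye-aye trios, reports the per-year
age effects with Wald tests, and solves for the equal-sex parental age
at which the fitted models would reproduce the phylogenetic
male-to-female ratio of 3.1.
"""

from pedmut.agemodel import (
    build_design,
    effect_per_year,
    fit_phased_regression,
    fit_total_regression,
    solve_equal_age_alpha,
)
from pedmut.datasets import PHYLO_ALPHA_AYE_AYE, aye_aye_trios

design = build_design(aye_aye_trios())

total = fit_total_regression(design)
for parent in ("maternal", "paternal"):
    eff = effect_per_year(total, parent)
    k = total.names.index("betaM" if parent == "maternal" else "betaP")
    print(
        f"{parent} age effect: {eff['effect']:+.2f} mutations/year "
        f"(95% CI {eff['ci_low']:.2f} to {eff['ci_high']:.2f}; "
        f"Wald P = {total.pvalues[k]:.2g})"
    )

fit_pat = fit_phased_regression(design, "paternal")
fit_mat = fit_phased_regression(design, "maternal")
print(f"phased-count models: paternal age P = {fit_pat.pvalues[1]:.2f}, "
      f"maternal age P = {fit_mat.pvalues[1]:.2g}")

sol = solve_equal_age_alpha(fit_pat, fit_mat, PHYLO_ALPHA_AYE_AYE, total_fit=total)
print(f"equal-sex age where predicted paternal/maternal = "
      f"{PHYLO_ALPHA_AYE_AYE}: {sol.age:.2f} years")
print("only a young cohort would show the long-term male bias; the sampled "
      "parents (mean 15.4 y) sit in the female-biased regime")
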