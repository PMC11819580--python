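"""Cohort rates and phasing summaries from the published per-trio tables.

Loads the 12-trio aye-aye and 21-trio baboon summary tables bundled with
the package, recomputes each trio's per-generation mutation rate from its
DNM count and callable genome size, and pools the read-backed phasing
outcomes into the male-to-female mutation ratio (alpha).
"""

import pandas as pd

from pedmut.datasets import FEMALE_BIAS_OUTLIER_CHILDREN, aye_aye_trios, baboon_trios
from pedmut.pedigree import Trio
from pedmut.phasing import counts_from_summary_table, pedigree_alpha
from pedmut.rates import cohort_summary, rates_from_summary_table

for name, table in [("aye-aye", aye_aye_trios()), ("baboon", baboon_trios())]:
    results = rates_from_summary_table(table)
    trios = [
        Trio(r.child_id, "f", "m",
             None if pd.isna(r.paternal_age) else r.paternal_age,
             None if pd.isna(r.maternal_age) else r.maternal_age)
        for r in table.itertuples(index=False)
    ]
    s = cohort_summary(results, trios)
    counts = counts_from_summary_table(table)
    phased = sum(c.n_phased for c in counts)
    total = sum(c.total for c in counts)
    print(f"{name}: {s['n_trios']} trios")
    print(f"  mean mutation rate  {s['mean_rate']:.2e} per bp per generation")
    print(f"  mean parental age   {s['mean_parental_age']:.1f} years")
    print(f"  phased              {phased}/{total} ({100 * phased / total:.1f}%)")
    print(f"  pedigree alpha      {pedigree_alpha(counts):.2f} (paternal/maternal)")

aye = counts_from_summary_table(aye_aye_trios())
excl = pedigree_alpha(aye, exclude=FEMALE_BIAS_OUTLIER_CHILDREN)
print(f"aye-aye alpha excluding the three offspring of the two oldest mothers: {excl:.2f}")
print("an alpha near 1 (or below) indicates the loss of the usual male mutation bias")
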