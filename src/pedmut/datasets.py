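"""Published per-trio summary tables used as in-package fixtures.

Two captive primate cohorts: 12 aye-aye (*Daubentonia madagascariensis*)
trios and 21 olive baboon (*Papio anubis*) trios.  Each row carries the
parental ages at conception (years), the autosomal de novo mutation (DNM)
count, the read-backed phasing outcome, and the haploid callable genome
size in units of 1e9 bp.  The per-generation mutation rate for a trio is
``n_mutations / (2 * callable_gb * 1e9)``.

These tables are the inputs for the statistics that need only per-trio
summaries: cohort rates, phased fractions, the pedigree male-to-female
ratio (alpha), and the identity-link parental-age Poisson regressions.
"""

from __future__ import annotations

import io

import pandas as pd

_AYE_AYE = """\
child_id\tpaternal_age\tmaternal_age\tn_mutations\tn_phased\tn_paternal\tn_maternal\tcallable_gb
100947\t22.0\t18.0\t117\t30\t7\t23\t1.67
100938\t30.5\t13.7\t48\t10\t9\t1\t1.78
100950\t16.8\t14.8\t25\t12\t9\t3\t1.86
100940\t9.3\t7.4\t30\t12\t7\t5\t1.86
100942\t17.5\t15.6\t30\t11\t11\t0\t1.85
100939\t11.3\t9.4\t25\t10\t9\t1\t1.87
100935\t8.5\t10.5\t44\t15\t9\t6\t1.86
100933\t24.4\t26.5\t108\t39\t16\t23\t1.86
100945\t15.6\t17.7\t83\t27\t11\t16\t1.87
100944\t12.1\t14.1\t75\t18\t10\t8\t1.83
100941\t20.7\t9.6\t36\t12\t11\t1\t1.81
100946\t17.7\t6.7\t26\t7\t4\t3\t1.87
"""

_BABOON = """\
child_id\tpaternal_age\tmaternal_age\tn_mutations\tn_phased\tn_paternal\tn_maternal\tmean_depth\tcallable_gb
39990\t5.5\t6.1\t29\t16\t11\t5\t41.3\t2.01
39992\t14.7\t15.4\t22\t14\t13\t1\t41.7\t1.99
40001\t9.9\t6.5\t32\t19\t15\t4\t39.6\t1.98
40005\t7.0\t6.9\t18\t12\t8\t4\t40.8\t2.03
16517\t9.5\t6.0\t18\t12\t10\t2\t45.0\t1.62
19181\t12.2\t8.7\t20\t8\t3\t5\t49.9\t1.48
26988\t14.5\t10.9\t31\t13\t12\t1\t47.6\t1.53
28246\t15.5\t11.9\t29\t16\t13\t3\t45.3\t1.64
15444\t8.2\t8.7\t23\t11\t10\t1\t48.2\t1.70
16413\t9.4\t9.9\t13\t7\t6\t1\t48.4\t1.71
17199\t10.4\t11.0\t24\t10\t10\t0\t49.0\t1.69
18385\t11.3\t11.8\t26\t17\t14\t3\t53.6\t1.64
19348\t12.5\t13.0\t11\t5\t5\t0\t50.2\t1.72
7267\t7.9\t\t35\t19\t10\t9\t48.3\t1.67
8395\t9.5\t\t17\t11\t9\t2\t30.7\t1.41
7311\t8.0\t5.3\t18\t10\t7\t3\t30.4\t1.49
10173\t\t12.9\t23\t16\t15\t1\t41.8\t1.50
11885\t15.2\t7.2\t33\t10\t7\t3\t55.9\t1.65
14068\t18.6\t10.7\t39\t13\t12\t1\t44.8\t2.00
14012\t18.5\t9.0\t24\t7\t6\t1\t30.9\t1.56
13951\t18.4\t10.4\t34\t10\t9\t1\t29.1\t1.29
"""


def aye_aye_trios() -> pd.DataFrame:
    """The 12-trio aye-aye cohort summary table."""
    return pd.read_csv(io.StringIO(_AYE_AYE), sep="\t", dtype={"child_id": str})


def baboon_trios() -> pd.DataFrame:
    """The 21-trio olive baboon cohort summary table (ages may be missing)."""
    return pd.read_csv(io.StringIO(_BABOON), sep="\t", dtype={"child_id": str})


#: Offspring whose maternally phased counts drive the cohort female bias:
#: the three children born to the two oldest mothers.
FEMALE_BIAS_OUTLIER_CHILDREN = ("100947", "100933", "100945")

#: 2x2 count tables for the APOBEC-signature enrichment checks, columns are
#: the two groups being compared, rows are (TpC>TpT, other C>T).
#: Maternally vs paternally phased mutations (non-CpG C>T denominator):
APOBEC_BY_PARENT = ((9, 5), (33, 35))
#: Old (>15 y) vs young (<15 y) mothers, maternally phased C>T mutations:
APOBEC_BY_MATERNAL_AGE = ((8, 1), (28, 5))

#: Transmission of detected DNMs to the third generation:
#: (transmitted, assessable) pooled over five trios, and for child 100947.
TRANSMISSION_COHORT = (160, 327)
TRANSMISSION_100947 = (53, 117)

#: Phylogenetic male-to-female substitution rate ratio for the aye-aye
#: branch, with the half-width of its 95% confidence interval.
PHYLO_ALPHA_AYE_AYE = 3.1
PHYLO_ALPHA_AYE_AYE_CI_HALFWIDTH = 0.41
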