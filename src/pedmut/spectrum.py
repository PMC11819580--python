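"""Mutation-spectrum classification and cohort statistical tests.

Single-base substitutions are collapsed to the six pyrimidine-context
types (C>A, C>G, C>T, T>A, T>C, T>G).  CpG status (a C followed by G on
the pyrimidine strand) and the APOBEC-associated TpC context (a C
preceded by T) are read from the trinucleotide context centred on the
mutated base.  Cohort tests: Fisher's exact test on 2x2 tables with the
unconditional sample odds ratio (ad/bc), the exact two-sided binomial
transmission test against the 50% germline expectation, a chi-square /
Monte-Carlo homogeneity test between mutation spectra, and a
genotype-based coefficient of relatedness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SPECTRUM_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = {"C>T", "T>C"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def classify_mutation(ref: str, alt: str, context: str) -> dict:
    """Classify a SNV given its reference-strand trinucleotide context.

    The context must be centred on the mutated base; purine-reference
    mutations are collapsed onto the pyrimidine strand.
    """
    ref, alt, context = ref.upper(), alt.upper(), context.upper()
    if len(context) != 3 or context[1] != ref:
        raise ValueError(f"context {context!r} does not match ref {ref!r}")
    if ref == alt or ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":  # collapse to pyrimidine strand
        context = revcomp(context)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    mut_type = f"{ref}>{alt}"
    return {
        "type": mut_type,
        "is_transition": mut_type in TRANSITIONS,
        "is_cpg": ref == "C" and context[2] == "G",
        "is_tpc": ref == "C" and context[0] == "T",
    }


@dataclass
class SpectrumCounts:
    counts: dict[str, int] = field(default_factory=lambda: {t: 0 for t in SPECTRUM_TYPES})
    cpg_ct: int = 0
    tpc_tt: int = 0

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        return np.array([self.counts[t] for t in SPECTRUM_TYPES], dtype=float)


def spectrum_summary(mutations: pd.DataFrame) -> dict:
    """Counts, Ti:Tv and CpG fraction for mutations with a ``context`` column."""
    sc = SpectrumCounts()
    for row in mutations.itertuples(index=False):
        cls = classify_mutation(row.ref, row.alt, row.context)
        sc.counts[cls["type"]] += 1
        if cls["is_cpg"] and cls["type"] == "C>T":
            sc.cpg_ct += 1
        if cls["is_tpc"] and cls["type"] == "C>T":
            sc.tpc_tt += 1
    ti = sum(sc.counts[t] for t in SPECTRUM_TYPES if t in TRANSITIONS)
    tv = sc.total - ti
    titv = ti / tv if tv else (float("inf") if ti else float("nan"))
    if sc.total == 0:
        log.warning("empty mutation list: ratios undefined")
    return {
        "spectrum": sc,
        "titv": titv,
        "cpg_fraction": sc.cpg_ct / sc.total if sc.total else float("nan"),
    }


@dataclass
class FisherResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    oddsratio: float  # unconditional sample OR, ad/bc
    pvalue: float
    conditional_or: float  # conditional MLE, for reference


def fisher_2x2(table) -> FisherResult:
    """Two-sided Fisher's exact test with the sample odds ratio ad/bc."""
    (a, b), (c, d) = table
    res = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        sample_or = float("inf") if a * d > 0 else (0.0 if (a == 0 or d == 0) else float("nan"))
    else:
        sample_or = (a * d) / (b * c)
    cond = stats.contingency.odds_ratio([[a, b], [c, d]]).statistic
    return FisherResult(((a, b), (c, d)), float(sample_or), float(res.pvalue), float(cond))


def tpc_enrichment_tests(
    mutations: pd.DataFrame,
    maternal_ages: pd.Series | dict,
    age_split: float = 15.0,
    overlapping: bool = True,
) -> dict[str, FisherResult]:
    """APOBEC-signature (TpC>TpT) enrichment among phased C>T mutations.

    Test 1 compares TpC>TpT counts between maternally and paternally
    phased mutations against all parent-assigned non-CpG C>T mutations.
    Test 2 compares, among maternally phased mutations, TpC>TpT counts of
    old (> split) versus young (< split) mothers against all maternal C>T
    mutations.  With ``overlapping=True`` the comparison rows are exactly
    the published layout (the signature subset versus the full C>T
    class); ``overlapping=False`` removes the signature counts from the
    comparison row.
    """
    ages = pd.Series(maternal_ages)
    rows = []
    for r in mutations.itertuples(index=False):
        cls = classify_mutation(r.ref, r.alt, r.context)
        rows.append(
            {
                "phase": r.phase,
                "child_id": r.child_id,
                "type": cls["type"],
                "is_cpg": cls["is_cpg"],
                "is_tpc": cls["is_tpc"],
            }
        )
    df = pd.DataFrame(rows)
    ct = df[(df["type"] == "C>T") & df["phase"].isin(["paternal", "maternal"])]
    tpc = ct[ct["is_tpc"] & ~ct["is_cpg"]]
    base = ct[~ct["is_cpg"]]
    if not overlapping:
        base = base[~base["is_tpc"]]
    t1 = (
        (int((tpc["phase"] == "maternal").sum()), int((tpc["phase"] == "paternal").sum())),
        (int((base["phase"] == "maternal").sum()), int((base["phase"] == "paternal").sum())),
    )

    mat = ct[(ct["phase"] == "maternal") & ~ct["is_cpg"]].copy()
    mat["mat_age"] = mat["child_id"].map(ages)
    mat = mat.dropna(subset=["mat_age"])
    old = mat["mat_age"] > age_split
    young = mat["mat_age"] < age_split
    mat_tpc = mat["is_tpc"]
    base2 = mat if overlapping else mat[~mat_tpc]
    t2 = (
        (int((mat_tpc & old).sum()), int((mat_tpc & young).sum())),
        (int((base2["mat_age"] > age_split).sum()), int((base2["mat_age"] < age_split).sum())),
    )
    return {"by_parent": fisher_2x2(t1), "by_maternal_age": fisher_2x2(t2)}


def transmission_test(k_transmitted: int, n_assessable: int) -> float:
    """Exact two-sided binomial test of k/n against p=0.5.

    Two-sided by summation of outcomes no more likely than the observed
    one (minimum-likelihood method).
    """
    if n_assessable < 1:
        raise ValueError("need at least one assessable mutation")
    if k_transmitted > n_assessable:
        raise ValueError("transmitted exceeds assessable")
    return float(stats.binomtest(k_transmitted, n_assessable, 0.5).pvalue)


def spectrum_comparison(
    groups: list[SpectrumCounts],
    n_permutations: int = 2000,
    rng: np.random.Generator | None = None,
) -> float:
    """Chi-square homogeneity test between six-type spectra.

    Uses the asymptotic chi-square p-value when all expected cells are at
    least 5, otherwise a Monte-Carlo p-value obtained by resampling group
    spectra from the pooled distribution (group totals fixed).
    Zero-total groups are excluded with a warning.
    """
    mats = [g.as_vector() for g in groups if g.total > 0]
    if len(mats) < len(groups):
        log.warning("excluded %d empty spectrum group(s)", len(groups) - len(mats))
    if len(mats) < 2:
        raise ValueError("need at least two non-empty groups")
    obs = np.vstack(mats)
    keep = obs.sum(axis=0) > 0
    obs = obs[:, keep]
    chi2, p, dof, expected = stats.chi2_contingency(obs)
    if (expected >= 5).all():
        return float(p)
    if rng is None:
        rng = np.random.default_rng(0)
    pooled = obs.sum(axis=0)
    probs = pooled / pooled.sum()
    totals = obs.sum(axis=1).astype(int)

    def chi2_stat(o: np.ndarray) -> float:
        e = np.outer(o.sum(axis=1), o.sum(axis=0)) / o.sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            contrib = np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1), 0.0)
        return float(contrib.sum())

    obs_stat = chi2_stat(obs)
    exceed = 1  # add-one correction
    for _ in range(n_permutations):
        sim = np.vstack([rng.multinomial(t, probs) for t in totals]).astype(float)
        if chi2_stat(sim) >= obs_stat - 1e-12:
            exceed += 1
    return exceed / (n_permutations + 1)


def relatedness_cor(gt_a: np.ndarray, gt_b: np.ndarray) -> float:
    """Coefficient of relatedness from genotype dosages at shared sites.

    ``(N_shared_het - 2 * N_IBS0) / min(N_het_a, N_het_b)`` over sites
    where both samples have non-missing calls (dosages 0/1/2, missing
    negative).  Values at or below zero indicate unrelated individuals;
    about 0.5 for parent-child pairs.
    """
    a = np.asarray(gt_a)
    b = np.asarray(gt_b)
    ok = (a >= 0) & (b >= 0)
    a, b = a[ok], b[ok]
    het_a = int((a == 1).sum())
    het_b = int((b == 1).sum())
    if min(het_a, het_b) == 0:
        raise ValueError("a sample has no heterozygous sites: CoR undefined")
    shared_het = int(((a == 1) & (b == 1)).sum())
    ibs0 = int((((a == 0) & (b == 2)) | ((a == 2) & (b == 0))).sum())
    return (shared_het - 2 * ibs0) / min(het_a, het_b)
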