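"""Callability-corrected per-generation mutation-rate estimation.

The rate for trio *i* is

    mu_i = N_mut,i / (2 * sum_x C_i^x)

where the denominator counts "callable sites": the number of haploid
depth-passing sites times the probability C = c_child * c_father *
c_mother that a true DNM genotype configuration would survive the
calling filters in every trio member (independence assumed).

The child-side callability c_child is estimated on high-confidence child
heterozygotes — sites where one parent is homozygous reference and the
other homozygous alternate — as the fraction passing the child-specific
candidate filters (depth window, GQ, caller concordance, strand support,
allelic balance).  Parent-side callabilities are estimated analogously
as the fraction of high-confidence homozygous-reference parental
genotypes passing the parent-specific filters (depth window, GQ, zero
alternate reads).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import FilterConfig
from .genotypes import GenotypeTable, HOMREF, HET, HOMALT
from .pedigree import Trio


class RateError(ValueError):
    pass


@dataclass
class CallabilityEstimate:
    trio_id: str
    c_child: float
    c_father: float
    c_mother: float
    n_filtered: dict[str, int]
    n_all: dict[str, int]
    depth_pass_sites: int | None = None  # haploid bp

    @property
    def product(self) -> float:
        return self.c_child * self.c_father * self.c_mother


@dataclass
class TrioRateResult:
    trio_id: str
    n_mut: int
    callable_sum: float  # haploid callable sites, sum_x C_i^x
    rate: float

    @classmethod
    def from_counts(cls, trio_id: str, n_mut: int, callable_sum: float) -> "TrioRateResult":
        if callable_sum <= 0:
            raise RateError(f"callable_sum must be positive (trio {trio_id})")
        return cls(trio_id, n_mut, callable_sum, n_mut / (2.0 * callable_sum))


def _child_pass(table: GenotypeTable, idx: np.ndarray, j: int, mean_depth: float,
                cfg: FilterConfig) -> np.ndarray:
    dp = table.dp[idx, j]
    gq = table.gq[idx, j]
    fwd, rev = table.alt_fwd[idx, j], table.alt_rev[idx, j]
    ar, aa = table.ad_ref[idx, j], table.ad_alt[idx, j]
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(ar + aa > 0, aa / np.maximum(ar + aa, 1), np.nan)
    return (
        (dp >= cfg.min_depth)
        & (dp <= cfg.max_depth(mean_depth))
        & (gq > cfg.gq_min)
        & table.concordant[idx, j]
        & (fwd >= 1)
        & (rev >= 1)
        & (ab > cfg.ab_min)
    )


def _parent_pass(table: GenotypeTable, idx: np.ndarray, j: int, mean_depth: float,
                 cfg: FilterConfig) -> np.ndarray:
    dp = table.dp[idx, j]
    gq = table.gq[idx, j]
    aa = table.ad_alt[idx, j]
    return (
        (dp >= cfg.min_depth)
        & (dp <= cfg.max_depth(mean_depth))
        & (gq > cfg.gq_min)
        & (aa == 0)
    )


def estimate_callability(
    trio: Trio,
    table: GenotypeTable,
    config: FilterConfig | None = None,
    depth_means: pd.Series | None = None,
    depth_pass_sites: int | None = None,
) -> CallabilityEstimate:
    """Estimate per-member callability from opposite-homozygote parent sites.

    Raises :class:`RateError` when no informative site exists for a member.
    """
    cfg = config or FilterConfig()
    if depth_means is None:
        depth_means = table.mean_depth()
    ic = table.sample_index(trio.child_id)
    fi = table.sample_index(trio.father_id)
    mi = table.sample_index(trio.mother_id)
    gt = table.gt

    # child: one parent hom-ref, the other hom-alt -> child is surely het
    opp = ((gt[:, fi] == HOMREF) & (gt[:, mi] == HOMALT)) | (
        (gt[:, fi] == HOMALT) & (gt[:, mi] == HOMREF)
    )
    child_sites = np.flatnonzero(opp & (gt[:, ic] == HET))
    # father hom-ref with high confidence: mother hom-alt, child het
    father_sites = np.flatnonzero(
        (gt[:, fi] == HOMREF) & (gt[:, mi] == HOMALT) & (gt[:, ic] == HET)
    )
    mother_sites = np.flatnonzero(
        (gt[:, mi] == HOMREF) & (gt[:, fi] == HOMALT) & (gt[:, ic] == HET)
    )
    n_all = {
        "child": len(child_sites),
        "father": len(father_sites),
        "mother": len(mother_sites),
    }
    if min(n_all.values()) == 0:
        raise RateError(
            f"trio {trio.child_id}: no informative opposite-homozygote sites "
            f"for callability ({n_all})"
        )
    cpass = _child_pass(table, child_sites, ic, float(depth_means[trio.child_id]), cfg)
    fpass = _parent_pass(table, father_sites, fi, float(depth_means[trio.father_id]), cfg)
    mpass = _parent_pass(table, mother_sites, mi, float(depth_means[trio.mother_id]), cfg)
    n_filt = {"child": int(cpass.sum()), "father": int(fpass.sum()), "mother": int(mpass.sum())}
    return CallabilityEstimate(
        trio_id=trio.child_id,
        c_child=n_filt["child"] / n_all["child"],
        c_father=n_filt["father"] / n_all["father"],
        c_mother=n_filt["mother"] / n_all["mother"],
        n_filtered=n_filt,
        n_all=n_all,
        depth_pass_sites=depth_pass_sites,
    )


def compute_trio_rate(
    n_mut: int, callable_sum: float, trio_id: str = ""
) -> TrioRateResult:
    """Per-generation rate mu = n_mut / (2 * callable_sum)."""
    return TrioRateResult.from_counts(trio_id, n_mut, callable_sum)


def callable_sum(estimate: CallabilityEstimate) -> float:
    """Haploid callable sites: depth-passing sites times the callability product."""
    if estimate.depth_pass_sites is None:
        raise RateError("depth_pass_sites unknown for this trio")
    return estimate.depth_pass_sites * estimate.product


def cohort_summary(
    results: list[TrioRateResult], trios: list[Trio]
) -> dict[str, float]:
    """Unweighted cohort means: rate, parental ages overall and per sex."""
    if not results:
        raise RateError("no trio results")
    rates = [r.rate for r in results]
    pat = [t.paternal_age for t in trios if t.paternal_age is not None]
    mat = [t.maternal_age for t in trios if t.maternal_age is not None]
    mean_pat = float(np.mean(pat)) if pat else float("nan")
    mean_mat = float(np.mean(mat)) if mat else float("nan")
    return {
        "mean_rate": float(np.mean(rates)),
        "mean_paternal_age": mean_pat,
        "mean_maternal_age": mean_mat,
        "mean_parental_age": float(np.mean([mean_pat, mean_mat])),
        "n_trios": len(results),
    }


def rates_from_summary_table(df: pd.DataFrame) -> list[TrioRateResult]:
    """Per-trio rates from a cohort summary table.

    Expects columns child_id, n_mutations and callable_gb (haploid
    callable sites in units of 1e9 bp).
    """
    return [
        TrioRateResult.from_counts(
            str(r.child_id), int(r.n_mutations), float(r.callable_gb) * 1e9
        )
        for r in df.itertuples(index=False)
    ]
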