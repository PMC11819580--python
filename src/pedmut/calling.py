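"""Trio de novo mutation calling: Mendelian-violation candidates and filters.

A candidate DNM is a site where both parents are called homozygous
reference and the child heterozygous.  Seven per-candidate filters are
then evaluated (each recorded as pass/fail/not_evaluable):

1. read depth between ``min_depth`` and a per-sample maximum in all trio
   members (default maximum: mean + 4*sqrt(mean); a 5x-mean alternative
   is available),
2. genotype quality strictly greater than ``gq_min`` in all members,
3. the child call is heterozygous under both callers (concordance flag),
4. the alternate allele is seen on both strands in the child,
5. no alternate-allele reads in either parent,
6. the alternate allele is absent from every non-sibling cohort sample
   (read-level by default; genotype-level optional),
7. child allelic balance strictly greater than ``ab_min``.

A candidate passes only if the site survived the ABHet prefilter and all
seven filters pass; a filter that cannot be evaluated fails closed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeTable, HOMREF, HET, HOMALT
from .pedigree import Pedigree, Trio

log = logging.getLogger(__name__)

PASS, FAIL, NOT_EVALUABLE = "pass", "fail", "not_evaluable"

FILTER_NAMES = (
    "depth",
    "gq",
    "caller_concordance",
    "strand",
    "parent_alt_reads",
    "cohort_absence",
    "allelic_balance",
)


@dataclass
class FilterConfig:
    min_depth: int = 15
    gq_min: float = 60.0
    ab_min: float = 0.35
    abhet_range: tuple[float, float] = (0.2, 0.8)
    max_depth_mode: str = "sigma4"  # or "fivex"
    cohort_absence_level: str = "read"  # or "genotype"
    mnm_distance: int = 10

    def max_depth(self, mean_depth: float) -> float:
        if self.max_depth_mode == "fivex":
            return 5.0 * mean_depth
        return mean_depth + 4.0 * np.sqrt(mean_depth)


def prefilter_sites(
    table: GenotypeTable, abhet_range: tuple[float, float] = (0.2, 0.8)
) -> tuple[GenotypeTable, pd.Series]:
    """Remove sites whose mean het-sample ABHet = ref/(ref+alt) is extreme.

    Sites with no heterozygous carriers are retained (not evaluable).
    Returns the filtered table and per-site verdicts on the input table.
    """
    lo, hi = abhet_range
    het = table.gt == HET
    ref = np.where(het & (table.ad_ref >= 0), table.ad_ref, 0).astype(float)
    alt = np.where(het & (table.ad_alt >= 0), table.ad_alt, 0).astype(float)
    tot = ref + alt
    valid = het & (table.ad_ref >= 0) & (table.ad_alt >= 0) & (tot > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abhet = np.where(valid, ref / np.where(tot > 0, tot, 1), np.nan)
    n_valid = valid.sum(axis=1)
    mean_abhet = np.where(n_valid > 0, np.nansum(abhet, axis=1) / np.maximum(n_valid, 1), np.nan)
    evaluable = n_valid > 0
    bad = evaluable & ((mean_abhet < lo) | (mean_abhet > hi))
    verdict = pd.Series(
        np.where(~evaluable, NOT_EVALUABLE, np.where(bad, FAIL, PASS)),
        index=table.sites.index,
    )
    n_removed = int(bad.sum())
    if n_removed:
        log.info("ABHet prefilter removed %d of %d sites", n_removed, table.n_sites)
    return table.subset_sites(~bad), verdict


def find_mendelian_violations(
    trio: Trio, table: GenotypeTable, exclude_contigs: set[str] | None = None
) -> pd.DataFrame:
    """Sites with father hom-ref, mother hom-ref and child het.

    Sites with a missing genotype in any trio member are skipped.
    Returns a DataFrame of candidate rows (site index preserved in
    ``site_idx``).
    """
    ic = table.sample_index(trio.child_id)
    fi = table.sample_index(trio.father_id)
    mi = table.sample_index(trio.mother_id)
    mask = (
        (table.gt[:, fi] == HOMREF)
        & (table.gt[:, mi] == HOMREF)
        & (table.gt[:, ic] == HET)
    )
    if exclude_contigs:
        mask &= ~table.sites["contig"].isin(exclude_contigs).to_numpy()
    idx = np.flatnonzero(mask)
    out = table.sites.iloc[idx].copy()
    out["site_idx"] = idx
    out["child_id"] = trio.child_id
    return out.reset_index(drop=True)


def _verdict(ok: np.ndarray, evaluable: np.ndarray) -> np.ndarray:
    out = np.where(ok, PASS, FAIL).astype(object)
    out[~evaluable] = NOT_EVALUABLE
    return out


def apply_dnm_filters(
    candidates: pd.DataFrame,
    table: GenotypeTable,
    trio: Trio,
    depth_means: pd.Series,
    pedigree: Pedigree | None = None,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Evaluate the seven candidate filters; adds per-filter columns and ``passes``.

    ``depth_means`` is the per-sample mean depth used for the maximum-depth
    bound.  Siblings (other children of the same two parents, identified
    through ``pedigree``) are exempt from the cohort-absence filter.
    A not-evaluable filter fails the candidate (fail closed).
    """
    cfg = config or FilterConfig()
    out = candidates.copy()
    if out.empty:
        for name in FILTER_NAMES:
            out[f"filter_{name}"] = pd.Series(dtype=object)
        out["passes"] = pd.Series(dtype=bool)
        return out
    idx = out["site_idx"].to_numpy()
    members = [trio.child_id, trio.father_id, trio.mother_id]
    cols = [table.sample_index(s) for s in members]
    ic, fi, mi = cols

    # 1: depth window in all three members
    ok = np.ones(len(out), dtype=bool)
    evaluable = np.ones(len(out), dtype=bool)
    for j, s in zip(cols, members):
        dp = table.dp[idx, j]
        evaluable &= dp >= 0
        ok &= (dp >= cfg.min_depth) & (dp <= cfg.max_depth(float(depth_means[s])))
    out["filter_depth"] = _verdict(ok, evaluable)

    # 2: GQ strictly > threshold in all three
    gq = table.gq[idx][:, cols]
    evaluable = (gq >= 0).all(axis=1)
    ok = (gq > cfg.gq_min).all(axis=1)
    out["filter_gq"] = _verdict(ok, evaluable)

    # 3: het under both callers in the child
    out["filter_caller_concordance"] = _verdict(
        table.concordant[idx, ic], np.ones(len(out), dtype=bool)
    )

    # 4: alt on both strands in the child
    fwd, rev = table.alt_fwd[idx, ic], table.alt_rev[idx, ic]
    evaluable = (fwd >= 0) & (rev >= 0)
    out["filter_strand"] = _verdict((fwd >= 1) & (rev >= 1), evaluable)

    # 5: zero alt reads in both parents
    pa = table.ad_alt[idx][:, [fi, mi]]
    evaluable = (pa >= 0).all(axis=1)
    out["filter_parent_alt_reads"] = _verdict((pa == 0).all(axis=1), evaluable)

    # 6: alt absent from all cohort samples other than siblings and the
    # child's own descendants (a true DNM is expected in ~half the
    # offspring of its carrier)
    exempt: set[str] = set()
    if pedigree is not None:
        for ind in pedigree.individuals.values():
            if (
                ind.id != trio.child_id
                and ind.father_id == trio.father_id
                and ind.mother_id == trio.mother_id
            ):
                exempt.add(ind.id)
        frontier = {trio.child_id}
        while frontier:
            kids = {
                k.id
                for parent in frontier
                for k in pedigree.children_of(parent)
            } - exempt
            exempt |= kids
            frontier = kids
    others = [
        j
        for j, s in enumerate(table.samples)
        if s not in members and s not in exempt
    ]
    if others:
        gt_o = table.gt[idx][:, others]
        has_alt_gt = (gt_o == HET) | (gt_o == HOMALT)
        if cfg.cohort_absence_level == "read":
            ad_o = table.ad_alt[idx][:, others]
            has_alt = has_alt_gt | (ad_o > 0)
        else:
            has_alt = has_alt_gt
        ok = ~has_alt.any(axis=1)
    else:
        ok = np.ones(len(out), dtype=bool)
    out["filter_cohort_absence"] = _verdict(ok, np.ones(len(out), dtype=bool))

    # 7: child allelic balance strictly > threshold
    ar, aa = table.ad_ref[idx, ic], table.ad_alt[idx, ic]
    evaluable = (ar >= 0) & (aa >= 0) & (ar + aa > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ab = np.where(evaluable, aa / np.maximum(ar + aa, 1), np.nan)
    out["filter_allelic_balance"] = _verdict(ab > cfg.ab_min, evaluable)

    out["passes"] = np.logical_and.reduce(
        [(out[f"filter_{n}"] == PASS).to_numpy() for n in FILTER_NAMES]
    )
    return out


def annotate_mnm_clusters(dnms: pd.DataFrame, distance: int = 10) -> pd.DataFrame:
    """Label SNVs within ``distance`` bp of another DNM of the same child.

    Each constituent SNV remains its own row; members of a cluster share
    an ``mnm_cluster_id``.
    """
    out = dnms.copy()
    out["mnm_cluster_id"] = pd.array([None] * len(out), dtype=object)
    cluster_no = 0
    for (child, contig), grp in out.groupby(["child_id", "contig"], sort=False):
        pos = grp["pos"].sort_values()
        close = pos.diff() <= distance
        cluster: list[int] = []
        prev_idx = None
        for idx_, is_close in zip(pos.index, close):
            if is_close and prev_idx is not None:
                if not cluster:
                    cluster = [prev_idx]
                cluster.append(idx_)
            else:
                if len(cluster) > 1:
                    cluster_no += 1
                    out.loc[cluster, "mnm_cluster_id"] = f"mnm{cluster_no}"
                cluster = []
            prev_idx = idx_
        if len(cluster) > 1:
            cluster_no += 1
            out.loc[cluster, "mnm_cluster_id"] = f"mnm{cluster_no}"
    return out


def annotate_sibling_shared(dnms: pd.DataFrame, pedigree: Pedigree) -> pd.DataFrame:
    """Flag DNMs observed at the same site in two siblings.

    Shared mutations stay in each sibling's list (counted once per
    carrier), both flagged ``shared_with_sibling``.
    """
    out = dnms.copy()
    out["shared_with_sibling"] = False
    for (contig, pos, alt), grp in out.groupby(["contig", "pos", "alt"], sort=False):
        if len(grp) < 2:
            continue
        ids = grp["child_id"].tolist()
        for i in grp.index:
            child = out.loc[i, "child_id"]
            me = pedigree[child]
            for other in ids:
                if other == child:
                    continue
                oth = pedigree[other]
                if oth.father_id == me.father_id and oth.mother_id == me.mother_id:
                    out.loc[i, "shared_with_sibling"] = True
    return out


def call_denovo(
    table: GenotypeTable,
    pedigree: Pedigree,
    trios: list[Trio],
    config: FilterConfig | None = None,
    exclude_contigs: set[str] | None = None,
    depth_means: pd.Series | None = None,
) -> pd.DataFrame:
    """Full calling pipeline over a cohort: prefilter, violations, filters.

    Returns the audit table of all candidates with per-filter verdicts;
    rows with ``passes`` form the mutation table.
    """
    cfg = config or FilterConfig()
    filtered, _ = prefilter_sites(table, cfg.abhet_range)
    if depth_means is None:
        depth_means = filtered.mean_depth()
    frames = []
    for trio in trios:
        cand = find_mendelian_violations(trio, filtered, exclude_contigs)
        frames.append(
            apply_dnm_filters(cand, filtered, trio, depth_means, pedigree, cfg)
        )
    audit = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["child_id", "contig", "pos", "ref", "alt", "passes"])
    )
    called = audit[audit["passes"] == True].reset_index(drop=True)  # noqa: E712
    called = annotate_mnm_clusters(called, cfg.mnm_distance)
    called = annotate_sibling_shared(called, pedigree)
    audit.attrs["called"] = called
    return audit


@dataclass
class ContigQC:
    contig: str
    male_mean_depth: float
    female_mean_depth: float
    male_het: float
    female_het: float
    depth_p: float
    het_p: float
    label: str = "autosomal"


def classify_contigs(
    qc: pd.DataFrame,
    depth_threshold: float = 25.0,
    alpha: float = 0.05,
) -> list[ContigQC]:
    """Label contigs autosomal / x_linked / unfiltered from per-individual QC.

    ``qc`` columns: contig, individual, sex ('male'/'female'), mean_depth,
    heterozygosity.  A contig is X-linked when either read depth or
    heterozygosity differs between the sexes (Welch t-test, P < alpha) and
    male depth is below ``depth_threshold``; significant contigs with high
    male depth are labelled unfiltered.  A single-sex cohort yields all
    autosomal with a warning.
    """
    out: list[ContigQC] = []
    sexes = set(qc["sex"])
    single_sex = len(sexes & {"male", "female"}) < 2
    if single_sex:
        log.warning("single-sex cohort: contig sex checks not possible")
    for contig, grp in qc.groupby("contig", sort=False):
        m = grp[grp["sex"] == "male"]
        f = grp[grp["sex"] == "female"]
        if single_sex or m.empty or f.empty:
            out.append(
                ContigQC(contig, np.nan, np.nan, np.nan, np.nan, 1.0, 1.0, "autosomal")
            )
            continue

        def welch(a: pd.Series, b: pd.Series) -> float:
            if a.nunique() <= 1 and b.nunique() <= 1 and a.iloc[0] == b.iloc[0]:
                return 1.0
            if len(a) < 2 or len(b) < 2:
                return 1.0
            return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

        depth_p = welch(m["mean_depth"], f["mean_depth"])
        het_p = welch(m["heterozygosity"], f["heterozygosity"])
        male_depth = float(m["mean_depth"].mean())
        significant = depth_p < alpha or het_p < alpha
        if significant and male_depth < depth_threshold:
            label = "x_linked"
        elif significant:
            label = "unfiltered"
        else:
            label = "autosomal"
        out.append(
            ContigQC(
                contig,
                male_depth,
                float(f["mean_depth"].mean()),
                float(m["heterozygosity"].mean()),
                float(f["heterozygosity"].mean()),
                depth_p,
                het_p,
                label,
            )
        )
    return out


def assess_transmission(
    dnms: pd.DataFrame, table: GenotypeTable, pedigree: Pedigree
) -> pd.DataFrame:
    """Transmission of each child's DNMs to that child's own offspring.

    A DNM counts as transmitted to a given offspring when that offspring
    carries the alternate allele; it is assessable when the offspring
    genotype at the site is not missing.  Returns per-child counts.
    """
    pos_lookup = {
        (c, p, a): i
        for i, (c, p, a) in enumerate(
            zip(table.sites["contig"], table.sites["pos"], table.sites["alt"])
        )
    }
    rows = []
    for child, grp in dnms.groupby("child_id", sort=False):
        kids = [k.id for k in pedigree.children_of(child) if k.id in table.samples]
        if not kids:
            continue
        transmitted = assessable = 0
        for kid in kids:
            j = table.sample_index(kid)
            for r in grp.itertuples(index=False):
                i = pos_lookup.get((r.contig, r.pos, r.alt))
                if i is None:
                    continue
                gt = table.gt[i, j]
                if gt < 0:
                    continue
                assessable += 1
                if gt in (HET, HOMALT):
                    transmitted += 1
        rows.append({"child_id": child, "transmitted": transmitted, "assessable": assessable})
    return pd.DataFrame(rows, columns=["child_id", "transmitted", "assessable"])
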