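"""Read-backed parent-of-origin assignment of de novo mutations.

A DNM is assigned to a parent by *read tracing*: heterozygous SNPs of the
child within read-pair reach of the DNM whose parental genotypes make the
allele origin unambiguous ("informative sites") are linked to the DNM
through reads or read pairs that carry both the DNM alternate allele and
an informative allele.  Every linking read votes for a parent; only a
unanimous vote with at least ``min_votes`` supporting reads assigns the
DNM, otherwise it stays unphased.  No DNM is ever assigned from genotypes
alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, HOMREF, HET, HOMALT
from .pedigree import Trio

log = logging.getLogger(__name__)

PATERNAL, MATERNAL, UNPHASED = "paternal", "maternal", "unphased"


@dataclass(frozen=True)
class InformativeSite:
    contig: str
    pos: int
    ref: str
    alt: str
    #: parent whose transmitted haplotype carries the REF allele
    ref_parent: str
    #: parent whose transmitted haplotype carries the ALT allele
    alt_parent: str
    distance_to_dnm: int


def find_informative_sites(
    dnm_contig: str,
    dnm_pos: int,
    trio: Trio,
    table: GenotypeTable,
    window: int = 1000,
) -> list[InformativeSite]:
    """Child-het sites within ±window bp whose allele origin is forced.

    The child's two alleles can be attributed to distinct parents when at
    most one parent is heterozygous: with opposite homozygote parents each
    allele has a unique source; with one het parent, the homozygous parent
    pins its own contribution and the other allele is forced to the het
    parent.  Both parents het is ambiguous and skipped.
    """
    ic = table.sample_index(trio.child_id)
    fi = table.sample_index(trio.father_id)
    mi = table.sample_index(trio.mother_id)
    sites = table.sites
    mask = (
        (sites["contig"] == dnm_contig)
        & (sites["pos"] >= dnm_pos - window)
        & (sites["pos"] <= dnm_pos + window)
        & (sites["pos"] != dnm_pos)
    ).to_numpy()
    out: list[InformativeSite] = []
    for i in np.flatnonzero(mask):
        if table.gt[i, ic] != HET:
            continue
        f, m = int(table.gt[i, fi]), int(table.gt[i, mi])
        if f < 0 or m < 0:
            continue
        # determine which parent contributed ref and which contributed alt
        if f == HOMREF and m == HOMALT:
            ref_par, alt_par = PATERNAL, MATERNAL
        elif f == HOMALT and m == HOMREF:
            ref_par, alt_par = MATERNAL, PATERNAL
        elif f == HET and m == HOMREF:
            # mother gave ref; the child's alt must be paternal
            ref_par, alt_par = MATERNAL, PATERNAL
        elif f == HET and m == HOMALT:
            ref_par, alt_par = PATERNAL, MATERNAL
        elif m == HET and f == HOMREF:
            ref_par, alt_par = PATERNAL, MATERNAL
        elif m == HET and f == HOMALT:
            ref_par, alt_par = MATERNAL, PATERNAL
        else:
            continue  # both het (or both same homozygote: Mendelian error)
        out.append(
            InformativeSite(
                contig=dnm_contig,
                pos=int(sites["pos"].iat[i]),
                ref=str(sites["ref"].iat[i]),
                alt=str(sites["alt"].iat[i]),
                ref_parent=ref_par,
                alt_parent=alt_par,
                distance_to_dnm=int(sites["pos"].iat[i] - dnm_pos),
            )
        )
    return out


def phase_dnm(
    dnm: pd.Series | dict,
    evidence: pd.DataFrame,
    sites: list[InformativeSite],
    min_votes: int = 1,
) -> str:
    """Vote-based assignment of one DNM from read evidence.

    ``evidence`` rows are (read_id, contig, pos, allele-base).  Reads (or
    read pairs, sharing a read_id) that carry the DNM alternate allele
    and at least one informative allele vote for a parent.  A unanimous
    vote with >= ``min_votes`` reads assigns that parent; any conflict or
    no vote leaves the DNM unphased.
    """
    contig, pos = dnm["contig"], int(dnm["pos"])
    alt = str(dnm["alt"])
    site_map = {s.pos: s for s in sites}
    ev = evidence[(evidence["contig"] == contig)]
    if ev.empty:
        return UNPHASED
    # reads (pairs share a read_id) that carry the DNM alternate allele
    at_dnm = ev[(ev["pos"] == pos) & (ev["allele"] == alt)]
    if at_dnm.empty:
        return UNPHASED
    carriers = set(at_dnm["read_id"])
    votes: list[str] = []
    for row in ev[ev["read_id"].isin(carriers)].itertuples(index=False):
        if row.pos == pos:
            continue
        s = site_map.get(int(row.pos))
        if s is None:
            continue
        if row.allele == s.alt:
            votes.append(s.alt_parent)
        elif row.allele == s.ref:
            votes.append(s.ref_parent)
        else:
            log.warning("read allele %s matches neither allele at %s:%s",
                        row.allele, contig, row.pos)
    if len(votes) >= min_votes and len(set(votes)) == 1:
        return votes[0]
    return UNPHASED


def phase_mutations(
    dnms: pd.DataFrame,
    table: GenotypeTable,
    trios: list[Trio],
    evidence: pd.DataFrame,
    window: int = 1000,
    min_votes: int = 1,
) -> pd.DataFrame:
    """Phase every DNM row; returns the table with a ``phase`` column."""
    by_child = {t.child_id: t for t in trios}
    ev_by_contig = {c: grp for c, grp in evidence.groupby("contig", sort=False)}
    empty = evidence.iloc[0:0]
    out = dnms.copy()
    phases = []
    for row in out.itertuples(index=False):
        trio = by_child.get(row.child_id)
        if trio is None:
            phases.append(UNPHASED)
            continue
        sites = find_informative_sites(row.contig, int(row.pos), trio, table, window)
        phases.append(phase_dnm({"contig": row.contig, "pos": row.pos, "alt": row.alt},
                                ev_by_contig.get(row.contig, empty), sites, min_votes))
    out["phase"] = phases
    return out


@dataclass
class PhasedCounts:
    trio_id: str
    n_paternal: int
    n_maternal: int
    n_unphased: int

    @property
    def total(self) -> int:
        return self.n_paternal + self.n_maternal + self.n_unphased

    @property
    def n_phased(self) -> int:
        return self.n_paternal + self.n_maternal

    @property
    def fraction_phased(self) -> float:
        return self.n_phased / self.total if self.total else 0.0


def summarize_phasing(dnms: pd.DataFrame) -> tuple[list[PhasedCounts], PhasedCounts]:
    """Per-trio and pooled phased counts from a mutation table with ``phase``."""
    per_trio = []
    for child, grp in dnms.groupby("child_id", sort=False):
        per_trio.append(
            PhasedCounts(
                trio_id=str(child),
                n_paternal=int((grp["phase"] == PATERNAL).sum()),
                n_maternal=int((grp["phase"] == MATERNAL).sum()),
                n_unphased=int((grp["phase"] == UNPHASED).sum()),
            )
        )
    pooled = PhasedCounts(
        trio_id="pooled",
        n_paternal=sum(c.n_paternal for c in per_trio),
        n_maternal=sum(c.n_maternal for c in per_trio),
        n_unphased=sum(c.n_unphased for c in per_trio),
    )
    return per_trio, pooled


def counts_from_summary_table(df: pd.DataFrame) -> list[PhasedCounts]:
    """PhasedCounts from a per-trio summary table.

    Expects columns child_id, n_mutations, n_paternal, n_maternal.
    """
    return [
        PhasedCounts(
            trio_id=str(r.child_id),
            n_paternal=int(r.n_paternal),
            n_maternal=int(r.n_maternal),
            n_unphased=int(r.n_mutations - r.n_paternal - r.n_maternal),
        )
        for r in df.itertuples(index=False)
    ]


def pedigree_alpha(
    counts: list[PhasedCounts], exclude: tuple[str, ...] = ()
) -> float:
    """Male-to-female mutation ratio: pooled paternal / pooled maternal counts."""
    pat = sum(c.n_paternal for c in counts if c.trio_id not in exclude)
    mat = sum(c.n_maternal for c in counts if c.trio_id not in exclude)
    if mat == 0:
        log.warning("zero maternal phased mutations: alpha undefined (infinite)")
        return float("inf")
    return pat / mat


def compare_phasers(a: pd.DataFrame, b: pd.DataFrame) -> dict[str, int]:
    """Concordance report between two phase columns over the same mutations.

    Inputs need columns (child_id, contig, pos, phase).  Reports counts of
    mutations phased by both and concordant, discordant, phased by only
    one of the two.
    """
    key = ["child_id", "contig", "pos"]
    merged = a[key + ["phase"]].merge(b[key + ["phase"]], on=key, suffixes=("_a", "_b"))
    pa = merged["phase_a"] != UNPHASED
    pb = merged["phase_b"] != UNPHASED
    return {
        "n": len(merged),
        "both_phased": int((pa & pb).sum()),
        "concordant": int((pa & pb & (merged["phase_a"] == merged["phase_b"])).sum()),
        "discordant": int((pa & pb & (merged["phase_a"] != merged["phase_b"])).sum()),
        "only_a": int((pa & ~pb).sum()),
        "only_b": int((~pa & pb).sum()),
    }
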