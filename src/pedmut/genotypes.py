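"""Multi-sample genotype table and VCF I/O.

The :class:`GenotypeTable` is the substrate for de novo mutation calling
and callability estimation: per biallelic SNV site and per sample it holds
the called genotype, read depth, genotype quality, allele depths, the
strand split of alternate-allele reads, and whether an independent second
caller agreed on a heterozygous call.

Layout: ``sites`` is a DataFrame (contig, pos, ref, alt) with 1-based VCF
positions; the per-sample fields are dense ``(n_sites, n_samples)`` numpy
arrays.  Missing integer values are encoded as -1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

HOMREF, HET, HOMALT, MISSING = 0, 1, 2, -1

_VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
##FORMAT=<ID=SAC,Number=.,Type=Integer,Description="Strand counts per allele: ref-fwd,ref-rev,alt-fwd,alt-rev">
##FORMAT=<ID=CC,Number=1,Type=Integer,Description="Second-caller concordant heterozygote (1=yes)">
"""

_GT_STRINGS = {HOMREF: "0/0", HET: "0/1", HOMALT: "1/1", MISSING: "./."}


@dataclass
class GenotypeTable:
    samples: list[str]
    sites: pd.DataFrame  # columns: contig, pos, ref, alt
    gt: np.ndarray  # int8, codes above
    dp: np.ndarray  # int32, -1 missing
    gq: np.ndarray
    ad_ref: np.ndarray
    ad_alt: np.ndarray
    alt_fwd: np.ndarray
    alt_rev: np.ndarray
    concordant: np.ndarray  # bool: second caller agrees the call is het
    contigs: dict[str, int] = field(default_factory=dict)  # name -> length

    def __post_init__(self) -> None:
        n = len(self.sites)
        for name in ("gt", "dp", "gq", "ad_ref", "ad_alt", "alt_fwd", "alt_rev", "concordant"):
            arr = getattr(self, name)
            if arr.shape != (n, len(self.samples)):
                raise ValueError(f"{name} has shape {arr.shape}, expected {(n, len(self.samples))}")
        if (np.minimum(self.ad_ref, self.ad_alt) < -1).any():
            raise ValueError("negative allele depths")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def subset_sites(self, mask: np.ndarray) -> "GenotypeTable":
        idx = np.asarray(mask)
        return GenotypeTable(
            samples=list(self.samples),
            sites=self.sites.loc[idx].reset_index(drop=True),
            gt=self.gt[idx],
            dp=self.dp[idx],
            gq=self.gq[idx],
            ad_ref=self.ad_ref[idx],
            ad_alt=self.ad_alt[idx],
            alt_fwd=self.alt_fwd[idx],
            alt_rev=self.alt_rev[idx],
            concordant=self.concordant[idx],
            contigs=dict(self.contigs),
        )

    def mean_depth(self) -> pd.Series:
        """Per-sample mean depth over sites with observed depth."""
        dp = np.where(self.dp >= 0, self.dp, np.nan).astype(float)
        return pd.Series(np.nanmean(dp, axis=0), index=self.samples)

    # ---------------------------------------------------------------- I/O

    def write_vcf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(_VCF_HEADER)
            for name, length in self.contigs.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(self.samples)
                + "\n"
            )
            for i, site in enumerate(self.sites.itertuples(index=False)):
                cells = []
                for j in range(len(self.samples)):
                    gt = _GT_STRINGS[int(self.gt[i, j])]
                    if self.gt[i, j] == MISSING:
                        cells.append("./.")
                        continue
                    # SAC ref strand split is not modelled; only alt counts matter
                    sac = (
                        f"{self.ad_ref[i, j]},0,{self.alt_fwd[i, j]},{self.alt_rev[i, j]}"
                        if self.alt_fwd[i, j] >= 0
                        else "."
                    )
                    cells.append(
                        f"{gt}:{self.ad_ref[i, j]},{self.ad_alt[i, j]}:"
                        f"{self.dp[i, j]}:{self.gq[i, j]}:{sac}:{int(self.concordant[i, j])}"
                    )
                fh.write(
                    f"{site.contig}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t.\t"
                    "GT:AD:DP:GQ:SAC:CC\t" + "\t".join(cells) + "\n"
                )


def read_genotype_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF 4.x with FORMAT GT:AD:DP:GQ (SAC and CC optional).

    Only biallelic SNVs are kept; indel and multiallelic records are
    dropped and their counts logged.  Missing FORMAT fields yield -1s so
    that downstream filters can report "not evaluable" instead of crashing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    contigs = dict(zip(vcf.seqnames, vcf.seqlens)) if vcf.seqlens else {}
    rows, gts, dps, gqs, adr, ada, afw, arv, conc = [], [], [], [], [], [], [], [], []
    n_indel = n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_indel += 1
            continue
        rows.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        gt = rec.gt_types.astype(np.int8)  # 0 homref, 1 het, 2 homalt, 3 unknown
        gt[gt == 3] = MISSING
        gts.append(gt)

        def fmt(name: str, ncol: int) -> np.ndarray:
            try:
                arr = rec.format(name)
            except KeyError:
                arr = None
            if arr is None:
                return np.full((len(samples), ncol), -1, dtype=np.int32)
            arr = np.asarray(arr)
            arr = np.where((arr < 0) | (arr > 2**30), -1, arr)
            return arr.astype(np.int32).reshape(len(samples), -1)

        ad = fmt("AD", 2)
        adr.append(ad[:, 0] if ad.shape[1] >= 1 else np.full(len(samples), -1))
        ada.append(ad[:, 1] if ad.shape[1] >= 2 else np.full(len(samples), -1))
        dps.append(fmt("DP", 1)[:, 0])
        gqs.append(fmt("GQ", 1)[:, 0])
        sac = fmt("SAC", 4)
        if sac.shape[1] >= 4:
            afw.append(sac[:, 2])
            arv.append(sac[:, 3])
        else:
            afw.append(np.full(len(samples), -1, dtype=np.int32))
            arv.append(np.full(len(samples), -1, dtype=np.int32))
        cc = fmt("CC", 1)[:, 0]
        conc.append(cc == 1)
    if n_indel:
        log.info("dropped %d indel records", n_indel)
    if n_multi:
        log.info("dropped %d multiallelic records", n_multi)

    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])

    def stack(lst, dtype):
        if not lst:
            return np.zeros((0, len(samples)), dtype=dtype)
        return np.vstack(lst).astype(dtype)

    return GenotypeTable(
        samples=samples,
        sites=sites,
        gt=stack(gts, np.int8),
        dp=stack(dps, np.int32),
        gq=stack(gqs, np.int32),
        ad_ref=stack(adr, np.int32),
        ad_alt=stack(ada, np.int32),
        alt_fwd=stack(afw, np.int32),
        alt_rev=stack(arv, np.int32),
        concordant=stack(conc, bool),
        contigs=contigs,
    )


def read_depth_mask(path: str | Path) -> pd.DataFrame:
    """Read a BED (0-based, half-open) depth mask into 1-based closed intervals."""
    bed = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end"], comment="#"
    )
    out = pd.DataFrame(
        {"contig": bed["contig"], "start": bed["start"] + 1, "end": bed["end"]}
    )
    return out


def mask_span(mask: pd.DataFrame) -> int:
    """Total haploid bp covered by a depth mask."""
    return int((mask["end"] - mask["start"] + 1).sum())
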