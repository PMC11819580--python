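"""End-to-end orchestration: simulate -> call -> phase -> rate -> regress.

Stages communicate through plain files (VCF, PED, TSV, JSON) so every
intermediate is auditable.  Re-running with the same config and seed
reproduces the same reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agemodel, calling, phasing, rates
from .calling import FilterConfig
from .genotypes import GenotypeTable, read_genotype_vcf, read_depth_mask, mask_span, HET
from .pedigree import Pedigree, read_pedigree, read_ages, enumerate_trios
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "pedmut_run"
    seed: int = 0
    # inputs (ignored when simulate=True)
    vcf: str | None = None
    ped: str | None = None
    ages: str | None = None
    reads: str | None = None
    mask_dir: str | None = None
    branch_lengths: str | None = None
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    window: int = 1000
    young_old_split: float = 15.0
    phased_scale: str = "total"
    pseudocount: float = 1.0

    def validate(self) -> None:
        if not 0 < self.filters.ab_min < 1:
            raise ValueError("ab_min must be in (0, 1)")
        lo, hi = self.filters.abhet_range
        if not 0 <= lo < hi <= 1:
            raise ValueError("abhet_range must be ordered within [0, 1]")


def contig_qc_table(table: GenotypeTable, ped: Pedigree) -> pd.DataFrame:
    """Per-contig, per-individual mean depth and heterozygosity for sex QC."""
    rows = []
    contigs = table.sites["contig"].to_numpy()
    for contig in pd.unique(contigs):
        m = contigs == contig
        for j, s in enumerate(table.samples):
            dp = table.dp[m, j]
            gt = table.gt[m, j]
            ok = gt >= 0
            rows.append(
                {
                    "contig": contig,
                    "individual": s,
                    "sex": ped[s].sex,
                    "mean_depth": float(dp[dp >= 0].mean()) if (dp >= 0).any() else np.nan,
                    "heterozygosity": float((gt[ok] == HET).mean()) if ok.any() else np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages and write a report bundle into ``outdir``."""
    cfg = config
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # resolved config, verbatim
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(type(o))

    with open(out / "config.json", "w") as fh:
        json.dump(dataclasses.asdict(cfg), fh, indent=1, default=str)

    truth = None
    if cfg.simulate:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed)
        cohort = simulate_cohort(sim)
        paths = cohort.write(out / "sim")
        table = cohort.genotypes
        ped = cohort.pedigree
        trios = cohort.trios
        evidence = cohort.read_evidence
        masks = {c: mask_span(m) for c, m in cohort.masks.items()}
        truth = cohort.truth
    else:
        if not (cfg.vcf and cfg.ped):
            raise ValueError("vcf and ped inputs are required when simulate=False")
        table = read_genotype_vcf(cfg.vcf)
        ped = read_pedigree(cfg.ped)
        ages = read_ages(cfg.ages) if cfg.ages else None
        trios = enumerate_trios(ped, ages)
        evidence = (
            pd.read_csv(cfg.reads, sep="\t") if cfg.reads else
            pd.DataFrame(columns=["read_id", "contig", "pos", "allele"])
        )
        masks = {}
        if cfg.mask_dir:
            for t in trios:
                p = Path(cfg.mask_dir) / f"mask_{t.child_id}.bed"
                if p.exists():
                    masks[t.child_id] = mask_span(read_depth_mask(p))

    report: dict = {"seed": cfg.seed, "n_trios": len(trios)}

    # ---- sex / X-contig QC and calling
    qc = contig_qc_table(table, ped)
    contig_labels = calling.classify_contigs(qc)
    x_linked = {c.contig for c in contig_labels if c.label == "x_linked"}
    report["x_linked_contigs"] = sorted(x_linked)

    audit = calling.call_denovo(
        table, ped, trios, cfg.filters, exclude_contigs=x_linked
    )
    called = audit.attrs["called"]
    audit.drop(columns=[], inplace=False).to_csv(out / "candidate_audit.tsv", sep="\t", index=False)
    report["n_candidates"] = int(len(audit))
    report["n_called"] = int(len(called))
    for name in calling.FILTER_NAMES:
        report[f"fail_{name}"] = int((audit[f"filter_{name}"] == "fail").sum()) if len(audit) else 0

    # ---- phasing
    mutations = phasing.phase_mutations(
        called, table, trios, evidence, window=cfg.window
    )
    mutations.to_csv(out / "mutations.csv", index=False)
    per_trio_counts, pooled = phasing.summarize_phasing(mutations)
    report["phased_fraction"] = pooled.fraction_phased
    report["alpha_pedigree"] = phasing.pedigree_alpha(per_trio_counts)

    # ---- rates
    depth_means = table.mean_depth()
    trio_rows = []
    for t in trios:
        try:
            est = rates.estimate_callability(
                t, table, cfg.filters, depth_means, masks.get(t.child_id)
            )
        except rates.RateError as e:
            log.warning("%s", e)
            continue
        n_mut = int((mutations["child_id"] == t.child_id).sum())
        if est.depth_pass_sites is None:
            continue
        cs = rates.callable_sum(est)
        res = rates.compute_trio_rate(n_mut, cs, t.child_id)
        counts = next(c for c in per_trio_counts if c.trio_id == t.child_id) if any(
            c.trio_id == t.child_id for c in per_trio_counts
        ) else phasing.PhasedCounts(t.child_id, 0, 0, 0)
        trio_rows.append(
            {
                "child_id": t.child_id,
                "paternal_age": t.paternal_age,
                "maternal_age": t.maternal_age,
                "n_mutations": n_mut,
                "n_phased": counts.n_phased,
                "n_paternal": counts.n_paternal,
                "n_maternal": counts.n_maternal,
                "callability": est.product,
                "callable_gb": cs / 1e9,
                "rate": res.rate,
            }
        )
    trio_table = pd.DataFrame(trio_rows)
    trio_table.to_csv(out / "per_trio.tsv", sep="\t", index=False)
    if len(trio_table):
        results = rates.rates_from_summary_table(trio_table)
        report["cohort"] = rates.cohort_summary(results, trios)

    # ---- age regressions
    if len(trio_table) >= 4:
        design = agemodel.build_design(trio_table)
        try:
            total_fit = agemodel.fit_total_regression(design)
            fit_p = agemodel.fit_phased_regression(
                design, "paternal", cfg.phased_scale, cfg.pseudocount
            )
            fit_m = agemodel.fit_phased_regression(
                design, "maternal", cfg.phased_scale, cfg.pseudocount
            )
            fits = {
                "total": {
                    "params": total_fit.params.tolist(),
                    "pvalues": total_fit.pvalues.tolist(),
                    "maternal_effect_per_year": agemodel.effect_per_year(total_fit, "maternal"),
                    "paternal_effect_per_year": agemodel.effect_per_year(total_fit, "paternal"),
                    "flags": total_fit.flags,
                },
                "phased_paternal": {
                    "params": fit_p.params.tolist(),
                    "pvalues": fit_p.pvalues.tolist(),
                },
                "phased_maternal": {
                    "params": fit_m.params.tolist(),
                    "pvalues": fit_m.pvalues.tolist(),
                },
            }
            with open(out / "fits.json", "w") as fh:
                json.dump(fits, fh, indent=1)
            report["fits"] = fits
            ages_grid = np.linspace(
                float(min(design[["paternal_age", "maternal_age"]].min())),
                float(max(design[["paternal_age", "maternal_age"]].max())),
                50,
            )
            lines = pd.concat(
                [
                    agemodel.predict_fig2_lines(fit_p, ages_grid).assign(parent="paternal"),
                    agemodel.predict_fig2_lines(fit_m, ages_grid).assign(parent="maternal"),
                ]
            )
            lines.to_csv(out / "age_regression_lines.tsv", sep="\t", index=False)
        except agemodel.FitError as e:
            log.warning("age regression skipped: %s", e)

    # ---- truth comparison
    if truth is not None:
        t_dnms = truth.dnms
        key_called = set(zip(mutations["child_id"], mutations["contig"], mutations["pos"]))
        key_truth = set(zip(t_dnms["child_id"], t_dnms["contig"], t_dnms["pos"]))
        tp = len(key_called & key_truth)
        report["truth"] = {
            "true_dnms": len(key_truth),
            "called_dnms": len(key_called),
            "true_positive": tp,
            "false_positive": len(key_called - key_truth),
            "false_negative": len(key_truth - key_called),
        }
        phase_truth = {
            (r.child_id, r.contig, r.pos): r.parent_of_origin
            for r in t_dnms.itertuples(index=False)
        }
        phased = mutations[mutations["phase"] != phasing.UNPHASED]
        correct = sum(
            phase_truth.get((r.child_id, r.contig, r.pos)) == r.phase
            for r in phased.itertuples(index=False)
        )
        report["truth"]["phased_correct"] = int(correct)
        report["truth"]["phased_total"] = int(len(phased))

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=float)
    return report
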