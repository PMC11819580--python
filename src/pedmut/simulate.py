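"""Synthetic pedigree-sequencing cohorts with known truth.

The generator emulates the data model of a trio-sequencing study of
germline mutation: founder genotypes drawn under Hardy-Weinberg at a
configurable polymorphism rate, Mendelian inheritance with one parental
haplotype transmitted per contig per meiosis (no intra-contig
recombination, so read-backed phasing truth is exact), de novo mutations
(DNMs) injected per trio with Poisson counts following an identity-link
linear parental-age model, and per-call noise on depth, genotype quality
and allelic balance that produces realistic filter false negatives.

Default study conditions mirror the aye-aye cohort: 12 trios, parental
ages uniform on 6.7-30.5 years, ~39x coverage, and mutation-model
coefficients calibrated so the expected per-trio DNM counts and the
per-parent split reproduce the cohort's observed scale (intercept -9.15
mutations, +1.87/year paternal, +2.28/year maternal at the simulated
callable genome size).  The genome itself is scaled down to desk size;
coefficients are expressed per callable bp so the counts stay on the
published scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeTable, HOMREF, HET, HOMALT
from .pedigree import Pedigree, Individual, Trio, MALE, FEMALE, write_pedigree

_BASES = np.array(list("ACGT"))

#: Per-year age effects (mutations/year) and intercept (mutations) used to
#: derive the default per-bp model coefficients.  These are the least-squares
#: calibration of the even-split linear family against the cohort's
#: per-parent inferred counts, reproducing the published count scale
#: (~19 DNMs at the youngest ages to ~117 at the oldest) with both parents
#: contributing and the maternal age effect exceeding the paternal.
PAPER_INTERCEPT = -9.15
PAPER_PATERNAL_PER_YEAR = 1.87
PAPER_MATERNAL_PER_YEAR = 2.28


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    n_trios: int = 12
    children_per_family: int = 1
    #: (name, length bp, is_X)
    genome: list[tuple[str, int, bool]] = field(
        default_factory=lambda: [
            ("chr1", 2_500_000, False),
            ("chr2", 2_500_000, False),
            ("chr3", 2_500_000, False),
            ("chr4", 2_500_000, False),
            ("chrX", 1_250_000, True),
        ]
    )
    diploid_callable_fraction: float = 0.9
    het_rate: float = 5e-4  # per-bp heterozygosity of founders
    beta0: float | None = None  # mutations (intercept)
    betaP: float | None = None  # mutations per (bp * year), diploid-callable scale
    betaM: float | None = None
    age_range: tuple[float, float] = (6.7, 30.5)
    depth_mean: float = 39.1
    gq_fail_rate: float = 0.03
    ab_concentration: float = 60.0  # Beta(k/2, k/2) allelic-balance noise
    alt_error_rate: float = 1e-4  # per-read high-quality error alt reads in hom-ref samples
    read_length: int = 150
    fragment_length: int = 500
    caller_discordance_rate: float = 0.01
    n_third_generation: int = 0  # trio children given an offspring of their own
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.diploid_callable_fraction <= 1:
            raise SimConfigError("diploid_callable_fraction must be in [0, 1]")
        if self.het_rate < 0 or self.depth_mean <= 0:
            raise SimConfigError("rates must be non-negative, depth positive")
        L = self.diploid_callable_size
        if self.beta0 is None:
            self.beta0 = PAPER_INTERCEPT
        if self.betaP is None:
            self.betaP = PAPER_PATERNAL_PER_YEAR / L
        if self.betaM is None:
            self.betaM = PAPER_MATERNAL_PER_YEAR / L

    @property
    def autosomes(self) -> list[tuple[str, int]]:
        return [(n, l) for n, l, is_x in self.genome if not is_x]

    @property
    def autosome_length(self) -> int:
        return sum(l for _, l in self.autosomes)

    @property
    def diploid_callable_size(self) -> float:
        """L: twice the depth-passing autosomal haploid size."""
        return 2.0 * self.autosome_length * self.diploid_callable_fraction

    def expected_dnms(self, paternal_age: float, maternal_age: float) -> float:
        L = self.diploid_callable_size
        mu = self.beta0 + self.betaP * L * paternal_age + self.betaM * L * maternal_age
        if mu < 0:
            raise SimConfigError(
                f"identity-link mean {mu:.2f} < 0 at ages "
                f"({paternal_age}, {maternal_age}); adjust coefficients"
            )
        return mu

    def paternal_fraction(self, paternal_age: float, maternal_age: float) -> float:
        """Expected paternal share of DNMs; the intercept splits evenly."""
        L = self.diploid_callable_size
        mu = self.expected_dnms(paternal_age, maternal_age)
        if mu == 0:
            return 0.5
        pat = self.beta0 / 2 + self.betaP * L * paternal_age
        return min(max(pat / mu, 0.0), 1.0)


@dataclass
class TruthSet:
    dnms: pd.DataFrame  # child_id, contig, pos, ref, alt, parent_of_origin,
    #                     on_callable, transmitted_to (';'-joined ids)
    trio_info: pd.DataFrame  # trio_id, depth_pass_bp, diploid_callable_bp
    true_gt: np.ndarray  # noise-free genotype codes, sites x samples
    samples: list[str]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "dnms": self.dnms.to_dict(orient="records"),
            "trio_info": self.trio_info.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class SimulatedCohort:
    config: SimConfig
    pedigree: Pedigree
    trios: list[Trio]
    genotypes: GenotypeTable
    truth: TruthSet
    read_evidence: pd.DataFrame  # read_id, contig, pos, allele (base)
    masks: dict[str, pd.DataFrame]  # trio child_id -> BED-like 1-based intervals
    # phased child haplotypes, needed to regenerate read evidence
    _hap: np.ndarray | None = None  # 2 x sites x samples, allele codes 0/1

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": outdir / "cohort.vcf",
            "ped": outdir / "cohort.ped",
            "ages": outdir / "ages.tsv",
            "reads": outdir / "read_evidence.tsv",
            "truth": outdir / "truth.json",
        }
        self.genotypes.write_vcf(paths["vcf"])
        write_pedigree(self.pedigree, paths["ped"])
        pd.DataFrame(
            {
                "child_id": [t.child_id for t in self.trios],
                "paternal_age": [t.paternal_age for t in self.trios],
                "maternal_age": [t.maternal_age for t in self.trios],
            }
        ).to_csv(paths["ages"], sep="\t", index=False)
        self.read_evidence.to_csv(paths["reads"], sep="\t", index=False)
        self.truth.to_json(paths["truth"])
        for child, mask in self.masks.items():
            p = outdir / f"mask_{child}.bed"
            # back to 0-based half-open BED
            pd.DataFrame(
                {"contig": mask["contig"], "start": mask["start"] - 1, "end": mask["end"]}
            ).to_csv(p, sep="\t", index=False, header=False)
            paths[f"mask_{child}"] = p
        return paths


def _sample_sites(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Polymorphic site positions with population allele frequencies."""
    rows = []
    for name, length, is_x in cfg.genome:
        # mean heterozygosity 2p(1-p) with p ~ U(0.05, 0.5) is ~0.32, so the
        # site density is het_rate / 0.32
        n = rng.poisson(cfg.het_rate * length / 0.32)
        n = min(n, length // 2)
        pos = np.sort(rng.choice(np.arange(1, length + 1), size=n, replace=False))
        for p in pos:
            rows.append((name, int(p), is_x))
    df = pd.DataFrame(rows, columns=["contig", "pos", "is_x"])
    df["pos"] = df["pos"].astype(int)
    df["is_x"] = df["is_x"].astype(bool)
    df["freq"] = rng.uniform(0.05, 0.5, size=len(df))
    ref_idx = rng.integers(0, 4, size=len(df))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(df))) % 4
    df["ref"] = _BASES[ref_idx]
    df["alt"] = _BASES[alt_idx]
    return df


def simulate_cohort(config: SimConfig, seed: int | None = None) -> SimulatedCohort:
    """Generate a full cohort: genotypes, truth DNMs, masks and read evidence.

    Deterministic for a fixed ``config`` (and ``seed`` override).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    sites = _sample_sites(cfg, rng)
    n_poly = len(sites)

    # ------------------------------------------------------ pedigree
    ped = Pedigree()
    trios: list[Trio] = []
    sample_order: list[str] = []
    fam = 0
    n_families = int(np.ceil(cfg.n_trios / cfg.children_per_family))
    child_no = 0
    for f in range(n_families):
        fam += 1
        father, mother = f"F{fam:03d}", f"M{fam:03d}"
        ped.add(Individual(father, MALE, family_id=str(fam)))
        ped.add(Individual(mother, FEMALE, family_id=str(fam)))
        sample_order += [father, mother]
        for _ in range(cfg.children_per_family):
            if child_no >= cfg.n_trios:
                break
            child_no += 1
            child = f"C{child_no:03d}"
            sex = MALE if rng.random() < 0.5 else FEMALE
            ped.add(Individual(child, sex, father, mother, family_id=str(fam)))
            sample_order.append(child)
            pa = float(rng.uniform(*cfg.age_range))
            ma = float(rng.uniform(*cfg.age_range))
            trios.append(Trio(child, father, mother, round(pa, 1), round(ma, 1)))
    # third generation: first k trio children get one offspring with a new mate
    grandchild_parent: dict[str, str] = {}
    for k in range(min(cfg.n_third_generation, len(trios))):
        trio = trios[k]
        child = ped[trio.child_id]
        fam += 1
        mate_sex = FEMALE if child.sex == MALE else MALE
        mate = f"S{k + 1:03d}"
        ped.add(Individual(mate, mate_sex, family_id=str(fam)))
        gkid = f"G{k + 1:03d}"
        father_id = trio.child_id if child.sex == MALE else mate
        mother_id = mate if child.sex == MALE else trio.child_id
        ped.add(
            Individual(gkid, MALE if rng.random() < 0.5 else FEMALE, father_id, mother_id, str(fam))
        )
        sample_order += [mate, gkid]
        grandchild_parent[gkid] = trio.child_id

    samples = sample_order
    sidx = {s: i for i, s in enumerate(samples)}
    n_smp = len(samples)

    # ------------------------------------------- haplotypes at polymorphic sites
    # hap[0] = paternally inherited haplotype (arbitrary for founders)
    hap = np.zeros((2, n_poly, n_smp), dtype=np.int8)
    freq = sites["freq"].to_numpy()
    is_x = sites["is_x"].to_numpy()
    contigs_arr = sites["contig"].to_numpy()
    contig_names = [n for n, _, _ in cfg.genome]

    founders = [i for i in samples if ped[i].is_founder]
    for s in founders:
        j = sidx[s]
        hap[0, :, j] = rng.random(n_poly) < freq
        hap[1, :, j] = rng.random(n_poly) < freq
        if ped[s].sex == MALE:
            hap[1, is_x, j] = hap[0, is_x, j]  # haploid X

    # children (2nd then 3rd generation), one parental haplotype per contig
    def inherit(child: str) -> None:
        j = sidx[child]
        ind = ped[child]
        for parent_id, h in ((ind.father_id, 0), (ind.mother_id, 1)):
            pj = sidx[parent_id]
            for c in contig_names:
                m = contigs_arr == c
                chosen = int(rng.integers(0, 2))
                hap[h, m, j] = hap[chosen, m, pj]

    gen2 = [t.child_id for t in trios]
    gen3 = list(grandchild_parent)
    for child in gen2 + gen3:
        inherit(child)

    true_gt_poly = (hap[0] + hap[1]).astype(np.int8)  # 0/1/2 alt dosage

    # ------------------------------------------------------- masks & DNMs
    autosome_names = [n for n, _ in cfg.autosomes]
    auto_lens = dict(cfg.autosomes)
    masks: dict[str, pd.DataFrame] = {}
    frac = cfg.diploid_callable_fraction
    for t in trios:
        masks[t.child_id] = pd.DataFrame(
            {
                "contig": autosome_names,
                "start": [1] * len(autosome_names),
                "end": [int(round(auto_lens[c] * frac)) for c in autosome_names],
            }
        )

    total_auto = cfg.autosome_length
    bounds = np.cumsum([auto_lens[c] for c in autosome_names])
    dnm_rows = []
    used_positions = {
        (c, p) for c, p in zip(sites["contig"], sites["pos"])
    }
    dnm_hap_alleles = []  # (child_idx, hap_index) for read evidence
    for t in trios:
        mu = cfg.expected_dnms(t.paternal_age, t.maternal_age)
        n_dnm = rng.poisson(mu)
        p_pat = cfg.paternal_fraction(t.paternal_age, t.maternal_age)
        for _ in range(n_dnm):
            while True:
                g = int(rng.integers(1, total_auto + 1))
                ci = int(np.searchsorted(bounds, g))
                contig = autosome_names[ci]
                pos = g - (int(bounds[ci - 1]) if ci else 0)
                pos = max(pos, 1)
                if (contig, pos) not in used_positions:
                    used_positions.add((contig, pos))
                    break
            paternal = rng.random() < p_pat
            ref, alt = rng.choice(4, size=2, replace=False)
            end = int(round(auto_lens[contig] * frac))
            transmitted_to = []
            dnm_rows.append(
                {
                    "child_id": t.child_id,
                    "contig": contig,
                    "pos": int(pos),
                    "ref": str(_BASES[ref]),
                    "alt": str(_BASES[alt]),
                    "parent_of_origin": "paternal" if paternal else "maternal",
                    "on_callable": bool(pos <= end),
                    "transmitted_to": transmitted_to,
                }
            )
            dnm_hap_alleles.append(0 if paternal else 1)

    dnms = pd.DataFrame(
        dnm_rows,
        columns=[
            "child_id",
            "contig",
            "pos",
            "ref",
            "alt",
            "parent_of_origin",
            "on_callable",
            "transmitted_to",
        ],
    )

    # transmission of DNMs to grandchildren: each DNM transmits with
    # probability 1/2, modelling independent meioses (DNMs are far apart,
    # so recombination decouples them; the strict one-haplotype-per-contig
    # rule is kept only for read-scale phasing evidence)
    carrier_children = {v: k for k, v in grandchild_parent.items()}
    dnm_carried_by_gkid = np.zeros(len(dnms), dtype=bool)
    for i, row in enumerate(dnm_rows):
        carrier = row["child_id"]
        if carrier not in carrier_children:
            continue
        gkid = carrier_children[carrier]
        if rng.random() < 0.5:
            row["transmitted_to"].append(gkid)
            dnm_carried_by_gkid[i] = True

    # --------------------------------------------- assemble the site table
    n_dnm_sites = len(dnms)
    all_sites = pd.concat(
        [
            sites[["contig", "pos", "ref", "alt"]].assign(kind="poly"),
            dnms[["contig", "pos", "ref", "alt"]].assign(kind="dnm"),
        ],
        ignore_index=True,
    )
    order = np.lexsort((all_sites["pos"].to_numpy(), all_sites["contig"].to_numpy()))
    all_sites = all_sites.iloc[order].reset_index(drop=True)
    inv = np.empty(len(order), dtype=int)
    inv[order] = np.arange(len(order))  # original index -> sorted row

    n_sites = len(all_sites)
    true_gt = np.zeros((n_sites, n_smp), dtype=np.int8)
    true_gt[inv[:n_poly]] = true_gt_poly
    # DNM sites: everyone hom-ref except the carrier (het) and carriers' kids
    for i in range(n_dnm_sites):
        r = inv[n_poly + i]
        true_gt[r, sidx[dnm_rows[i]["child_id"]]] = HET
        if dnm_carried_by_gkid[i]:
            gkid = carrier_children[dnm_rows[i]["child_id"]]
            true_gt[r, sidx[gkid]] = HET

    # full haplotype matrix over all sites (for read evidence)
    hap_all = np.zeros((2, n_sites, n_smp), dtype=np.int8)
    hap_all[:, inv[:n_poly], :] = hap
    for i in range(n_dnm_sites):
        r = inv[n_poly + i]
        j = sidx[dnm_rows[i]["child_id"]]
        hap_all[dnm_hap_alleles[i], r, j] = 1
        if dnm_carried_by_gkid[i]:
            gkid = carrier_children[dnm_rows[i]["child_id"]]
            gj = sidx[gkid]
            h = 0 if ped[gkid].father_id == dnm_rows[i]["child_id"] else 1
            hap_all[h, r, gj] = 1

    # ------------------------------------------------------------- noise
    gt = true_gt.copy()
    dp = rng.poisson(cfg.depth_mean, size=(n_sites, n_smp)).astype(np.int32)
    # haploid X in males at half depth
    site_is_x = all_sites["contig"].isin(
        [n for n, _, isx in cfg.genome if isx]
    ).to_numpy()
    male = np.array([ped[s].sex == MALE for s in samples])
    xm = np.outer(site_is_x, male)
    dp[xm] = rng.poisson(cfg.depth_mean / 2, size=int(xm.sum()))

    ab = rng.beta(cfg.ab_concentration / 2, cfg.ab_concentration / 2, size=(n_sites, n_smp))
    ad_alt = np.where(
        gt == HET,
        rng.binomial(np.maximum(dp, 0), ab),
        np.where(gt == HOMALT, dp, rng.binomial(np.maximum(dp, 0), cfg.alt_error_rate)),
    ).astype(np.int32)
    ad_alt = np.minimum(ad_alt, dp)
    ad_ref = (dp - ad_alt).astype(np.int32)
    gq = np.where(
        rng.random((n_sites, n_smp)) < cfg.gq_fail_rate,
        rng.integers(20, 61, size=(n_sites, n_smp)),
        99,
    ).astype(np.int32)
    alt_fwd = rng.binomial(ad_alt, 0.5).astype(np.int32)
    alt_rev = (ad_alt - alt_fwd).astype(np.int32)
    concordant = ~(
        (gt == HET) & (rng.random((n_sites, n_smp)) < cfg.caller_discordance_rate)
    )

    table = GenotypeTable(
        samples=samples,
        sites=all_sites[["contig", "pos", "ref", "alt"]].copy(),
        gt=gt,
        dp=dp,
        gq=gq,
        ad_ref=ad_ref,
        ad_alt=ad_alt,
        alt_fwd=alt_fwd,
        alt_rev=alt_rev,
        concordant=concordant,
        contigs={n: l for n, l, _ in cfg.genome},
    )

    trio_info = pd.DataFrame(
        {
            "trio_id": [t.child_id for t in trios],
            "depth_pass_bp": [
                int((masks[t.child_id]["end"] - masks[t.child_id]["start"] + 1).sum())
                for t in trios
            ],
            "diploid_callable_bp": [cfg.diploid_callable_size] * len(trios),
        }
    )
    dnms_out = dnms.copy()
    dnms_out["transmitted_to"] = [";".join(x) for x in dnms["transmitted_to"]]
    truth = TruthSet(dnms=dnms_out, trio_info=trio_info, true_gt=true_gt, samples=samples)

    cohort = SimulatedCohort(
        config=cfg,
        pedigree=ped,
        trios=trios,
        genotypes=table,
        truth=truth,
        read_evidence=pd.DataFrame(columns=["read_id", "contig", "pos", "allele"]),
        masks=masks,
        _hap=hap_all,
    )
    cohort.read_evidence = simulate_read_evidence(cohort, rng)
    return cohort


def simulate_read_evidence(
    cohort: SimulatedCohort, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Haplotype-consistent read pairs around each true DNM.

    For every true DNM, paired reads covering the site are drawn at the
    configured depth; each pair comes from one of the child's two
    haplotypes and reports the haplotype's base at the DNM and at every
    child-heterozygous site it covers.  Pairs without informative sites
    are emitted too.
    """
    cfg = cohort.config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    hap = cohort._hap
    if hap is None:
        raise ValueError("cohort lacks haplotype state")
    sites = cohort.genotypes.sites
    pos_by_contig = {
        c: grp["pos"].to_numpy() for c, grp in sites.groupby("contig", sort=False)
    }
    rowidx_by_contig = {
        c: grp.index.to_numpy() for c, grp in sites.groupby("contig", sort=False)
    }
    sidx = {s: i for i, s in enumerate(cohort.genotypes.samples)}
    rl, fl = cfg.read_length, cfg.fragment_length

    rows = []
    read_no = 0
    for dnm in cohort.truth.dnms.itertuples(index=False):
        j = sidx[dnm.child_id]
        contig_pos = pos_by_contig.get(dnm.contig)
        if contig_pos is None:
            continue
        contig_rows = rowidx_by_contig[dnm.contig]
        site_row = contig_rows[np.searchsorted(contig_pos, dnm.pos)]
        n_pairs = rng.poisson(cfg.depth_mean / 2)
        for _ in range(n_pairs):
            h = int(rng.integers(0, 2))
            start = int(rng.integers(dnm.pos - fl + 1, dnm.pos + 1))
            windows = [(start, start + rl - 1), (start + fl - rl, start + fl - 1)]
            covered = np.zeros(len(contig_pos), dtype=bool)
            for s, e in windows:
                covered |= (contig_pos >= s) & (contig_pos <= e)
            if not covered[np.searchsorted(contig_pos, dnm.pos)]:
                continue
            read_no += 1
            rid = f"r{read_no:07d}"
            for k in np.flatnonzero(covered):
                r = contig_rows[k]
                # only child-het sites are reportable phase information
                if cohort.genotypes.gt[r, j] != HET and r != site_row:
                    continue
                allele_is_alt = hap[h, r, j] == 1
                base = sites["alt"].iat[r] if allele_is_alt else sites["ref"].iat[r]
                rows.append((rid, dnm.contig, int(contig_pos[k]), base))
    return pd.DataFrame(rows, columns=["read_id", "contig", "pos", "allele"])


def simulate_count_cohort(
    n_trios: int,
    diploid_callable_bp: float,
    beta0: float,
    betaP: float,
    betaM: float,
    rng: np.random.Generator,
    age_range: tuple[float, float] = (6.7, 30.5),
    phased_fraction: float = 0.31,
) -> pd.DataFrame:
    """Lightweight count-level cohort for regression calibration studies.

    Returns a per-trio design table (ages, diploid callable size L, total
    and parent-of-origin phased counts) without simulating genotypes.
    The betas are on the per-(bp*year) scale of the identity-link model;
    the intercept splits evenly between parents.
    """
    L = diploid_callable_bp
    xp = rng.uniform(*age_range, size=n_trios)
    xm = rng.uniform(*age_range, size=n_trios)
    mu_pat = beta0 / 2 + betaP * L * xp
    mu_mat = beta0 / 2 + betaM * L * xm
    mu_tot = mu_pat + mu_mat
    if (mu_tot < 0).any():
        raise SimConfigError("negative expected counts under identity link")
    with np.errstate(invalid="ignore"):
        p_pat = np.where(mu_tot > 0, np.clip(mu_pat, 0, None) / mu_tot, 0.5)
    p_pat = np.clip(p_pat, 0.0, 1.0)
    n_tot = rng.poisson(mu_tot)
    n_pat = rng.binomial(n_tot, p_pat)
    n_mat = n_tot - n_pat
    ph_pat = rng.binomial(n_pat, phased_fraction)
    ph_mat = rng.binomial(n_mat, phased_fraction)
    return pd.DataFrame(
        {
            "child_id": [f"T{i:04d}" for i in range(n_trios)],
            "paternal_age": xp,
            "maternal_age": xm,
            "n_mutations": n_tot,
            "n_paternal": ph_pat,
            "n_maternal": ph_mat,
            "n_phased": ph_pat + ph_mat,
            "callable_gb": L / 2 / 1e9,
        }
    )


def simulate_branch_lengths(
    alpha_true: float,
    autosome_count: int = 31,
    noise_sd: float = 0.0,
    mean_autosome_length: float = 0.123,
    branch: str = "sim",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Branch-length table with a known male-to-female rate ratio.

    The X/autosome substitution-rate ratio is set to ``(4+2a)/(3+3a)``;
    per-autosome lengths are jittered multiplicatively (lognormal with
    sigma ``noise_sd``).
    """
    if alpha_true <= 0:
        raise ValueError("alpha_true must be positive")
    if rng is None:
        rng = np.random.default_rng(0)
    ratio = (4 + 2 * alpha_true) / (3 + 3 * alpha_true)
    a_len = mean_autosome_length * (
        rng.lognormal(0.0, noise_sd, size=autosome_count) if noise_sd > 0 else np.ones(autosome_count)
    )
    x_len = mean_autosome_length * ratio
    rows = [
        {"branch": branch, "chromosome": f"chr{i + 1}", "is_X": False, "branch_length": a}
        for i, a in enumerate(a_len)
    ]
    rows.append(
        {"branch": branch, "chromosome": "chrX", "is_X": True, "branch_length": x_len}
    )
    return pd.DataFrame(rows)


def config_to_yaml(cfg: SimConfig, path: str | Path) -> None:
    import yaml

    d = asdict(cfg)
    d["genome"] = [list(g) for g in cfg.genome]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> SimConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["genome"] = [tuple(g) for g in d["genome"]]
    d["age_range"] = tuple(d["age_range"])
    return SimConfig(**d)
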