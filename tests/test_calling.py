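import numpy as np
import pandas as pd
import pytest

from pedmut import calling
from pedmut.calling import FilterConfig, classify_contigs, prefilter_sites
from pedmut.genotypes import HET, HOMREF, HOMALT
from conftest import make_table, nuclear_pedigree

TRIO_SAMPLES = ["dad", "mom", "kid"]


def _clean_candidate_row(pos=100, **overrides):
    """A site that passes every filter unless perturbed."""
    row = {
        "contig": "chr1",
        "pos": pos,
        "ref": "A",
        "alt": "G",
        "dad": (HOMREF, 40, 99, 40, 0, 0, 0, True),
        "mom": (HOMREF, 38, 99, 38, 0, 0, 0, True),
        "kid": (HET, 40, 99, 20, 20, 10, 10, True),
    }
    row.update(overrides)
    return row


def _call(rows, extra_samples=()):
    samples = TRIO_SAMPLES + list(extra_samples)
    table = make_table(samples, rows)
    ped, trio = nuclear_pedigree()
    cand = calling.find_mendelian_violations(trio, table)
    depth_means = pd.Series(40.0, index=samples)
    return calling.apply_dnm_filters(cand, table, trio, depth_means, ped)


# ------------------------------------------------------------- prefilter

@pytest.mark.parametrize(
    "ad_ref,ad_alt,kept",
    [(5, 45, False), (25, 25, True), (41, 9, False)],
    ids=["abhet_0.10_removed", "abhet_0.50_kept", "abhet_0.82_removed"],
)
def test_abhet_prefilter(ad_ref, ad_alt, kept):
    table = make_table(
        TRIO_SAMPLES,
        [_clean_candidate_row(kid=(HET, ad_ref + ad_alt, 99, ad_ref, ad_alt, 2, 2, True))],
    )
    filtered, verdict = prefilter_sites(table)
    assert (filtered.n_sites == 1) == kept


def test_abhet_no_het_carriers_not_evaluable():
    table = make_table(
        TRIO_SAMPLES,
        [{"contig": "chr1", "pos": 5,
          "dad": (HOMREF, 40, 99, 40, 0, 0, 0, True),
          "mom": (HOMREF, 40, 99, 40, 0, 0, 0, True),
          "kid": (HOMALT, 40, 99, 0, 40, 20, 20, True)}],
    )
    filtered, verdict = prefilter_sites(table)
    assert filtered.n_sites == 1
    assert verdict.iloc[0] == calling.NOT_EVALUABLE


# --------------------------------------------------- Mendelian violations

@pytest.mark.parametrize(
    "dad_gt,mom_gt,kid_gt,expected",
    [
        (HOMREF, HOMREF, HET, 1),
        (HOMREF, HET, HET, 0),
        (HOMREF, HOMREF, HOMALT, 0),
        (HET, HOMREF, HET, 0),
    ],
)
def test_mendelian_violation_definition(dad_gt, mom_gt, kid_gt, expected):
    table = make_table(
        TRIO_SAMPLES,
        [_clean_candidate_row(
            dad=(dad_gt, 40, 99, 40, 0, 0, 0, True),
            mom=(mom_gt, 40, 99, 40 if mom_gt == HOMREF else 20,
                 0 if mom_gt == HOMREF else 20, 5, 5, True),
            kid=(kid_gt, 40, 99, 20 if kid_gt == HET else 0,
                 20 if kid_gt == HET else 40, 10, 10, True),
        )],
    )
    ped, trio = nuclear_pedigree()
    cand = calling.find_mendelian_violations(trio, table)
    assert len(cand) == expected


def test_missing_genotype_skipped():
    table = make_table(
        TRIO_SAMPLES,
        [_clean_candidate_row(dad=(-1, -1, -1, -1, -1, -1, -1, True))],
    )
    ped, trio = nuclear_pedigree()
    assert len(calling.find_mendelian_violations(trio, table)) == 0


def test_x_linked_contigs_excluded():
    table = make_table(TRIO_SAMPLES, [_clean_candidate_row()])
    ped, trio = nuclear_pedigree()
    cand = calling.find_mendelian_violations(trio, table, exclude_contigs={"chr1"})
    assert len(cand) == 0


# ----------------------------------------------------------- the filters

def test_clean_candidate_passes_everything():
    audit = _call([_clean_candidate_row()])
    assert len(audit) == 1
    assert audit["passes"].iloc[0]
    for name in calling.FILTER_NAMES:
        assert audit[f"filter_{name}"].iloc[0] == calling.PASS


@pytest.mark.parametrize(
    "override,failing",
    [
        ({"mom": (HOMREF, 14, 99, 14, 0, 0, 0, True)}, "depth"),
        ({"kid": (HET, 300, 99, 150, 150, 75, 75, True)}, "depth"),
        ({"kid": (HET, 40, 60, 20, 20, 10, 10, True)}, "gq"),
        ({"kid": (HET, 40, 99, 20, 20, 10, 10, False)}, "caller_concordance"),
        ({"kid": (HET, 40, 99, 20, 20, 20, 0, True)}, "strand"),
        ({"dad": (HOMREF, 40, 99, 39, 1, 1, 0, True)}, "parent_alt_reads"),
        ({"kid": (HET, 40, 99, 26, 14, 7, 7, True)}, "allelic_balance"),
    ],
    ids=["mom_depth_14", "kid_depth_above_max", "gq_exactly_60",
         "caller_discordant", "one_strand_only", "parent_one_alt_read",
         "ab_0.35_strict"],
)
def test_each_filter_fails_its_violator_alone(override, failing):
    audit = _call([_clean_candidate_row(**override)])
    assert len(audit) == 1
    assert audit[f"filter_{failing}"].iloc[0] == calling.FAIL
    for name in calling.FILTER_NAMES:
        if name != failing:
            assert audit[f"filter_{name}"].iloc[0] == calling.PASS, name
    assert not audit["passes"].iloc[0]


def test_allelic_balance_boundary():
    """AB = 7/20 = 0.35 fails (strict); 8/21 ~ 0.381 passes."""
    fail = _call([_clean_candidate_row(kid=(HET, 20, 99, 13, 7, 4, 3, True))])
    assert fail["filter_allelic_balance"].iloc[0] == calling.FAIL
    ok = _call([_clean_candidate_row(kid=(HET, 21, 99, 13, 8, 4, 4, True))])
    assert ok["filter_allelic_balance"].iloc[0] == calling.PASS


def test_max_depth_modes():
    cfg4 = FilterConfig(max_depth_mode="sigma4")
    cfg5 = FilterConfig(max_depth_mode="fivex")
    assert cfg4.max_depth(40.0) == pytest.approx(40 + 4 * np.sqrt(40))
    assert cfg5.max_depth(40.0) == 200.0


def test_missing_strand_counts_fail_closed():
    audit = _call([_clean_candidate_row(kid=(HET, 40, 99, 20, 20, -1, -1, True))])
    assert audit["filter_strand"].iloc[0] == calling.NOT_EVALUABLE
    assert not audit["passes"].iloc[0]


def test_cohort_absence_read_vs_genotype_level():
    row = _clean_candidate_row(other=(HOMREF, 40, 99, 39, 1, 1, 0, True))
    samples = TRIO_SAMPLES + ["other"]
    table = make_table(samples, [row])
    ped, trio = nuclear_pedigree()
    depth_means = pd.Series(40.0, index=samples)
    cand = calling.find_mendelian_violations(trio, table)
    strict = calling.apply_dnm_filters(cand, table, trio, depth_means, ped,
                                       FilterConfig(cohort_absence_level="read"))
    lenient = calling.apply_dnm_filters(cand, table, trio, depth_means, ped,
                                        FilterConfig(cohort_absence_level="genotype"))
    assert strict["filter_cohort_absence"].iloc[0] == calling.FAIL
    assert lenient["filter_cohort_absence"].iloc[0] == calling.PASS


def test_sibling_carrier_exempt_from_cohort_absence(tmp_path):
    from pedmut.pedigree import Pedigree, Individual, Trio, MALE, FEMALE

    ped = Pedigree()
    ped.add(Individual("dad", MALE))
    ped.add(Individual("mom", FEMALE))
    ped.add(Individual("kid", MALE, "dad", "mom"))
    ped.add(Individual("sib", FEMALE, "dad", "mom"))
    trio = Trio("kid", "dad", "mom")
    row = _clean_candidate_row(sib=(HET, 40, 99, 20, 20, 10, 10, True))
    samples = TRIO_SAMPLES + ["sib"]
    table = make_table(samples, [row])
    cand = calling.find_mendelian_violations(trio, table)
    audit = calling.apply_dnm_filters(
        cand, table, trio, pd.Series(40.0, index=samples), ped
    )
    assert audit["filter_cohort_absence"].iloc[0] == calling.PASS


# --------------------------------------------------------------- contigs

def _qc(contig, male_depth, female_depth, male_het=0.001, female_het=0.001,
        jitter=0.0, n=4, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        rows.append({"contig": contig, "individual": f"m{i}", "sex": "male",
                     "mean_depth": male_depth + jitter * rng.standard_normal(),
                     "heterozygosity": male_het + jitter * 1e-4 * rng.standard_normal()})
        rows.append({"contig": contig, "individual": f"f{i}", "sex": "female",
                     "mean_depth": female_depth + jitter * rng.standard_normal(),
                     "heterozygosity": female_het + jitter * 1e-4 * rng.standard_normal()})
    return pd.DataFrame(rows)


def test_classify_contigs_rules():
    qc = pd.concat([
        _qc("cA", 12.0, 24.0, jitter=0.3, seed=1),      # low male depth, significant
        _qc("cB", 40.0, 40.0, jitter=0.3, seed=2),      # no difference
        _qc("cC", 40.0, 40.0, male_het=0.0002, female_het=0.002,
            jitter=0.05, seed=3),                        # het differs, male depth high
    ])
    labels = {c.contig: c.label for c in classify_contigs(qc)}
    assert labels["cA"] == "x_linked"
    assert labels["cB"] == "autosomal"
    assert labels["cC"] == "unfiltered"


def test_single_sex_cohort_all_autosomal():
    qc = _qc("cA", 12.0, 24.0, jitter=0.3)
    qc = qc[qc["sex"] == "male"]
    labels = classify_contigs(qc)
    assert all(c.label == "autosomal" for c in labels)


# ---------------------------------------------------------- transmission

def test_transmission_counts_against_truth(small_cohort):
    from pedmut import phasing

    c = small_cohort
    audit = calling.call_denovo(c.genotypes, c.pedigree, c.trios)
    called = audit.attrs["called"]
    res = calling.assess_transmission(called, c.genotypes, c.pedigree)
    assert not res.empty
    truth = c.truth.dnms
    for row in res.itertuples(index=False):
        child_called = called[called["child_id"] == row.child_id]
        keys = set(zip(child_called["contig"], child_called["pos"]))
        tr = truth[(truth["child_id"] == row.child_id)
                   & truth["transmitted_to"].str.len().gt(0)]
        expected = sum((c_, p_) in keys for c_, p_ in zip(tr["contig"], tr["pos"]))
        assert row.transmitted == expected
        assert row.assessable == len(child_called)


def test_transmission_fraction_near_half(small_cohort):
    c = small_cohort
    audit = calling.call_denovo(c.genotypes, c.pedigree, c.trios)
    res = calling.assess_transmission(audit.attrs["called"], c.genotypes, c.pedigree)
    k, n = res["transmitted"].sum(), res["assessable"].sum()
    assert n > 40
    # binomial(n, 0.5) within 4 sigma
    assert abs(k - n / 2) < 4 * np.sqrt(n * 0.25)


def test_no_third_generation_empty_result():
    table = make_table(TRIO_SAMPLES, [_clean_candidate_row()])
    ped, trio = nuclear_pedigree()
    dnms = pd.DataFrame([{"child_id": "kid", "contig": "chr1", "pos": 100,
                          "ref": "A", "alt": "G"}])
    assert calling.assess_transmission(dnms, table, ped).empty


def test_grandchildren_all_homref_zero_transmitted():
    from pedmut.pedigree import Pedigree, Individual, Trio, MALE, FEMALE

    ped = Pedigree()
    for args in [("dad", MALE), ("mom", FEMALE), ("mate", FEMALE)]:
        ped.add(Individual(*args))
    ped.add(Individual("kid", MALE, "dad", "mom"))
    ped.add(Individual("gkid", MALE, "kid", "mate"))
    samples = ["dad", "mom", "kid", "mate", "gkid"]
    table = make_table(samples, [_clean_candidate_row()])  # gkid defaults hom-ref
    dnms = pd.DataFrame([{"child_id": "kid", "contig": "chr1", "pos": 100,
                          "ref": "A", "alt": "G"}])
    res = calling.assess_transmission(dnms, table, ped)
    assert res["transmitted"].iloc[0] == 0 and res["assessable"].iloc[0] == 1


# ----------------------------------------------------------------- MNMs

def test_mnm_clustering_and_sibling_sharing():
    from pedmut.pedigree import Pedigree, Individual, MALE, FEMALE

    ped = Pedigree()
    ped.add(Individual("dad", MALE))
    ped.add(Individual("mom", FEMALE))
    ped.add(Individual("kid", MALE, "dad", "mom"))
    ped.add(Individual("sib", FEMALE, "dad", "mom"))
    dnms = pd.DataFrame(
        [
            {"child_id": "kid", "contig": "c1", "pos": 100, "ref": "A", "alt": "G"},
            {"child_id": "kid", "contig": "c1", "pos": 105, "ref": "C", "alt": "T"},
            {"child_id": "kid", "contig": "c1", "pos": 500, "ref": "C", "alt": "T"},
            {"child_id": "sib", "contig": "c1", "pos": 500, "ref": "C", "alt": "T"},
        ]
    )
    out = calling.annotate_mnm_clusters(dnms)
    clustered = out[out["mnm_cluster_id"].notna()]
    assert set(clustered["pos"]) == {100, 105}
    out = calling.annotate_sibling_shared(out, ped)
    assert set(out[out["shared_with_sibling"]]["pos"]) == {500}
    # counted once per carrier: both rows retained
    assert (out["pos"] == 500).sum() == 2
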