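import numpy as np
import pandas as pd
import pytest

from pedmut.genotypes import GenotypeTable
from pedmut.pedigree import Pedigree, Individual, Trio, MALE, FEMALE
from pedmut.simulate import SimConfig, simulate_cohort


def make_table(
    samples: list[str],
    rows: list[dict],
    contigs: dict[str, int] | None = None,
) -> GenotypeTable:
    """Hand-build a GenotypeTable.

    Each row dict: contig, pos, ref, alt plus per-sample tuples
    ``sample -> (gt, dp, gq, ad_ref, ad_alt, alt_fwd, alt_rev, concordant)``.
    Unlisted samples default to clean hom-ref calls.
    """
    default = (0, 40, 99, 40, 0, 0, 0, True)
    n, m = len(rows), len(samples)
    arrays = {
        k: np.zeros((n, m), dtype=np.int32)
        for k in ("gt", "dp", "gq", "ad_ref", "ad_alt", "alt_fwd", "alt_rev")
    }
    conc = np.ones((n, m), dtype=bool)
    sites = []
    for i, row in enumerate(rows):
        sites.append((row["contig"], row["pos"], row.get("ref", "A"), row.get("alt", "G")))
        for j, s in enumerate(samples):
            vals = row.get(s, default)
            for k, key in enumerate(("gt", "dp", "gq", "ad_ref", "ad_alt", "alt_fwd", "alt_rev")):
                arrays[key][i, j] = vals[k]
            conc[i, j] = vals[7]
    return GenotypeTable(
        samples=list(samples),
        sites=pd.DataFrame(sites, columns=["contig", "pos", "ref", "alt"]),
        gt=arrays["gt"].astype(np.int8),
        dp=arrays["dp"],
        gq=arrays["gq"],
        ad_ref=arrays["ad_ref"],
        ad_alt=arrays["ad_alt"],
        alt_fwd=arrays["alt_fwd"],
        alt_rev=arrays["alt_rev"],
        concordant=conc,
        contigs=contigs or {},
    )


def nuclear_pedigree() -> tuple[Pedigree, Trio]:
    ped = Pedigree()
    ped.add(Individual("dad", MALE))
    ped.add(Individual("mom", FEMALE))
    ped.add(Individual("kid", MALE, "dad", "mom"))
    return ped, Trio("kid", "dad", "mom", 20.0, 15.0)


SMALL_SIM = SimConfig(
    n_trios=4,
    genome=[
        ("chr1", 400_000, False),
        ("chr2", 400_000, False),
        ("chrX", 200_000, True),
    ],
    seed=5,
    n_third_generation=2,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A 4-trio cohort with third-generation offspring, shared across tests."""
    return simulate_cohort(SMALL_SIM)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort: every true DNM should be callable and called."""
    cfg = SimConfig(
        n_trios=3,
        genome=[("chr1", 300_000, False), ("chr2", 300_000, False)],
        seed=11,
        gq_fail_rate=0.0,
        alt_error_rate=0.0,
        caller_discordance_rate=0.0,
        ab_concentration=400.0,
        diploid_callable_fraction=1.0,
    )
    return simulate_cohort(cfg)
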