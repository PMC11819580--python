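"""Pedigree data model and PLINK PED I/O.

A :class:`Pedigree` is a collection of :class:`Individual` records with
optional parent links.  A :class:`Trio` is a (child, father, mother)
unit — the unit at which de novo mutations are called — annotated with
the parental ages at the child's conception.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

log = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

_SEX_CODES = {"1": MALE, "2": FEMALE}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycles, sex conflicts, ...)."""


@dataclass
class Individual:
    id: str
    sex: str = UNKNOWN
    father_id: str | None = None
    mother_id: str | None = None
    family_id: str = "0"

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


@dataclass(frozen=True)
class Trio:
    child_id: str
    father_id: str
    mother_id: str
    paternal_age: float | None = None
    maternal_age: float | None = None

    def __post_init__(self) -> None:
        for age in (self.paternal_age, self.maternal_age):
            if age is not None and not age > 0:
                raise PedigreeError(f"non-positive parental age for {self.child_id}")


@dataclass
class Pedigree:
    individuals: dict[str, Individual] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def add(self, ind: Individual) -> None:
        self.individuals[ind.id] = ind

    @property
    def founders(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.is_founder]

    def children_of(self, iid: str) -> list[Individual]:
        return [
            i
            for i in self.individuals.values()
            if iid in (i.father_id, i.mother_id)
        ]

    def validate(self) -> None:
        """Raise :class:`PedigreeError` on sex conflicts or cyclic ancestry."""
        fathers = {i.father_id for i in self.individuals.values() if i.father_id}
        mothers = {i.mother_id for i in self.individuals.values() if i.mother_id}
        both = fathers & mothers
        if both:
            raise PedigreeError(f"used as both father and mother: {sorted(both)}")
        for iid, ind in self.individuals.items():
            if ind.father_id and ind.father_id in self.individuals:
                if self.individuals[ind.father_id].sex == FEMALE:
                    raise PedigreeError(f"father {ind.father_id} of {iid} is female")
            if ind.mother_id and ind.mother_id in self.individuals:
                if self.individuals[ind.mother_id].sex == MALE:
                    raise PedigreeError(f"mother {ind.mother_id} of {iid} is male")
        # cycle check by DFS over parent links
        WHITE, GRAY, BLACK = 0, 1, 2
        color = {iid: WHITE for iid in self.individuals}

        def visit(iid: str, stack: list[str]) -> None:
            color[iid] = GRAY
            ind = self.individuals[iid]
            for pid in (ind.father_id, ind.mother_id):
                if pid is None or pid not in self.individuals:
                    continue
                if color[pid] == GRAY:
                    raise PedigreeError(f"cyclic ancestry through {pid}")
                if color[pid] == WHITE:
                    visit(pid, stack + [pid])
            color[iid] = BLACK

        for iid in self.individuals:
            if color[iid] == WHITE:
                visit(iid, [iid])


def read_pedigree(path: str | Path) -> Pedigree:
    """Read a six-column PLINK PED file (family, id, father, mother, sex, phenotype).

    Unknown parents are coded ``0``.  Sex codes 1/2 map to male/female;
    anything else is recorded as unknown.
    """
    ped = Pedigree()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected 6 columns, got {len(fields)}")
            fam, iid, fid, mid, sex, _pheno = fields[:6]
            ped.add(
                Individual(
                    id=iid,
                    sex=_SEX_CODES.get(sex, UNKNOWN),
                    father_id=None if fid == "0" else fid,
                    mother_id=None if mid == "0" else mid,
                    family_id=fam,
                )
            )
    ped.validate()
    return ped


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind in ped.individuals.values():
            sex = {MALE: "1", FEMALE: "2"}.get(ind.sex, "0")
            fh.write(
                f"{ind.family_id}\t{ind.id}\t{ind.father_id or 0}\t"
                f"{ind.mother_id or 0}\t{sex}\t-9\n"
            )


def read_ages(path: str | Path) -> pd.DataFrame:
    """Read a TSV of parental ages: child_id, paternal_age, maternal_age."""
    return pd.read_csv(path, sep="\t", dtype={"child_id": str})


def enumerate_trios(
    ped: Pedigree, ages: pd.DataFrame | Mapping[str, tuple[float, float]] | None = None
) -> list[Trio]:
    """One :class:`Trio` per child whose two parents are both in the pedigree.

    Children with exactly one in-pedigree parent are skipped with a
    warning.  Siblings yield separate trios, and an individual mating with
    several partners yields one trio per offspring.
    """
    age_map: dict[str, tuple[float | None, float | None]] = {}
    if isinstance(ages, pd.DataFrame):
        for row in ages.itertuples(index=False):
            pat = getattr(row, "paternal_age", None)
            mat = getattr(row, "maternal_age", None)
            age_map[str(row.child_id)] = (
                None if pd.isna(pat) else float(pat),
                None if pd.isna(mat) else float(mat),
            )
    elif ages is not None:
        age_map = {k: (v[0], v[1]) for k, v in ages.items()}

    trios: list[Trio] = []
    for ind in ped.individuals.values():
        n_known = sum(p is not None and p in ped for p in (ind.father_id, ind.mother_id))
        if n_known == 0:
            continue
        if n_known == 1:
            log.warning("child %s has exactly one in-pedigree parent; skipped", ind.id)
            continue
        pat_age, mat_age = age_map.get(ind.id, (None, None))
        trios.append(
            Trio(
                child_id=ind.id,
                father_id=ind.father_id,  # type: ignore[arg-type]
                mother_id=ind.mother_id,  # type: ignore[arg-type]
                paternal_age=pat_age,
                maternal_age=mat_age,
            )
        )
    return trios


def third_generation_pairs(ped: Pedigree, trios: Iterable[Trio]) -> dict[str, list[str]]:
    """Map trio children to their own offspring present in the pedigree."""
    out: dict[str, list[str]] = {}
    for trio in trios:
        kids = [c.id for c in ped.children_of(trio.child_id)]
        if kids:
            out[trio.child_id] = sorted(kids)
    return out
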