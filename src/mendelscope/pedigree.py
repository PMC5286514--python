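"""Pedigree parsing and family-role queries.

Reads the 6-column PED convention (family, individual, father, mother,
sex, phenotype; phenotype 2 = affected, 1 = unaffected, 0/-9 = unknown)
and exposes the role lookups every inheritance model needs: the affected
set, the parents of an individual, and full siblings.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable


class PedigreeError(ValueError):
    """Raised for malformed or inconsistent pedigree input."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Phenotype(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


_SEX_CODES = {"1": Sex.MALE, "2": Sex.FEMALE}
_PHENO_CODES = {"2": Phenotype.AFFECTED, "1": Phenotype.UNAFFECTED}


@dataclass(frozen=True)
class Sample:
    """One individual: ids of both parents are None for founders."""

    sample_id: str
    family_id: str
    father_id: str | None
    mother_id: str | None
    sex: Sex
    affected: Phenotype

    @property
    def is_founder(self) -> bool:
        return self.father_id is None and self.mother_id is None


class Pedigree:
    """An ordered collection of samples from a single family.

    Sample order follows the input file and defines the default column
    order expected in genotype matrices (a VCF header's own order wins
    on conflict — the VCF is authoritative for its columns).
    """

    def __init__(self, samples: Iterable[Sample]):
        self.samples: list[Sample] = list(samples)
        self._by_id: dict[str, Sample] = {}
        families = set()
        for s in self.samples:
            if not s.sample_id:
                raise PedigreeError("empty sample id")
            if s.sample_id in self._by_id:
                raise PedigreeError(f"duplicate sample id {s.sample_id!r}")
            self._by_id[s.sample_id] = s
            families.add(s.family_id)
        if len(families) > 1:
            raise PedigreeError(
                f"multiple families in one pedigree: {sorted(families)}"
            )
        for s in self.samples:
            for pid, role in ((s.father_id, "father"), (s.mother_id, "mother")):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"sample {s.sample_id!r} references absent {role} id {pid!r}"
                    )
        self._check_no_ancestry_cycle()

    def _check_no_ancestry_cycle(self) -> None:
        # a sample must never be its own ancestor
        for s in self.samples:
            seen = set()
            stack = [p for p in (s.father_id, s.mother_id) if p]
            while stack:
                pid = stack.pop()
                if pid == s.sample_id:
                    raise PedigreeError(
                        f"sample {s.sample_id!r} is its own ancestor"
                    )
                if pid in seen:
                    continue
                seen.add(pid)
                p = self._by_id[pid]
                stack.extend(q for q in (p.father_id, p.mother_id) if q)

    # -- lookups -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.samples)

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    def __getitem__(self, sample_id: str) -> Sample:
        try:
            return self._by_id[sample_id]
        except KeyError:
            raise PedigreeError(f"unknown sample id {sample_id!r}") from None

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def founders(self) -> list[Sample]:
        return [s for s in self.samples if s.is_founder]

    @property
    def affected(self) -> list[Sample]:
        return [s for s in self.samples if s.affected is Phenotype.AFFECTED]

    @property
    def unaffected(self) -> list[Sample]:
        return [s for s in self.samples if s.affected is Phenotype.UNAFFECTED]

    def serialize(self) -> str:
        """Render back to 6-column PED text (inverse of :func:`parse_ped`)."""
        sex_code = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
        phe_code = {
            Phenotype.AFFECTED: "2",
            Phenotype.UNAFFECTED: "1",
            Phenotype.UNKNOWN: "0",
        }
        lines = []
        for s in self.samples:
            lines.append(
                "\t".join(
                    [
                        s.family_id,
                        s.sample_id,
                        s.father_id or "0",
                        s.mother_id or "0",
                        sex_code[s.sex],
                        phe_code[s.affected],
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def parse_ped(source: str | Path) -> Pedigree:
    """Parse PED text (or a path to a PED file) into a validated Pedigree.

    Lines starting with '#' are comments; fields are tab- or
    space-delimited; at least 6 columns are required. Parent id '0'
    means no parent recorded.
    """
    if isinstance(source, Path):
        text = source.read_text()
    elif "\n" not in source and Path(source).is_file():
        text = Path(source).read_text()
    else:
        text = source

    samples = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise PedigreeError(
                f"line {lineno}: expected >=6 columns, got {len(fields)}"
            )
        fam, sid, fid, mid, sex, phe = fields[:6]
        samples.append(
            Sample(
                sample_id=sid,
                family_id=fam,
                father_id=None if fid == "0" else fid,
                mother_id=None if mid == "0" else mid,
                sex=_SEX_CODES.get(sex, Sex.UNKNOWN),
                affected=_PHENO_CODES.get(phe, Phenotype.UNKNOWN),
            )
        )
    return Pedigree(samples)


def roles_of(
    pedigree: Pedigree, sample_id: str
) -> tuple[Sample | None, Sample | None, set[str]]:
    """Return (father, mother, sibling ids) for one individual.

    Siblings share *both* parent ids with the query sample (founders,
    having no recorded parents, therefore have no siblings; a spouse is
    never a sibling).
    """
    s = pedigree[sample_id]
    father = pedigree[s.father_id] if s.father_id else None
    mother = pedigree[s.mother_id] if s.mother_id else None
    siblings: set[str] = set()
    if s.father_id and s.mother_id:
        siblings = {
            t.sample_id
            for t in pedigree.samples
            if t.sample_id != sample_id
            and t.father_id == s.father_id
            and t.mother_id == s.mother_id
        }
    return father, mother, siblings


def require_trio_complete(pedigree: Pedigree) -> None:
    """Check that both parents of every affected member are in the pedigree.

    The recessive / LOH / compound-het models all condition on parental
    genotypes, so this is enforced at model entry rather than at parse.
    """
    if not pedigree.affected:
        raise PedigreeError("pedigree has no affected member")
    for s in pedigree.affected:
        if s.father_id is None or s.mother_id is None:
            raise PedigreeError(
                f"affected sample {s.sample_id!r} lacks a recorded parent; "
                "trio-dependent models need both parents"
            )
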