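"""HGVS mutation-catalog parsing, codon arithmetic, and truncation stats.

Published mutation catalogs mix standard HGVS with house dialects (bare
"fs5" offsets, "del56" counts, inserted-sequence edits with no keyword),
so the parsers here are deliberately tolerant: each entry records what
was normalized, and unparseable entries are excluded from statistics
with a logged count rather than silently dropped.

Coordinate conventions: cDNA (c.) positions count from the A of the
initiator ATG as 1, so the 1-based codon containing c.N is ceil(N/3).
Frameshift descriptions follow the fsTer_k / fsX_k convention in which
the substituted residue is position 1 of the new reading frame, hence a
frameshift starting at codon S with fsTer_k terminates at codon
S + k - 1.

Two truncation measures are exposed: the fraction of entries whose
protein description carries an explicit stop token (Ter/X), and the
broader biological measure that also counts frameshifts written without
a stop token. Catalogs that summarize "truncating" fractions may use
either convention, so both are computed.
"""

from __future__ import annotations

import enum
import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)


class HgvsError(ValueError):
    """Raised when an HGVS description cannot be parsed."""


class EditType(enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    INSERTION = "insertion"
    DUPLICATION = "duplication"
    DELINS = "delins"
    INDEL_AMBIGUOUS = "indel_ambiguous"


class ProteinClass(enum.Enum):
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    MISSENSE = "missense"
    INFRAME_DEL = "inframe_del"
    INFRAME_DUP = "inframe_dup"
    OTHER = "other"


# -- codon arithmetic -------------------------------------------------------


def codon_index(cdna_pos: int) -> int:
    """1-based codon containing a CDS position (A of ATG = 1): ceil(N/3)."""
    if cdna_pos < 1:
        raise HgvsError(f"CDS position must be >= 1, got {cdna_pos}")
    return math.ceil(cdna_pos / 3)


def fs_termination_codon(start_codon: int, ter_offset: int) -> int:
    """Codon at which a frameshift fsTer_k / fsX_k description terminates.

    The substituted residue is position 1 of the new frame, so the stop
    lands at start_codon + ter_offset - 1. An offset of 1 would mean the
    first novel residue is already a stop, which HGVS writes as a plain
    nonsense change, not a frameshift — hence ter_offset >= 2.
    """
    if start_codon < 1:
        raise HgvsError(f"start codon must be >= 1, got {start_codon}")
    if ter_offset < 2:
        raise HgvsError(
            f"fsTer offset must be >= 2 (got {ter_offset}); fsTer1 is not a "
            "frameshift description"
        )
    return start_codon + ter_offset - 1


# -- cDNA parsing -----------------------------------------------------------

_CDNA_PATTERNS: list[tuple[re.Pattern[str], EditType]] = [
    (re.compile(r"^(\d+)([ACGT])>([ACGT])$"), EditType.SUBSTITUTION),
    (re.compile(r"^(\d+)_(\d+)ins([ACGT]+)$"), EditType.INSERTION),
    (re.compile(r"^(\d+)(?:_(\d+))?dup([ACGT]*)$"), EditType.DUPLICATION),
    (re.compile(r"^(\d+)(?:_(\d+))?delins([ACGT]+)$"), EditType.DELINS),
    (re.compile(r"^(\d+)(?:_(\d+))?del([ACGT]+|\d+)?$"), EditType.DELETION),
    # house dialect: "N_MSEQ" — a range followed by bare sequence, with no
    # del/ins keyword; treated as an ambiguous edit spanning N_M
    (re.compile(r"^(\d+)_(\d+)([ACGT]+)$"), EditType.INDEL_AMBIGUOUS),
]


def parse_cdna_hgvs(text: str) -> tuple[tuple[int, int], EditType]:
    """Parse a (possibly dialectal) c. description to positions and type.

    Internal whitespace is tolerated anywhere (published tables break
    descriptions across lines). Returns ((start, end), edit_type) with
    1-based CDS coordinates, end == start for single-position edits.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact.startswith("c."):
        raise HgvsError(f"not a cDNA description: {text!r}")
    body = compact[2:]
    for pattern, edit_type in _CDNA_PATTERNS:
        m = pattern.match(body)
        if m:
            start = int(m.group(1))
            end = int(m.group(2)) if pattern.groups >= 2 and m.group(2) and m.group(2).isdigit() else start
            if start < 1 or end < start:
                raise HgvsError(f"invalid position range in {text!r}")
            return (start, end), edit_type
    raise HgvsError(f"unparseable cDNA description: {text!r}")


# -- protein parsing --------------------------------------------------------

_AA3 = (
    "Ala Arg Asn Asp Cys Gln Glu Gly His Ile Leu Lys Met Phe Pro Ser Thr "
    "Trp Tyr Val Sec Pyl Ter"
).split()
_AA3_TO_1 = dict(
    zip(_AA3, "A R N D C Q E G H I L K M F P S T W Y V U O *".split())
)

_P_FS3 = re.compile(
    r"^([A-Z][a-z]{2})(\d+)(?:[A-Z][a-z]{2})?fs(?:(Ter|X)(\d+)?|(\d+))?$"
)
_P_FS1 = re.compile(r"^([A-Z])(\d+)([A-Z])?fs(?:(Ter|X)(\d+)?|(\d+))?$")
_P_NONSENSE3 = re.compile(r"^([A-Z][a-z]{2})(\d+)(?:Ter|X|\*)$")
_P_NONSENSE1 = re.compile(r"^([A-Z])(\d+)(?:X|\*)$")
_P_MISSENSE3 = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})$")
_P_MISSENSE1 = re.compile(r"^([A-Z])(\d+)([A-Z])$")
_P_RANGE_EDIT3 = re.compile(
    r"^([A-Z][a-z]{2})(\d+)(?:_([A-Z][a-z]{2})(\d+))?(del|dup)$"
)


def parse_protein_hgvs(text: str) -> tuple[ProteinClass, bool, int]:
    """Parse a p. description to (class, explicit stop token?, residue).

    Both three-letter (Arg1104Ter) and one-letter (R1104X) dialects are
    accepted; Ter, X and * are equivalent stop tokens. The residue index
    returned is the first affected residue.
    """
    compact = re.sub(r"\s+", "", text)
    if not compact.startswith("p."):
        raise HgvsError(f"not a protein description: {text!r}")
    body = compact[2:].strip("()")

    for fs_pat in (_P_FS3, _P_FS1):
        m = fs_pat.match(body)
        if m:
            explicit_ter = m.group(4) is not None  # a Ter/X token after fs
            return ProteinClass.FRAMESHIFT, explicit_ter, int(m.group(2))
    for ns_pat in (_P_NONSENSE3, _P_NONSENSE1):
        m = ns_pat.match(body)
        if m:
            return ProteinClass.NONSENSE, True, int(m.group(2))
    m = _P_RANGE_EDIT3.match(body)
    if m:
        cls = ProteinClass.INFRAME_DEL if m.group(5) == "del" else ProteinClass.INFRAME_DUP
        return cls, False, int(m.group(2))
    for ms_pat in (_P_MISSENSE3, _P_MISSENSE1):
        m = ms_pat.match(body)
        if m:
            return ProteinClass.MISSENSE, False, int(m.group(2))
    raise HgvsError(f"unparseable protein description: {text!r}")


def aa3_to_1(token: str) -> str:
    try:
        return _AA3_TO_1[token]
    except KeyError:
        raise HgvsError(f"unknown amino-acid token {token!r}") from None


# -- catalog ----------------------------------------------------------------


@dataclass(frozen=True)
class CatalogEntry:
    cdna_hgvs: str
    protein_hgvs: str
    cdna_positions: tuple[int, int]
    edit_type: EditType
    protein_class: ProteinClass
    explicit_ter: bool
    residue_index: int

    @property
    def truncating(self) -> bool:
        """Explicit stop token, or a frameshift (biologically truncating)."""
        return self.explicit_ter or self.protein_class is ProteinClass.FRAMESHIFT


def parse_catalog_entry(cdna: str, protein: str) -> CatalogEntry:
    positions, edit_type = parse_cdna_hgvs(cdna)
    protein_class, explicit_ter, residue = parse_protein_hgvs(protein)
    return CatalogEntry(
        cdna_hgvs=cdna.strip(),
        protein_hgvs=protein.strip(),
        cdna_positions=positions,
        edit_type=edit_type,
        protein_class=protein_class,
        explicit_ter=explicit_ter,
        residue_index=residue,
    )


def read_catalog(path: str | Path) -> tuple[list[CatalogEntry], list[tuple[str, str, str]]]:
    """Read a dna_change/protein_change TSV into parsed entries.

    Returns (entries, failures); each failure is (dna, protein, reason)
    and the count is logged.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if not {"dna_change", "protein_change"} <= set(df.columns):
        raise HgvsError(
            f"catalog {path} must have dna_change and protein_change columns"
        )
    entries, failures = [], []
    for row in df.itertuples():
        try:
            entries.append(parse_catalog_entry(row.dna_change, row.protein_change))
        except HgvsError as exc:
            failures.append((row.dna_change, row.protein_change, str(exc)))
    if failures:
        logger.warning("%s: %d unparseable catalog entries excluded", path, len(failures))
    return entries, failures


def load_lyst_catalog() -> list[CatalogEntry]:
    """The packaged LYST pathogenic-variant catalog (41 published alleles)."""
    with resources.as_file(
        resources.files("mendelscope.data") / "lyst_table1.tsv"
    ) as p:
        entries, failures = read_catalog(p)
    if failures:
        raise HgvsError(f"packaged catalog has unparseable rows: {failures}")
    return entries


@dataclass(frozen=True)
class CatalogStats:
    n_entries: int
    min_cdna_pos: int
    max_cdna_pos: int
    ter_fraction: float  # percent of entries with an explicit Ter/X stop
    truncating_fraction: float  # percent truncating incl. bare frameshifts


def catalog_stats(entries: list[CatalogEntry]) -> CatalogStats:
    """Span and truncation summary of a catalog (percentages in [0,100])."""
    if not entries:
        raise HgvsError("catalog_stats needs at least one entry")
    starts = [e.cdna_positions[0] for e in entries]
    ends = [e.cdna_positions[1] for e in entries]
    n = len(entries)
    n_ter = sum(e.explicit_ter for e in entries)
    n_trunc = sum(e.truncating for e in entries)
    return CatalogStats(
        n_entries=n,
        min_cdna_pos=min(starts),
        max_cdna_pos=max(ends),
        ter_fraction=100.0 * n_ter / n,
        truncating_fraction=100.0 * n_trunc / n,
    )


def catalog_consistency(entries: list[CatalogEntry]) -> list[tuple[CatalogEntry, int, int]]:
    """Cross-check cDNA and protein coordinates of each entry.

    Returns entries where codon_index(cdna start) differs from the
    protein's first affected residue, as (entry, codon_from_cdna,
    residue_from_protein). Insertions and duplications at codon
    boundaries legitimately differ by one (the first *changed* residue
    is the next codon), so mismatches are reported for review rather
    than treated as errors.
    """
    mismatches = []
    for e in entries:
        expected = codon_index(e.cdna_positions[0])
        if expected != e.residue_index:
            mismatches.append((e, expected, e.residue_index))
    return mismatches
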