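"""Variant call-set reading, normalization, and dual-caller consensus.

The consensus operation is the reliability filter of the screen: only
variants called independently by both pipelines at the same normalized
(chrom, pos, ref, alt) key are retained. Correctness of the intersection
therefore rests on the two normalization primitives here — multiallelic
splitting and left-normalization to the minimal VCF representation.

Coordinates are 1-based inclusive everywhere a VCF position is exposed;
chromosome names compare equal after stripping an optional "chr" prefix.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import pysam

from .pedigree import Pedigree

logger = logging.getLogger(__name__)


class VariantError(ValueError):
    """Raised for malformed or inconsistent variant input."""


class GenotypeCall(enum.Enum):
    """Unphased biallelic diploid genotype (after multiallelic splitting)."""

    HOM_REF = "0/0"
    HET = "0/1"
    HOM_ALT = "1/1"
    MISSING = "./."

    @property
    def alt_dosage(self) -> int | None:
        return {"0/0": 0, "0/1": 1, "1/1": 2, "./.": None}[self.value]

    def carries_alt(self) -> bool:
        return self in (GenotypeCall.HET, GenotypeCall.HOM_ALT)


def norm_chrom(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


VariantKey = tuple[str, int, str, str]


@dataclass
class VariantRecord:
    """One normalized biallelic variant with per-sample genotypes."""

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    id: str | None = None
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    callers: frozenset[str] = frozenset()
    secondary_genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise VariantError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise VariantError("empty allele")
        if self.ref == self.alt:
            raise VariantError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> VariantKey:
        return (norm_chrom(self.chrom), self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # e.g. chr1:235969126G>A
        return f"{self.chrom}:{self.pos}{self.ref}>{self.alt}"


# -- raw records and multiallelic splitting --------------------------------


@dataclass
class RawVariant:
    """A possibly multiallelic site as read from a VCF, GT field only.

    ``genotype_indices`` maps sample id to the tuple of allele indices
    from the GT field (0 = ref, k = k-th alt), or None where the call is
    fully or partially missing (half-calls are conservatively missing).
    """

    chrom: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    id: str | None
    genotype_indices: dict[str, tuple[int, int] | None]


def split_multiallelic(raw: RawVariant, caller_label: str = "") -> list[VariantRecord]:
    """Decompose one site into one biallelic record per alt allele.

    For each alt k the diploid genotype is recoded by the dosage of
    allele k alone: a genotype referencing a *different* alt contributes
    reference dosage for this record (e.g. GT 1/2 is het for both the
    first and the second alt; 2/2 is hom_ref for the first alt and
    hom_alt for the second). Total alt dosage per sample is conserved
    across the split records.
    """
    out = []
    for k, alt in enumerate(raw.alts, start=1):
        if alt in ("*", "<NON_REF>") or alt.startswith("<"):
            continue  # spanning-deletion / symbolic alleles are out of scope
        genotypes = {}
        for sample, gt in raw.genotype_indices.items():
            if gt is None:
                genotypes[sample] = GenotypeCall.MISSING
            else:
                dosage = sum(1 for a in gt if a == k)
                genotypes[sample] = {
                    0: GenotypeCall.HOM_REF,
                    1: GenotypeCall.HET,
                    2: GenotypeCall.HOM_ALT,
                }[dosage]
        out.append(
            VariantRecord(
                chrom=raw.chrom,
                pos=raw.pos,
                ref=raw.ref,
                alt=alt,
                id=raw.id,
                genotypes=genotypes,
                callers=frozenset({caller_label} if caller_label else ()),
            )
        )
    return out


def read_vcf(path: str | Path, pedigree: Pedigree, caller_label: str) -> list[VariantRecord]:
    """Read a multi-sample VCF into split biallelic records, GT only.

    The VCF header's sample columns must cover every pedigree sample;
    extra columns are ignored. Malformed or half genotype calls become
    missing (counted and logged). All FORMAT fields other than GT are
    ignored.
    """
    vf = pysam.VariantFile(str(path))
    header_samples = list(vf.header.samples)
    missing = [s for s in pedigree.sample_ids if s not in header_samples]
    if missing:
        raise VariantError(
            f"pedigree samples absent from VCF header of {path}: {missing}"
        )
    wanted = [s for s in header_samples if s in pedigree.sample_ids]

    records: list[VariantRecord] = []
    n_bad_gt = 0
    for rec in vf:
        gts: dict[str, tuple[int, int] | None] = {}
        for sample in wanted:
            try:
                alleles = rec.samples[sample].get("GT")
            except Exception:
                alleles = None
            if (
                alleles is None
                or len(alleles) != 2
                or any(a is None for a in alleles)
            ):
                if alleles is not None and any(a is not None for a in alleles):
                    n_bad_gt += 1  # half-call -> missing, conservatively
                gts[sample] = None
            else:
                gts[sample] = (alleles[0], alleles[1])
        raw = RawVariant(
            chrom=rec.chrom,
            pos=rec.pos,  # pysam exposes the 1-based VCF POS here
            ref=rec.ref,
            alts=tuple(rec.alts or ()),
            id=rec.id,
            genotype_indices=gts,
        )
        records.extend(split_multiallelic(raw, caller_label))
    if n_bad_gt:
        logger.warning("%s: %d half/malformed GT calls set to missing", path, n_bad_gt)
    return records


# -- normalization ----------------------------------------------------------


@dataclass(frozen=True)
class ReferenceWindow:
    """A slice of reference sequence anchored at a 1-based position."""

    start: int  # 1-based genomic position of seq[0]
    seq: str

    def base(self, pos: int) -> str:
        i = pos - self.start
        if i < 0 or i >= len(self.seq):
            raise VariantError(f"position {pos} outside reference window")
        return self.seq[i].upper()

    def slice(self, pos: int, length: int) -> str:
        return "".join(self.base(pos + i) for i in range(length))


def left_normalize(
    record: VariantRecord, window: ReferenceWindow | None = None
) -> VariantRecord:
    """Reduce a record to its minimal, left-aligned VCF representation.

    Trailing then leading shared bases are trimmed; with a reference
    window, indels are additionally shifted left as far as the preceding
    reference sequence allows (the classic left-alignment loop), keeping
    the VCF anchor base for pure insertions/deletions. Without a window
    only the reference-free trimming is performed. Idempotent.
    """
    pos, ref, alt = record.pos, record.ref.upper(), record.alt.upper()
    if window is not None and window.slice(pos, len(ref)) != ref:
        raise VariantError(
            f"ref allele {ref} disagrees with reference at {record.chrom}:{pos}"
        )

    # trim shared trailing bases, extending left from the reference when
    # an allele would otherwise become empty
    while ref and alt and ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if window is None or pos - 1 < window.start:
                break  # no reference context left to shift across
            prev = window.base(pos - 1)
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
        else:
            ref = ref[:-1]
            alt = alt[:-1]

    # trim shared leading bases, keeping the anchor for pure indels
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref = ref[1:]
        alt = alt[1:]
        pos += 1

    if (pos, ref, alt) == (record.pos, record.ref, record.alt):
        return record
    return replace(record, pos=pos, ref=ref, alt=alt)


# -- consensus --------------------------------------------------------------


def _index_by_key(records: list[VariantRecord], label: str) -> dict[VariantKey, VariantRecord]:
    idx: dict[VariantKey, VariantRecord] = {}
    for r in records:
        if r.key in idx:
            raise VariantError(
                f"duplicate key {r.key} within call set {label!r}: "
                "normalize and split before intersecting"
            )
        idx[r.key] = r
    return idx


def intersect_callsets(
    set_a: list[VariantRecord], set_b: list[VariantRecord]
) -> list[VariantRecord]:
    """Consensus of two callers: records present in both by normalized key.

    Genotypes come from set_a (the primary caller); set_b's genotypes
    are kept as a secondary annotation so per-sample discordance can be
    reported downstream. Output is sorted by (chrom, pos, ref, alt).
    """
    idx_a = _index_by_key(set_a, "A")
    idx_b = _index_by_key(set_b, "B")
    out = []
    for key in sorted(set(idx_a) & set(idx_b)):
        a, b = idx_a[key], idx_b[key]
        out.append(
            replace(
                a,
                callers=a.callers | b.callers,
                secondary_genotypes=dict(b.genotypes),
            )
        )
    return out


def discordant_samples(record: VariantRecord) -> list[str]:
    """Samples whose genotype differs between the two callers (GT_DISCORDANT)."""
    if not record.secondary_genotypes:
        return []
    return sorted(
        s
        for s, g in record.genotypes.items()
        if s in record.secondary_genotypes and record.secondary_genotypes[s] is not g
    )


def write_vcf(
    records: list[VariantRecord],
    pedigree: Pedigree,
    path: str | Path,
    source: str = "mendelscope",
) -> None:
    """Write biallelic records as a minimal GT-only VCF 4.2 file."""
    samples = pedigree.sample_ids
    contigs = sorted({r.chrom for r in records})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for r in records:
            gts = "\t".join(
                (r.genotypes.get(s, GenotypeCall.MISSING)).value for s in samples
            )
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id or '.'}\t{r.ref}\t{r.alt}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )
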