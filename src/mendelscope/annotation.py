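"""Population-frequency and functional-consequence annotation.

Each consensus variant is classified against a strand-aware gene model
(transcripts with TSS, exons, CDS, plus spliced CDS sequences) and a
reference-cohort allele-frequency table. The screen keeps rare variants
(MAF below threshold, or absent from the table — novel implies rare) and
routes them into two streams: a coding stream of protein-disrupting
consequences and a regulatory stream of upstream (< 1 kb to the TSS) and
5' UTR variants checked against transcription-factor binding sites.

The CDS FASTA is authoritative for codon translation, so no whole-genome
reference is required. The standard genetic code is assumed throughout.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .variants import VariantError, VariantRecord, norm_chrom


class AnnotationError(ValueError):
    pass


class Consequence(enum.Enum):
    STOPGAIN = "stopgain"
    STOPLOSS = "stoploss"
    FRAMESHIFT_INSERTION = "frameshift_insertion"
    FRAMESHIFT_DELETION = "frameshift_deletion"
    SPLICE_SITE = "splice_site"
    MISSENSE = "missense"
    SYNONYMOUS = "synonymous"
    NONFRAMESHIFT_INDEL = "nonframeshift_indel"
    UTR5 = "utr5"
    UTR3 = "utr3"
    INTRONIC = "intronic"
    UPSTREAM = "upstream"
    INTERGENIC = "intergenic"


#: most-severe-first ordering used to pick one reported consequence per
#: variant when several transcripts overlap (ANNOVAR-like behaviour)
SEVERITY_ORDER = [
    Consequence.STOPGAIN,
    Consequence.STOPLOSS,
    Consequence.FRAMESHIFT_INSERTION,
    Consequence.FRAMESHIFT_DELETION,
    Consequence.SPLICE_SITE,
    Consequence.MISSENSE,
    Consequence.SYNONYMOUS,
    Consequence.NONFRAMESHIFT_INDEL,
    Consequence.UTR5,
    Consequence.UTR3,
    Consequence.INTRONIC,
    Consequence.UPSTREAM,
    Consequence.INTERGENIC,
]
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

#: categories retained in the coding candidate stream
CODING_RETAINED = frozenset(
    {
        Consequence.STOPGAIN,
        Consequence.STOPLOSS,
        Consequence.MISSENSE,
        Consequence.FRAMESHIFT_INSERTION,
        Consequence.FRAMESHIFT_DELETION,
        Consequence.SPLICE_SITE,
    }
)

#: categories diverted to the regulatory candidate stream
REGULATORY = frozenset({Consequence.UPSTREAM, Consequence.UTR5})


@dataclass
class Transcript:
    """A strand-aware transcript with its spliced CDS sequence.

    ``exons`` are 1-based inclusive genomic intervals in genomic order;
    ``cds_start``/``cds_end`` delimit the genomic CDS extent; and
    ``cds_sequence`` is the spliced CDS read 5'→3' in coding orientation
    (for a − strand transcript, the reverse complement of the genomic
    CDS bases).
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]
    cds_start: int
    cds_end: int
    cds_sequence: str

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds_sequence = self.cds_sequence.upper()
        last = 0
        for s, e in self.exons:
            if s <= last:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            last = e
        if len(self.cds_sequence) % 3 != 0:
            raise AnnotationError(
                f"{self.transcript_id}: CDS length {len(self.cds_sequence)} "
                "not a multiple of 3"
            )
        if len(self.cds_sequence) != self._genomic_cds_len():
            raise AnnotationError(
                f"{self.transcript_id}: CDS sequence length "
                f"{len(self.cds_sequence)} != genomic CDS extent "
                f"{self._genomic_cds_len()}"
            )
        self._cds_pos_cache: dict[int, int] | None = None

    def _genomic_cds_len(self) -> int:
        n = 0
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                n += hi - lo + 1
        return n

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start site: the strand-appropriate transcript end."""
        return self.span[0] if self.strand == "+" else self.span[1]

    def _cds_map(self) -> dict[int, int]:
        if self._cds_pos_cache is None:
            genomic = []
            for s, e in self.exons:
                lo, hi = max(s, self.cds_start), min(e, self.cds_end)
                if lo <= hi:
                    genomic.extend(range(lo, hi + 1))
            n = len(genomic)
            if self.strand == "+":
                self._cds_pos_cache = {g: i + 1 for i, g in enumerate(genomic)}
            else:
                self._cds_pos_cache = {g: n - i for i, g in enumerate(genomic)}
        return self._cds_pos_cache

    def cds_position(self, genomic_pos: int) -> int | None:
        """1-based spliced CDS coordinate of a genomic position, or None."""
        return self._cds_map().get(genomic_pos)

    def in_exon(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.exons)

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] - self.exons[i][1] > 1
        ]


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ConsequenceCall:
    variant: VariantRecord
    category: Consequence
    gene: str | None = None
    transcript_id: str | None = None
    cdna_pos: int | None = None
    protein_change: str | None = None

    @property
    def severity(self) -> int:
        return _SEVERITY_RANK[self.category]


# -- gene-model input -------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(gtf_path: str | Path, cds_fasta_path: str | Path) -> list[Transcript]:
    """Load transcripts from a GTF subset plus a spliced-CDS FASTA.

    Only ``exon`` and ``CDS`` features are used, grouped by their
    ``transcript_id`` attribute; the FASTA (keyed by transcript_id) is
    the authority for the coding sequence.
    """
    cds_seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(cds_fasta_path), "fasta")}

    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}  # tid -> (gene, chrom, strand)
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"malformed GTF line: {line.rstrip()!r}")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature not in ("exon", "CDS"):
                continue
            a = dict(_ATTR_RE.findall(attrs))
            tid = a.get("transcript_id")
            if tid is None:
                raise AnnotationError(f"GTF feature without transcript_id: {line!r}")
            gene = a.get("gene_name") or a.get("gene_id") or tid
            meta.setdefault(tid, (gene, chrom, strand))
            target = exons if feature == "exon" else cds
            target.setdefault(tid, []).append((int(start), int(end)))

    transcripts = []
    for tid, (gene, chrom, strand) in meta.items():
        if tid not in cds:
            continue  # non-coding transcripts carry no consequence logic here
        if tid not in cds_seqs:
            raise AnnotationError(f"no CDS sequence in FASTA for {tid}")
        cds_iv = sorted(cds[tid])
        transcripts.append(
            Transcript(
                gene=gene,
                transcript_id=tid,
                chrom=chrom,
                strand=strand,
                exons=sorted(exons.get(tid, cds_iv)),
                cds_start=cds_iv[0][0],
                cds_end=cds_iv[-1][1],
                cds_sequence=cds_seqs[tid],
            )
        )
    return transcripts


# -- allele-frequency filter ------------------------------------------------


class AlleleFrequencyTable:
    """Reference-cohort minor allele frequencies keyed by variant.

    Missing keys are permitted and mean the variant is novel in the
    cohort (and therefore passes the rare filter).
    """

    def __init__(self, entries: dict[tuple[str, int, str, str], float]):
        for key, af in entries.items():
            if not 0.0 <= af <= 1.0:
                raise AnnotationError(f"AF {af} outside [0,1] for {key}")
        self._af = {
            (norm_chrom(c), p, r, a): af for (c, p, r, a), af in entries.items()
        }

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AlleleFrequencyTable":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            names=["chrom", "pos", "ref", "alt", "af"],
            dtype={"chrom": str},
        )
        return cls(
            {
                (row.chrom, int(row.pos), row.ref, row.alt): float(row.af)
                for row in df.itertuples()
            }
        )

    def lookup(self, variant: VariantRecord) -> float | None:
        return self._af.get(variant.key)

    def __len__(self) -> int:
        return len(self._af)


def rare_filter(
    variants: list[VariantRecord],
    af_table: AlleleFrequencyTable,
    threshold: float = 0.01,
) -> list[VariantRecord]:
    """Keep variants with cohort MAF strictly below threshold or unrecorded.

    The boundary is read literally (af == threshold is removed); absence
    from the table means novel, which passes. A threshold of 0 therefore
    keeps exactly the unrecorded (novel) variants.
    """
    if not 0.0 <= threshold <= 1.0:
        raise AnnotationError(f"MAF threshold must be in [0,1], got {threshold}")
    kept = []
    for v in variants:
        af = af_table.lookup(v)
        if af is None or af < threshold:
            kept.append(v)
    return kept


# -- consequence calling ----------------------------------------------------


def coding_consequence(variant: VariantRecord, transcript: Transcript) -> ConsequenceCall:
    """Classify a CDS-overlapping variant on one transcript.

    SNVs are resolved by translating the affected codon from the spliced
    CDS sequence; indels are classified by length difference modulo 3.
    A variant within 2 bp of an intron edge is a splice-site call and no
    protein change is computed.
    """
    ref_span = (variant.pos, variant.pos + len(variant.ref) - 1)
    for istart, iend in transcript.introns():
        for edge in (istart, istart + 1, iend - 1, iend):
            if ref_span[0] <= edge <= ref_span[1]:
                return ConsequenceCall(
                    variant,
                    Consequence.SPLICE_SITE,
                    gene=transcript.gene,
                    transcript_id=transcript.transcript_id,
                )

    minus = transcript.strand == "-"
    cds = transcript.cds_sequence

    if variant.is_snv:
        c = transcript.cds_position(variant.pos)
        if c is None:
            raise AnnotationError(
                f"{variant} does not overlap the CDS of {transcript.transcript_id}"
            )
        ref_base = revcomp(variant.ref) if minus else variant.ref.upper()
        alt_base = revcomp(variant.alt) if minus else variant.alt.upper()
        if cds[c - 1] != ref_base:
            raise VariantError(
                f"{variant}: ref disagrees with CDS of {transcript.transcript_id} "
                f"at c.{c} ({cds[c - 1]} vs {ref_base})"
            )
        codon_i = (c - 1) // 3  # 0-based codon index
        offset = (c - 1) % 3
        codon = cds[3 * codon_i : 3 * codon_i + 3]
        mutant = codon[:offset] + alt_base + codon[offset + 1 :]
        aa_ref = str(Seq(codon).translate())
        aa_alt = str(Seq(mutant).translate())
        if aa_alt == "*" and aa_ref != "*":
            category = Consequence.STOPGAIN
        elif aa_ref == "*" and aa_alt != "*":
            category = Consequence.STOPLOSS
        elif aa_ref == aa_alt:
            category = Consequence.SYNONYMOUS
        else:
            category = Consequence.MISSENSE
        aa_alt_txt = "X" if aa_alt == "*" else aa_alt
        return ConsequenceCall(
            variant,
            category,
            gene=transcript.gene,
            transcript_id=transcript.transcript_id,
            cdna_pos=c,
            protein_change=f"p.{aa_ref}{codon_i + 1}{aa_alt_txt}",
        )

    # indel / delins
    delta = len(variant.alt) - len(variant.ref)
    if delta % 3 != 0:
        category = (
            Consequence.FRAMESHIFT_INSERTION
            if delta > 0
            else Consequence.FRAMESHIFT_DELETION
        )
    else:
        category = Consequence.NONFRAMESHIFT_INDEL
    # first CDS base touched by the edit, searching the ref span
    cdna_pos = None
    positions = range(ref_span[0], ref_span[1] + 1)
    for p in reversed(positions) if minus else positions:
        c = transcript.cds_position(p)
        if c is not None:
            cdna_pos = c if cdna_pos is None else min(cdna_pos, c)
    if cdna_pos is None:
        raise AnnotationError(
            f"{variant} does not overlap the CDS of {transcript.transcript_id}"
        )
    return ConsequenceCall(
        variant,
        category,
        gene=transcript.gene,
        transcript_id=transcript.transcript_id,
        cdna_pos=cdna_pos,
    )


def _classify_one(
    variant: VariantRecord, tx: Transcript, upstream_bp: int
) -> ConsequenceCall | None:
    if norm_chrom(tx.chrom) != norm_chrom(variant.chrom):
        return None
    lo, hi = tx.span
    vlo, vhi = variant.pos, variant.pos + len(variant.ref) - 1
    if vhi < lo or vlo > hi:
        # outside the transcript: upstream iff strictly within upstream_bp
        # of the TSS on the 5' side, strand-aware
        dist = tx.tss - vhi if tx.strand == "+" else vlo - tx.tss
        if 0 < dist < upstream_bp:
            return ConsequenceCall(
                variant, Consequence.UPSTREAM, gene=tx.gene, transcript_id=tx.transcript_id
            )
        return None
    # overlaps the transcript body
    overlaps_cds = any(
        tx.cds_position(p) is not None for p in range(vlo, vhi + 1)
    )
    near_splice = any(
        vlo <= edge <= vhi
        for istart, iend in tx.introns()
        for edge in (istart, istart + 1, iend - 1, iend)
    )
    if overlaps_cds:
        # coding_consequence itself demotes to splice_site near intron edges
        return coding_consequence(variant, tx)
    if near_splice:
        return ConsequenceCall(
            variant, Consequence.SPLICE_SITE, gene=tx.gene, transcript_id=tx.transcript_id
        )
    if any(tx.in_exon(p) for p in range(vlo, vhi + 1)):
        # exonic but non-CDS: 5' or 3' UTR in transcription sense
        if tx.strand == "+":
            utr5 = vhi < tx.cds_start
        else:
            utr5 = vlo > tx.cds_end
        cat = Consequence.UTR5 if utr5 else Consequence.UTR3
        return ConsequenceCall(variant, cat, gene=tx.gene, transcript_id=tx.transcript_id)
    return ConsequenceCall(
        variant, Consequence.INTRONIC, gene=tx.gene, transcript_id=tx.transcript_id
    )


def assign_region(
    variant: VariantRecord,
    transcripts: list[Transcript],
    upstream_bp: int = 1000,
) -> ConsequenceCall:
    """One reported consequence per variant: the most severe across
    all overlapping transcripts, intergenic as the total fallback."""
    calls = []
    for tx in transcripts:
        call = _classify_one(variant, tx, upstream_bp)
        if call is not None:
            calls.append(call)
    if not calls:
        return ConsequenceCall(variant, Consequence.INTERGENIC)
    return min(calls, key=lambda c: c.severity)


def consequence_filter(calls: list[ConsequenceCall]) -> list[ConsequenceCall]:
    """The coding stream: keep protein-disrupting categories only.

    Synonymous, non-frameshift indel and noncoding categories are
    removed; upstream and 5' UTR calls belong to the regulatory stream
    and are likewise not retained here.
    """
    return [c for c in calls if c.category in CODING_RETAINED]


def regulatory_stream(calls: list[ConsequenceCall]) -> list[ConsequenceCall]:
    return [c for c in calls if c.category in REGULATORY]


# -- TFBS overlap -----------------------------------------------------------


def read_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Read 0-based half-open BED intervals into per-chromosome trees."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom, start, end = norm_chrom(fields[0]), int(fields[1]), int(fields[2])
            if end > start:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
    return trees


def tfbs_overlap(
    variants: list[VariantRecord], tfbs: dict[str, IntervalTree]
) -> list[VariantRecord]:
    """Variants whose 1-based position falls inside any BED interval.

    BED is 0-based half-open, so 1-based position p overlaps [start,
    end) iff start <= p - 1 < end.
    """
    out = []
    for v in variants:
        tree = tfbs.get(norm_chrom(v.chrom))
        if tree is not None and tree.overlaps(v.pos - 1):
            out.append(v)
    return out
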