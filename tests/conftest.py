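"""Shared fixtures: the worked-example family and its synthetic gene model.

The ``mini_family`` fixture reconstructs, as files, the published worked
example this package is tested against: a five-member nuclear family
(two unaffected parents, one unaffected daughter, two affected
children) carrying a trans-configured compound-het pair in a LYST
surrogate gene — a stop-gain SNV at chr1:235969126 G>A (c.3310C>T,
p.R1104X, paternal) and a frameshift insertion at chr1:235915327 A>AT
(c.7605, maternal) — plus six decoy variants that each exercise one
pipeline filter.

The transcript is a synthetic surrogate (no real LYST sequence is
shipped): a two-exon − strand gene built so that those two genomic
coordinates fall at the published cDNA positions, with the affected
codons forced to CGA (codon 1104, one substitution from a stop) and AAT
(codon 2535, Asn).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pytest

from mendelscope.pedigree import Pedigree, parse_ped
from mendelscope.variants import GenotypeCall, VariantRecord, write_vcf

GT = GenotypeCall
_STOPS = {"TAA", "TAG", "TGA"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

FIG1A_PED = """\
# two-generation family: two affected children, three unaffected members
FAM1\tI-1\t0\t0\t1\t1
FAM1\tI-2\t0\t0\t2\t1
FAM1\tII-1\tI-1\tI-2\t2\t1
FAM1\tII-2\tI-1\tI-2\t2\t2
FAM1\tII-3\tI-1\tI-2\t1\t2
"""

SAMPLES = ["I-1", "I-2", "II-1", "II-2", "II-3"]

# surrogate LYST gene geometry (minus strand, two exons, CDS == exons)
EXON1 = (235_968_436, 235_972_435)  # transcription-first: CDS c.1..4000
EXON2 = (235_915_132, 235_918_931)  # CDS c.4001..7800
N_CODONS = 2600
TSS = EXON1[1]

SG_POS, SG_CDNA = 235_969_126, 3310  # stop-gain site, codon 1104
INS_POS, INS_CDNA = 235_915_327, 7605  # insertion site, codon 2535


def _gts(i1: GT, i2: GT, ii1: GT, ii2: GT, ii3: GT) -> dict[str, GT]:
    return dict(zip(SAMPLES, (i1, i2, ii1, ii2, ii3)))


def build_surrogate_cds(rng: np.random.Generator | None = None) -> str:
    rng = rng or np.random.default_rng(20170201)
    codons = ["ATG"]
    while len(codons) < N_CODONS - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    codons[1103] = "CGA"  # codon 1104: Arg, C>T in place gives TGA (stop)
    codons[2534] = "AAT"  # codon 2535: Asn, its third base is c.7605 = T
    codons[499] = "GGC"  # codon 500: Gly, third-base C>T is synonymous
    return "".join(codons)


def cds_coord(p: int) -> int:
    """Genomic position -> 1-based spliced CDS coordinate (− strand)."""
    if EXON1[0] <= p <= EXON1[1]:
        return EXON1[1] - p + 1
    if EXON2[0] <= p <= EXON2[1]:
        return 4000 + (EXON2[1] - p + 1)
    raise ValueError(f"{p} outside surrogate exons")


@dataclass
class MiniFamily:
    root: Path
    vcf_a: Path
    vcf_b: Path
    ped: Path
    gene_model: Path
    cds_fasta: Path
    af_table: Path
    tfbs_bed: Path
    cds: str
    sg_key: tuple[str, int, str, str]
    ins_key: tuple[str, int, str, str]


def build_mini_family(root: Path) -> MiniFamily:
    root.mkdir(parents=True, exist_ok=True)
    cds = build_surrogate_cds()

    def gbase(p: int) -> str:
        # plus-strand genomic base implied by the coding (−) strand
        return _COMP[cds[cds_coord(p) - 1]]

    assert gbase(SG_POS) == "G" and gbase(INS_POS) == "A"

    v_sg = VariantRecord(
        "chr1", SG_POS, "G", "A", id="rs80338652",
        genotypes=_gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HET, GT.HET),
    )
    v_ins = VariantRecord(
        "chr1", INS_POS, "A", "AT",
        genotypes=_gts(GT.HOM_REF, GT.HET, GT.HET, GT.HET, GT.HET),
    )
    # decoys, one per filter
    p_common = EXON1[1] - 598 + 1  # c.598, removed by the MAF filter
    common_ref = gbase(p_common)
    v_common = VariantRecord(
        "chr1", p_common, common_ref, _COMP[common_ref],
        genotypes=_gts(GT.HET, GT.HOM_REF, GT.HET, GT.HOM_REF, GT.HET),
    )
    v_syn = VariantRecord(  # c.1500, GGC->GGT, dropped as synonymous
        "chr1", EXON1[1] - 1500 + 1, "G", "A",
        genotypes=_gts(GT.HOM_REF, GT.HET, GT.HOM_REF, GT.HET, GT.HET),
    )
    p_del = 235_918_000  # 3-bp in-frame deletion, dropped as nonframeshift
    del_ref = "".join(gbase(p_del + i) for i in range(4))
    v_del = VariantRecord(
        "chr1", p_del, del_ref, del_ref[0],
        genotypes=_gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HET, GT.HOM_REF),
    )
    v_upstream = VariantRecord(  # 365 bp 5' of the − strand TSS
        "chr1", TSS + 365, "A", "G",
        genotypes=_gts(GT.HET, GT.HET, GT.HOM_REF, GT.HET, GT.HOM_REF),
    )
    v_intergenic = VariantRecord(
        "chr1", 235_910_000, "C", "T",
        genotypes=_gts(GT.HOM_REF, GT.HET, GT.HET, GT.HOM_REF, GT.HET),
    )
    p_aonly = EXON1[1] - 1000 + 1  # caller-A private, dropped at consensus
    aonly_ref = gbase(p_aonly)
    v_a_only = VariantRecord(
        "chr1", p_aonly, aonly_ref, _COMP[aonly_ref],
        genotypes=_gts(GT.HET, GT.HET, GT.HET, GT.HET, GT.HET),
    )

    shared = [v_sg, v_ins, v_common, v_syn, v_upstream, v_intergenic]
    # caller B encodes the deletion unnormalized (extra shared trailing
    # base); trimming must reconcile the two representations
    pad = gbase(p_del + 4)
    v_del_b = VariantRecord(
        "chr1", p_del, del_ref + pad, del_ref[0] + pad, genotypes=v_del.genotypes
    )
    records_a = sorted(shared + [v_del, v_a_only], key=lambda r: r.pos)
    records_b = sorted(shared + [v_del_b], key=lambda r: r.pos)

    ped_path = root / "family.ped"
    ped_path.write_text(FIG1A_PED)
    pedigree = parse_ped(ped_path)
    vcf_a, vcf_b = root / "caller_a.vcf", root / "caller_b.vcf"
    write_vcf(records_a, pedigree, vcf_a, source="fixture_caller_a")
    write_vcf(records_b, pedigree, vcf_b, source="fixture_caller_b")

    gtf = root / "genes.gtf"
    attrs = 'gene_id "LYST"; transcript_id "NM_000081_surrogate";'
    lines = []
    for feature in ("exon", "CDS"):
        for start, end in (EXON2, EXON1):
            lines.append(
                f"chr1\tsynthetic\t{feature}\t{start}\t{end}\t.\t-\t.\t{attrs}"
            )
    gtf.write_text("\n".join(lines) + "\n")
    fasta = root / "cds.fa"
    fasta.write_text(f">NM_000081_surrogate synthetic LYST surrogate\n{cds}\n")

    af = root / "af.tsv"
    af.write_text(
        "# chrom\tpos\tref\talt\taf\n"
        f"chr1\t{SG_POS}\tG\tA\t0.0005\n"
        f"chr1\t{v_common.pos}\t{v_common.ref}\t{v_common.alt}\t0.25\n"
        f"chr1\t{v_syn.pos}\tG\tA\t0.001\n"
        f"chr1\t{v_upstream.pos}\tA\tG\t0.002\n"
    )
    tfbs = root / "tfbs.bed"
    tfbs.write_text("")  # no conserved TFBS annotated: the regulatory outcome

    return MiniFamily(
        root=root,
        vcf_a=vcf_a,
        vcf_b=vcf_b,
        ped=ped_path,
        gene_model=gtf,
        cds_fasta=fasta,
        af_table=af,
        tfbs_bed=tfbs,
        cds=cds,
        sg_key=("1", SG_POS, "G", "A"),
        ins_key=("1", INS_POS, "A", "AT"),
    )


@pytest.fixture(scope="session")
def mini_family(tmp_path_factory: pytest.TempPathFactory) -> MiniFamily:
    return build_mini_family(tmp_path_factory.mktemp("mini_family"))


@pytest.fixture()
def fig1a_pedigree() -> Pedigree:
    return parse_ped(FIG1A_PED)


@pytest.fixture()
def table3_variants() -> tuple[VariantRecord, VariantRecord]:
    """The two causal variants with the published genotype matrix."""
    v_sg = VariantRecord(
        "chr1", SG_POS, "G", "A", id="rs80338652",
        genotypes=_gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HET, GT.HET),
    )
    v_ins = VariantRecord(
        "chr1", INS_POS, "A", "AT",
        genotypes=_gts(GT.HOM_REF, GT.HET, GT.HET, GT.HET, GT.HET),
    )
    return v_sg, v_ins
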