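"""Rare-variant filtering, region assignment, and consequence calling."""

import numpy as np
import pytest
from Bio.Seq import Seq

from mendelscope.annotation import (
    AlleleFrequencyTable,
    Consequence,
    Transcript,
    assign_region,
    coding_consequence,
    consequence_filter,
    rare_filter,
    read_bed,
    read_gene_models,
    regulatory_stream,
    revcomp,
    tfbs_overlap,
)
from mendelscope.variants import VariantRecord

from conftest import build_surrogate_cds

_STOPS = {"TAA", "TAG", "TGA"}


def _random_cds(rng, n_codons):
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _plus_tx(cds, start=1000, gene="G1", tid="T1"):
    end = start + len(cds) - 1
    return Transcript(
        gene=gene, transcript_id=tid, chrom="chr1", strand="+",
        exons=[(start, end)], cds_start=start, cds_end=end, cds_sequence=cds,
    )


def _minus_tx(cds, start=1000, gene="G1", tid="T1"):
    end = start + len(cds) - 1
    return Transcript(
        gene=gene, transcript_id=tid, chrom="chr1", strand="-",
        exons=[(start, end)], cds_start=start, cds_end=end,
        cds_sequence=cds,  # coding orientation; genome carries revcomp
    )


class TestRareFilter:
    @staticmethod
    def _setup():
        v_common = VariantRecord("chr1", 100, "A", "G")
        v_rare = VariantRecord("chr1", 200, "C", "T")
        v_novel = VariantRecord("chr1", 235915327, "A", "AT")
        v_edge = VariantRecord("chr1", 300, "G", "C")
        table = AlleleFrequencyTable(
            {
                ("chr1", 100, "A", "G"): 0.25,
                ("chr1", 200, "C", "T"): 0.005,
                ("chr1", 300, "G", "C"): 0.01,
            }
        )
        return [v_common, v_rare, v_novel, v_edge], table

    def test_threshold_and_novel_semantics(self):
        variants, table = self._setup()
        kept = rare_filter(variants, table, 0.01)
        # common removed; rare kept; novel insertion kept; the boundary
        # af == 0.01 is removed under the strict "< threshold" reading
        assert [v.pos for v in kept] == [200, 235915327]

    def test_threshold_extremes(self):
        variants, table = self._setup()
        assert len(rare_filter(variants, table, 1.0)) == 4  # all af < 1
        assert [v.pos for v in rare_filter(variants, table, 0.0)] == [235915327]


class TestAssignRegion:
    def test_upstream_plus_strand(self):
        tx = _plus_tx(_random_cds(np.random.default_rng(0), 20))
        v = VariantRecord("chr1", 500, "A", "G")  # 500 bp 5' of TSS=1000
        assert assign_region(v, [tx]).category is Consequence.UPSTREAM

    def test_upstream_minus_strand_is_genomically_downstream(self):
        tx = _minus_tx(_random_cds(np.random.default_rng(0), 20))
        v = VariantRecord("chr1", tx.span[1] + 500, "A", "G")
        assert assign_region(v, [tx]).category is Consequence.UPSTREAM

    def test_upstream_boundary_is_strict(self):
        tx = _plus_tx(_random_cds(np.random.default_rng(0), 20), start=5000)
        # distance exactly 1000 must not count as upstream
        exactly = VariantRecord("chr1", tx.tss - 1000, "A", "G")
        assert assign_region(exactly, [tx]).category is Consequence.INTERGENIC
        just_inside = VariantRecord("chr1", tx.tss - 999, "A", "G")
        assert assign_region(just_inside, [tx]).category is Consequence.UPSTREAM

    def test_cds_variant_is_handed_to_coding(self):
        cds = _random_cds(np.random.default_rng(1), 20)
        tx = _plus_tx(cds)
        pos = 1000 + 10
        ref = cds[10]
        alt = "ACGT".replace(ref, "")[0]
        call = assign_region(VariantRecord("chr1", pos, ref, alt), [tx])
        assert call.category in {
            Consequence.MISSENSE,
            Consequence.SYNONYMOUS,
            Consequence.STOPGAIN,
        }
        assert call.gene == "G1" and call.cdna_pos == 11

    def test_utr_intron_and_intergenic(self):
        cds = _random_cds(np.random.default_rng(2), 20)  # 60 bp
        # two exons with UTRs: exon1 950..1009 (UTR5 950..999), intron,
        # exon2 1100..1160 (CDS tail + UTR3)
        tx = Transcript(
            gene="G1", transcript_id="T1", chrom="chr1", strand="+",
            exons=[(950, 1009), (1100, 1160)], cds_start=1000, cds_end=1149,
            cds_sequence=cds,
        )
        assert assign_region(VariantRecord("chr1", 960, "A", "G"), [tx]).category is Consequence.UTR5
        assert assign_region(VariantRecord("chr1", 1155, "A", "G"), [tx]).category is Consequence.UTR3
        assert assign_region(VariantRecord("chr1", 1050, "A", "G"), [tx]).category is Consequence.INTRONIC
        assert assign_region(VariantRecord("chr1", 5000, "A", "G"), [tx]).category is Consequence.INTERGENIC
        # within 2 bp of the intron edge: splice site
        assert assign_region(VariantRecord("chr1", 1010, "A", "G"), [tx]).category is Consequence.SPLICE_SITE

    def test_most_severe_across_transcripts_wins(self):
        cds = "ATG" + "TGC" + "TAA"  # Cys codon; C>A at its 3rd base -> TGA stop
        tx_coding = _plus_tx(cds, start=1000, tid="T1")
        tx_other = Transcript(
            gene="G1", transcript_id="T2", chrom="chr1", strand="+",
            exons=[(900, 1100)], cds_start=1050, cds_end=1058,
            cds_sequence="ATGAAATAA",
        )
        v = VariantRecord("chr1", 1005, "C", "A")
        call = assign_region(v, [tx_other, tx_coding])
        assert call.category is Consequence.STOPGAIN
        assert call.transcript_id == "T1"


class TestCodingConsequence:
    def test_stopgain_at_codon_1104_of_the_surrogate(self):
        cds = build_surrogate_cds()
        tx = _plus_tx(cds, start=1)
        # codon 1104 is CGA (Arg); C>T in its first base gives TGA
        pos = 3310
        call = coding_consequence(VariantRecord("chr1", pos, "C", "T"), tx)
        assert call.category is Consequence.STOPGAIN
        assert call.protein_change == "p.R1104X"
        assert call.cdna_pos == 3310

    def test_minus_strand_stopgain_matches_published_coordinates(self, mini_family):
        txs = read_gene_models(mini_family.gene_model, mini_family.cds_fasta)
        v = VariantRecord("chr1", 235969126, "G", "A")
        call = coding_consequence(v, txs[0])
        assert call.category is Consequence.STOPGAIN
        assert call.cdna_pos == 3310
        assert call.protein_change == "p.R1104X"

    def test_frameshift_and_inframe_indels(self):
        cds = _random_cds(np.random.default_rng(3), 30)
        tx = _plus_tx(cds)
        ins = VariantRecord("chr1", 1010, cds[10], cds[10] + "A")
        assert coding_consequence(ins, tx).category is Consequence.FRAMESHIFT_INSERTION
        dele = VariantRecord("chr1", 1010, cds[10:14], cds[10])
        assert coding_consequence(dele, tx).category is Consequence.NONFRAMESHIFT_INDEL
        del4 = VariantRecord("chr1", 1010, cds[10:15], cds[10])
        assert coding_consequence(del4, tx).category is Consequence.FRAMESHIFT_DELETION

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_retranslation_oracle_on_random_snvs(self, strand):
        """Single-codon translation must agree with re-translating the
        whole mutant CDS and diffing the protein, over >=1000 SNVs."""
        rng = np.random.default_rng(42)
        cds = _random_cds(rng, 40)  # 120 bp
        make = _plus_tx if strand == "+" else _minus_tx
        tx = make(cds)
        lo, hi = tx.span
        n_checked = 0
        while n_checked < 1000:
            pos = int(rng.integers(lo, hi + 1))
            c = tx.cds_position(pos)
            coding_ref = cds[c - 1]
            genomic_ref = coding_ref if strand == "+" else revcomp(coding_ref)
            genomic_alt = "ACGT"[int(rng.integers(4))]
            if genomic_alt == genomic_ref:
                continue
            call = coding_consequence(
                VariantRecord("chr1", pos, genomic_ref, genomic_alt), tx
            )
            coding_alt = genomic_alt if strand == "+" else revcomp(genomic_alt)
            mutant = cds[: c - 1] + coding_alt + cds[c:]
            p_ref = str(Seq(cds).translate())
            p_mut = str(Seq(mutant).translate())
            i = (c - 1) // 3
            if p_mut[i] == "*" and p_ref[i] != "*":
                expected = Consequence.STOPGAIN
            elif p_ref[i] == "*" and p_mut[i] != "*":
                expected = Consequence.STOPLOSS
            elif p_ref == p_mut:
                expected = Consequence.SYNONYMOUS
            else:
                expected = Consequence.MISSENSE
            assert call.category is expected, (pos, genomic_ref, genomic_alt)
            n_checked += 1


class TestStreams:
    def test_consequence_filter_retains_disrupting_categories(self, mini_family):
        txs = read_gene_models(mini_family.gene_model, mini_family.cds_fasta)
        sg = assign_region(VariantRecord("chr1", 235969126, "G", "A"), txs)
        ins = assign_region(VariantRecord("chr1", 235915327, "A", "AT"), txs)
        syn = assign_region(VariantRecord("chr1", 235970936, "G", "A"), txs)
        assert sg.category is Consequence.STOPGAIN
        assert ins.category is Consequence.FRAMESHIFT_INSERTION
        assert syn.category is Consequence.SYNONYMOUS
        kept = consequence_filter([sg, ins, syn])
        assert [c.category for c in kept] == [
            Consequence.STOPGAIN,
            Consequence.FRAMESHIFT_INSERTION,
        ]

    def test_regulatory_stream_collects_upstream_and_utr5(self, mini_family):
        txs = read_gene_models(mini_family.gene_model, mini_family.cds_fasta)
        up = assign_region(VariantRecord("chr1", 235972800, "A", "G"), txs)
        assert up.category is Consequence.UPSTREAM
        assert regulatory_stream([up]) == [up]
        assert consequence_filter([up]) == []


class TestTfbsOverlap:
    def _tree(self, tmp_path, body):
        p = tmp_path / "sites.bed"
        p.write_text(body)
        return read_bed(p)

    def test_half_open_boundary_enumeration(self, tmp_path):
        # BED [start, end) covers 1-based positions start+1 .. end
        v = VariantRecord("chr1", 100, "A", "G")
        assert tfbs_overlap([v], self._tree(tmp_path, "chr1\t99\t100\n")) == [v]
        assert tfbs_overlap([v], self._tree(tmp_path, "chr1\t100\t200\n")) == []
        assert tfbs_overlap([v], self._tree(tmp_path, "chr1\t0\t99\n")) == []
        v101 = VariantRecord("chr1", 101, "A", "G")
        assert tfbs_overlap([v101], self._tree(tmp_path, "chr1\t100\t200\n")) == [v101]

    def test_empty_interval_file_gives_empty_result(self, tmp_path):
        v = VariantRecord("chr1", 100, "A", "G")
        assert tfbs_overlap([v], self._tree(tmp_path, "")) == []
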