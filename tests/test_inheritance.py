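"""Recessive, LOH, and compound-het model behaviour.

The compound-het model is additionally validated against an independent
brute-force oracle that literally re-checks the four defining
conditions over all variant pairs of each gene.
"""

from itertools import combinations

import numpy as np
import pytest

from mendelscope.annotation import Consequence, ConsequenceCall
from mendelscope.inheritance import (
    Model,
    compound_het_model,
    loh_model,
    recessive_model,
)
from mendelscope.pedigree import PedigreeError, parse_ped
from mendelscope.variants import GenotypeCall, VariantRecord

from conftest import SAMPLES, _gts

GT = GenotypeCall


def _v(pos, gts, gene=None, ref="A", alt="G"):
    return VariantRecord("chr1", pos, ref, alt, genotypes=gts)


def _call(v, gene):
    return ConsequenceCall(v, Consequence.MISSENSE, gene=gene)


class TestRecessive:
    def test_definitional_pattern_passes(self, fig1a_pedigree):
        v = _v(10, _gts(GT.HET, GT.HET, GT.HOM_REF, GT.HOM_ALT, GT.HOM_ALT))
        out = recessive_model([v], fig1a_pedigree)
        assert len(out) == 1 and out[0].model is Model.RECESSIVE
        v2 = _v(10, _gts(GT.HET, GT.HET, GT.HET, GT.HOM_ALT, GT.HOM_ALT))
        assert len(recessive_model([v2], fig1a_pedigree)) == 1

    def test_unaffected_hom_alt_rejects(self, fig1a_pedigree):
        v = _v(10, _gts(GT.HET, GT.HET, GT.HOM_ALT, GT.HOM_ALT, GT.HOM_ALT))
        assert recessive_model([v], fig1a_pedigree) == []

    def test_published_genotype_matrix_fires_neither_single_variant_model(
        self, fig1a_pedigree, table3_variants
    ):
        # both causal variants are het in the affected children, so the
        # recessive and LOH screens correctly stay silent
        vs = list(table3_variants)
        assert recessive_model(vs, fig1a_pedigree) == []
        assert loh_model(vs, fig1a_pedigree) == []

    def test_missing_parent_genotype_fails_strict_passes_lenient(self, fig1a_pedigree):
        v = _v(10, _gts(GT.MISSING, GT.HET, GT.HOM_REF, GT.HOM_ALT, GT.HOM_ALT))
        assert recessive_model([v], fig1a_pedigree, strict_missing=True) == []
        assert len(recessive_model([v], fig1a_pedigree, strict_missing=False)) == 1

    def test_sample_absent_from_matrix_is_an_entry_error(self, fig1a_pedigree):
        v = VariantRecord("chr1", 10, "A", "G", genotypes={"I-1": GT.HET})
        with pytest.raises(PedigreeError, match="absent"):
            recessive_model([v], fig1a_pedigree)


class TestLoh:
    def test_definitional_pattern_passes(self, fig1a_pedigree):
        v = _v(10, _gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HOM_ALT, GT.HOM_ALT))
        out = loh_model([v], fig1a_pedigree)
        assert len(out) == 1 and out[0].model is Model.LOH

    def test_both_parents_het_is_recessive_not_loh(self, fig1a_pedigree):
        v = _v(10, _gts(GT.HET, GT.HET, GT.HOM_REF, GT.HOM_ALT, GT.HOM_ALT))
        assert loh_model([v], fig1a_pedigree) == []
        assert len(recessive_model([v], fig1a_pedigree)) == 1

    def test_disjoint_from_recessive_on_random_matrices(self, fig1a_pedigree):
        rng = np.random.default_rng(7)
        states = [GT.HOM_REF, GT.HET, GT.HOM_ALT, GT.MISSING]
        for i in range(300):
            gts = {s: states[rng.integers(4)] for s in SAMPLES}
            v = _v(10 + i, gts)
            rec = recessive_model([v], fig1a_pedigree)
            loh = loh_model([v], fig1a_pedigree)
            assert not (rec and loh)


class TestCompoundHet:
    def test_published_worked_example(self, fig1a_pedigree, table3_variants):
        v_sg, v_ins = table3_variants
        calls = [_call(v_sg, "LYST"), _call(v_ins, "LYST")]
        out = compound_het_model(calls, fig1a_pedigree)
        assert len(out) == 1
        cand = out[0]
        assert cand.gene == "LYST"
        assert {v.pos for v in cand.variants} == {v_sg.pos, v_ins.pos}
        # stop-gain carried by the father, insertion by the mother
        assert cand.phase_assignment[str(v_sg)] == "I-1"
        assert cand.phase_assignment[str(v_ins)] == "I-2"

    def test_cis_pair_rejected(self, fig1a_pedigree):
        # both variants carried by the father, mother hom-ref at both:
        # no trans assignment exists
        v1 = _v(10, _gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HET, GT.HET))
        v2 = _v(20, _gts(GT.HET, GT.HOM_REF, GT.HOM_REF, GT.HET, GT.HET), alt="C")
        out = compound_het_model([_call(v1, "G"), _call(v2, "G")], fig1a_pedigree)
        assert out == []

    def test_ambiguous_phase_excluded_by_default(self, fig1a_pedigree):
        # both parents het at both variants: either orientation works
        g = _gts(GT.HET, GT.HET, GT.HOM_REF, GT.HET, GT.HET)
        v1, v2 = _v(10, dict(g)), _v(20, dict(g), alt="C")
        calls = [_call(v1, "G"), _call(v2, "G")]
        assert compound_het_model(calls, fig1a_pedigree) == []
        out = compound_het_model(calls, fig1a_pedigree, include_ambiguous_phase=True)
        assert len(out) == 1
        assert out[0].phase_assignment is None  # reported but unphased

    def test_pair_symmetry_single_candidate(self, fig1a_pedigree, table3_variants):
        v_sg, v_ins = table3_variants
        out_fwd = compound_het_model(
            [_call(v_sg, "LYST"), _call(v_ins, "LYST")], fig1a_pedigree
        )
        out_rev = compound_het_model(
            [_call(v_ins, "LYST"), _call(v_sg, "LYST")], fig1a_pedigree
        )
        assert len(out_fwd) == len(out_rev) == 1
        assert out_fwd[0].phase_assignment == out_rev[0].phase_assignment

    def test_adding_unrelated_variant_preserves_candidates(
        self, fig1a_pedigree, table3_variants
    ):
        v_sg, v_ins = table3_variants
        calls = [_call(v_sg, "LYST"), _call(v_ins, "LYST")]
        base = compound_het_model(calls, fig1a_pedigree)
        extra = _v(99, _gts(GT.HET, GT.HOM_REF, GT.HET, GT.HOM_REF, GT.HOM_REF))
        more = compound_het_model(calls + [_call(extra, "OTHER")], fig1a_pedigree)
        base_keys = {frozenset(str(v) for v in c.variants) for c in base}
        more_keys = {frozenset(str(v) for v in c.variants) for c in more}
        assert base_keys <= more_keys

    def test_agrees_with_brute_force_oracle_on_random_instances(self, fig1a_pedigree):
        rng = np.random.default_rng(2024)
        n_instances = 120
        for _ in range(n_instances):
            calls = _random_instance(rng)
            got = compound_het_model(calls, fig1a_pedigree)
            expected = _oracle_pairs(calls, fig1a_pedigree)
            got_keys = {
                (c.gene, frozenset(v.key for v in c.variants)) for c in got
            }
            assert got_keys == expected


def _random_instance(rng) -> list[ConsequenceCall]:
    n_genes = int(rng.integers(1, 6))
    n_variants = int(rng.integers(2, 51))
    states = [GT.HOM_REF, GT.HET, GT.HOM_ALT, GT.MISSING]
    probs = [0.45, 0.35, 0.15, 0.05]
    calls = []
    for i in range(n_variants):
        gts = {s: states[rng.choice(4, p=probs)] for s in SAMPLES}
        v = VariantRecord("chr1", 1000 + i, "A", "G", genotypes=gts)
        calls.append(_call(v, f"G{int(rng.integers(n_genes)) + 1}"))
    return calls


def _oracle_pairs(calls, pedigree):
    """Literal condition-by-condition re-check over all gene pairs."""
    carriers = (GT.HET, GT.HOM_ALT)
    affected = [s.sample_id for s in pedigree.affected]
    unaffected = [s.sample_id for s in pedigree.unaffected]
    by_gene: dict[str, dict] = {}
    for c in calls:
        by_gene.setdefault(c.gene, {})[c.variant.key] = c.variant
    result = set()
    for gene, vmap in by_gene.items():
        for k1, k2 in combinations(sorted(vmap), 2):
            v1, v2 = vmap[k1], vmap[k2]
            # (a) + (d): every affected het at both (hom-alt/missing fail)
            if not all(
                v.genotypes[a] is GT.HET for v in (v1, v2) for a in affected
            ):
                continue
            # (b): forced trans configuration via the parents
            father, mother = "I-1", "I-2"
            orientations = []
            for p, q in ((father, mother), (mother, father)):
                if (
                    v1.genotypes[p] in carriers
                    and v1.genotypes[q] is GT.HOM_REF
                    and v2.genotypes[q] in carriers
                    and v2.genotypes[p] is GT.HOM_REF
                ):
                    orientations.append((p, q))
            if len(orientations) != 1:  # none, or ambiguous (excluded)
                continue
            # (c): no unaffected double carrier; missing is inconclusive
            # and fails under strict handling unless the other genotype
            # already proves non-carriage
            bad = False
            for u in unaffected:
                g1, g2 = v1.genotypes[u], v2.genotypes[u]
                clear1 = g1 is not GT.MISSING and g1 not in carriers
                clear2 = g2 is not GT.MISSING and g2 not in carriers
                if not (clear1 or clear2):
                    bad = True
                    break
            if bad:
                continue
            result.add((gene, frozenset({v1.key, v2.key})))
    return result
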