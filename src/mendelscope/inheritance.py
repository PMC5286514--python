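"""Candidate selection under recessive, LOH, and compound-het models.

All three models screen an unphased family genotype matrix against the
pedigree. The recessive model looks for affected homozygotes with both
parents heterozygous; the LOH (loss-of-heterozygosity) model for
affected homozygotes with exactly one carrier parent — a
Mendelian-inconsistent signature suggestive of a hemizygous deletion or
uniparental event; and the compound-het model for gene-level pairs of
heterozygous variants whose trans configuration is forced by the
parental genotypes (each variant carried by a different parent, the
other parent homozygous reference).

Missing genotypes are handled strictly by default: a condition that
needs a concrete genotype fails on a missing call. Lenient mode treats
missing as compatible with anything.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations

from .annotation import ConsequenceCall
from .pedigree import Pedigree, PedigreeError, require_trio_complete
from .variants import GenotypeCall, VariantRecord


class Model(enum.Enum):
    RECESSIVE = "recessive"
    LOH = "loh"
    COMPOUND_HET = "compound_het"


@dataclass
class InheritanceCandidate:
    model: Model
    variants: list[VariantRecord]  # 1 for recessive/loh, 2 for compound_het
    gene: str | None = None
    genotype_pattern: dict[str, dict[str, str]] | None = None
    phase_assignment: dict[str, str] | None = None  # variant key str -> parent id

    @property
    def sort_key(self) -> tuple:
        v = self.variants[0]
        return (self.gene or "", v.key)


def _snapshot(variants: list[VariantRecord]) -> dict[str, dict[str, str]]:
    return {
        str(v): {s: g.value for s, g in v.genotypes.items()} for v in variants
    }


class _Geno:
    """Strict/lenient predicate evaluation over one genotype matrix."""

    def __init__(self, pedigree: Pedigree, strict_missing: bool = True):
        self.ped = pedigree
        self.strict = strict_missing
        require_trio_complete(pedigree)

    def _get(self, variant: VariantRecord, sample_id: str) -> GenotypeCall:
        try:
            return variant.genotypes[sample_id]
        except KeyError:
            raise PedigreeError(
                f"sample {sample_id!r} absent from genotype matrix at {variant}"
            ) from None

    def _test(self, g: GenotypeCall, predicate) -> bool:
        # strict mode: a missing call fails whatever condition needed it;
        # lenient mode: missing is compatible with anything
        if g is GenotypeCall.MISSING:
            return not self.strict
        return predicate(g)

    def is_(self, v: VariantRecord, sid: str, *states: GenotypeCall) -> bool:
        return self._test(self._get(v, sid), lambda g: g in states)

    def is_not(self, v: VariantRecord, sid: str, *states: GenotypeCall) -> bool:
        return self._test(self._get(v, sid), lambda g: g not in states)

    def parents_of(self, sid: str) -> tuple[str, str]:
        s = self.ped[sid]
        return s.father_id, s.mother_id  # completeness checked at entry


def recessive_model(
    variants: list[VariantRecord],
    pedigree: Pedigree,
    strict_missing: bool = True,
) -> list[InheritanceCandidate]:
    """Affected hom-alt, every parent of an affected het, no unaffected
    hom-alt."""
    G = _Geno(pedigree, strict_missing)
    HET, HOM_ALT = GenotypeCall.HET, GenotypeCall.HOM_ALT
    out = []
    for v in variants:
        ok = all(G.is_(v, a.sample_id, HOM_ALT) for a in pedigree.affected)
        if ok:
            parent_ids = {p for a in pedigree.affected for p in G.parents_of(a.sample_id)}
            ok = all(G.is_(v, p, HET) for p in parent_ids)
        if ok:
            ok = all(G.is_not(v, u.sample_id, HOM_ALT) for u in pedigree.unaffected)
        if ok:
            out.append(
                InheritanceCandidate(
                    Model.RECESSIVE, [v], genotype_pattern=_snapshot([v])
                )
            )
    out.sort(key=lambda c: c.sort_key)
    return out


def loh_model(
    variants: list[VariantRecord],
    pedigree: Pedigree,
    strict_missing: bool = True,
) -> list[InheritanceCandidate]:
    """Affected hom-alt with exactly one carrier parent, the other parent
    hom-ref: the Mendelian-inconsistent homozygosity signature. Disjoint
    from the recessive model by construction (which needs both parents
    het)."""
    G = _Geno(pedigree, strict_missing)
    HET, HOM_ALT, HOM_REF = GenotypeCall.HET, GenotypeCall.HOM_ALT, GenotypeCall.HOM_REF
    out = []
    for v in variants:
        ok = all(G.is_(v, a.sample_id, HOM_ALT) for a in pedigree.affected)
        if ok:
            for a in pedigree.affected:
                f, m = G.parents_of(a.sample_id)
                f_carrier = G.is_(v, f, HET, HOM_ALT)
                m_carrier = G.is_(v, m, HET, HOM_ALT)
                f_ref = G.is_(v, f, HOM_REF)
                m_ref = G.is_(v, m, HOM_REF)
                if not ((f_carrier and m_ref) or (m_carrier and f_ref)):
                    ok = False
                    break
        if ok:
            ok = all(G.is_not(v, u.sample_id, HOM_ALT) for u in pedigree.unaffected)
        if ok:
            out.append(
                InheritanceCandidate(Model.LOH, [v], genotype_pattern=_snapshot([v]))
            )
    out.sort(key=lambda c: c.sort_key)
    return out


def _orientations(
    G: _Geno,
    v1: VariantRecord,
    v2: VariantRecord,
    father: str,
    mother: str,
    forced: bool,
) -> list[tuple[str, str]]:
    """Orientations (parent-of-v1, parent-of-v2) admitted by one parent pair.

    A *forced* orientation additionally requires each parent to be
    hom-ref at the partner variant, so the trans configuration is the
    only explanation; the relaxed form demands only that each parent
    carries its assigned variant (phase compatible but unverified).
    """
    HET, HOM_ALT, HOM_REF = GenotypeCall.HET, GenotypeCall.HOM_ALT, GenotypeCall.HOM_REF
    orientations = []
    for p, q in ((father, mother), (mother, father)):
        ok = G.is_(v1, p, HET, HOM_ALT) and G.is_(v2, q, HET, HOM_ALT)
        if ok and forced:
            ok = G.is_(v1, q, HOM_REF) and G.is_(v2, p, HOM_REF)
        if ok:
            orientations.append((p, q))
    return orientations


def compound_het_model(
    calls: list[ConsequenceCall],
    pedigree: Pedigree,
    strict_missing: bool = True,
    include_ambiguous_phase: bool = False,
) -> list[InheritanceCandidate]:
    """Gene-level pairs of heterozygous variants in forced trans phase.

    A pair (v1, v2) in one gene is a candidate iff every affected member
    is het at both; the parental genotypes force a trans assignment
    (each variant carried by a different parent, who is hom-ref at the
    other variant) consistently across all affected members; no
    unaffected member carries alt alleles at both; and no affected
    member is hom-alt at either. Pairs whose phase cannot be resolved
    (both orientations admissible) are excluded unless requested.
    """
    G = _Geno(pedigree, strict_missing)
    HET, HOM_ALT = GenotypeCall.HET, GenotypeCall.HOM_ALT

    by_gene: dict[str, list[ConsequenceCall]] = {}
    for c in calls:
        if c.gene is not None:
            by_gene.setdefault(c.gene, []).append(c)

    out = []
    for gene in sorted(by_gene):
        variants = sorted(
            {c.variant.key: c.variant for c in by_gene[gene]}.values(),
            key=lambda v: v.key,
        )
        for v1, v2 in combinations(variants, 2):
            if not all(
                G.is_(v, a.sample_id, HET)
                for v in (v1, v2)
                for a in pedigree.affected
            ):
                continue  # also rules out affected hom-alt at either
            def _shared(forced: bool) -> set[tuple[str, str]]:
                shared: set[tuple[str, str]] | None = None
                for a in pedigree.affected:
                    f, m = G.parents_of(a.sample_id)
                    o = set(_orientations(G, v1, v2, f, m, forced))
                    shared = o if shared is None else shared & o
                    if not shared:
                        return set()
                return shared or set()

            forced = _shared(forced=True)
            ambiguous = False
            if len(forced) == 1:
                pass  # uniquely phased
            elif include_ambiguous_phase and _shared(forced=False):
                ambiguous = True  # compatible but not forced
            else:
                continue

            def _not_double_carrier(uid: str) -> bool:
                # Kleene logic: satisfied if either genotype is concretely
                # non-carrier; unknown (missing) fails in strict mode
                g1, g2 = G._get(v1, uid), G._get(v2, uid)
                if g1 is not GenotypeCall.MISSING and not g1.carries_alt():
                    return True
                if g2 is not GenotypeCall.MISSING and not g2.carries_alt():
                    return True
                if GenotypeCall.MISSING in (g1, g2):
                    return not G.strict
                return False

            # ambiguous pairs exist precisely because both parents carry
            # both variants, so the double-carrier screen exempts the
            # affected members' parents in that mode
            parent_ids = {
                p for a in pedigree.affected for p in G.parents_of(a.sample_id)
            }
            if not all(
                _not_double_carrier(u.sample_id)
                for u in pedigree.unaffected
                if not (ambiguous and u.sample_id in parent_ids)
            ):
                continue
            if ambiguous:
                phase = None
            else:
                p1, p2 = next(iter(forced))
                phase = {str(v1): p1, str(v2): p2}
            out.append(
                InheritanceCandidate(
                    Model.COMPOUND_HET,
                    [v1, v2],
                    gene=gene,
                    genotype_pattern=_snapshot([v1, v2]),
                    phase_assignment=phase,
                )
            )
    out.sort(key=lambda c: c.sort_key)
    return out
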