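# Methods

## Study design and scope

`mendelscope` re-implements, as a tested library, the variant
prioritization logic of a family-based recessive-disease screen: one
nuclear family, two independent variant-calling pipelines, a
rare-variant filter against a reference cohort, consequence annotation
against a gene model, and three inheritance models (recessive, LOH,
compound heterozygous). It operates at the *call-set* level: read
alignment and the callers themselves are out of scope, as are
structural variants, X-linked models, imprinting, and de novo
screening.

## Coordinate and matching conventions

- VCF positions are 1-based inclusive wherever exposed; interval
  arithmetic (BED, exon containment) is 0-based half-open internally
  and converted at the boundary. A BED interval `[start, end)` covers
  1-based positions `start+1 .. end`.
- Chromosome names compare equal after stripping an optional `chr`
  prefix on either side, so `chr1` call sets intersect cleanly with `1`
  annotation tables.
- cDNA (`c.`) positions count the A of the initiator ATG as 1; the
  codon containing `c.N` is `ceil(N/3)`. Frameshift `fsTer_k`/`fsX_k`
  descriptions place the substituted residue at position 1 of the new
  frame, so termination falls at codon `start + k − 1` (`k ≥ 2`;
  `fsTer1` would be a plain nonsense change and is rejected).

## Consensus and normalization

The reliability filter keeps variants called by both pipelines at the
same normalized `(chrom, pos, ref, alt)` key. Multiallelic sites are
first split per alt allele, recoding each diploid genotype by the
dosage of that allele alone (total alt dosage is conserved across the
split). Half-calls (`./1`) become missing — conservative, since the
models treat missing strictly.

Left-normalization follows the classic algorithm: shared trailing
bases are trimmed (extending left from the reference when an allele
would empty), then shared leading bases are trimmed keeping the VCF
anchor. Full left-alignment needs reference context; the pipeline
itself carries no genome FASTA (its gene model is a GTF subset plus
spliced-CDS FASTA, which keeps the package download-free), so
`run_prioritization` applies the reference-free trimming form. That is
sufficient to reconcile padded/unpadded indel encodings between
callers; representations differing by homopolymer placement would
additionally need a reference window, which `left_normalize` accepts
when available. Genotype disagreements between callers at a shared key
do not remove the record: caller A's genotypes are used and the
discordant samples are flagged in the report.

## Consequence model

The CDS FASTA is authoritative for translation (standard genetic code;
no selenocysteine or readthrough). SNVs are resolved by translating
the affected codon — the unit test suite proves this equivalent to
re-translating the whole mutant CDS on 1000+ random SNVs per strand.
Indels are classified by length difference modulo 3; a variant within
2 bp of an intron edge becomes a splice-site call with no protein
change. When several transcripts overlap, the most severe call is
reported, ordered: stopgain > stoploss > frameshift > splice site >
missense > synonymous > non-frameshift indel > UTR5 > UTR3 > intronic >
upstream > intergenic.

"Noncoding" removal is interpreted as two streams: intronic/UTR3/
intergenic variants are dropped; upstream (< 1 kb to the TSS,
strand-aware, strict inequality on the distance) and 5'UTR variants
form a separate regulatory stream that is checked for TFBS overlap and
reported, but does not feed the inheritance models unless
`include_regulatory_in_models` is set. The MAF boundary is strict
(`af < threshold`); absence from the frequency table means novel and
passes; threshold 0 therefore yields a novel-only screen.

## Inheritance models

All three models require both parents of every affected member to be
present and genotyped (checked at model entry). Missing genotypes are
strict by default: any condition that needs a concrete genotype fails
on a missing call (three-valued logic — a condition already decided by
the other genotype of a pair is not failed by missingness elsewhere).
Lenient mode treats missing as compatible with anything.

The LOH model deserves a caveat: "loss of heterozygosity" is often
named but rarely defined in family screens. Here it is affected
homozygosity with exactly one carrier parent and the other parent
homozygous reference — a Mendelian-inconsistent pattern consistent
with a hemizygous deletion or uniparental event. Under these
definitions the recessive and LOH models are provably disjoint (the
parental conditions are mutually exclusive), which the suite property-
tests on random matrices.

Compound-het pairs require a *forced* trans configuration: an
assignment of the two variants to two different parents where each
carrier parent is homozygous reference at the partner variant. Pairs
where both parents carry both variants cannot be phased from genotypes
alone; they are excluded by default and reported with
`phase_assignment = null` under `include_ambiguous_phase`. In that
mode the no-unaffected-double-carrier condition exempts the affected
members' parents — they are, by construction of the ambiguous case,
double carriers, and applying the condition to them would make the
option vacuous. Unaffected siblings are always screened.

One documentation note: in the motivating study the abstract assigns
the stop-gain variant to the mother, while the genotype table and the
Sanger validation assign it to the father. This package follows the
genotype matrix (stop-gain paternal, insertion maternal); the
discrepancy is inherent to the source and is not resolved here.

## HGVS catalog

The catalog parsers accept published-table dialects beyond strict
HGVS: internal whitespace anywhere, bare frameshift offsets (`fs5`),
deletion counts (`del56`), and range-plus-sequence edits with no
keyword (parsed as an ambiguous indel over the range). Unparseable
entries are excluded from statistics with a logged count. Two
truncation measures are reported because published "truncating"
fractions are ambiguous about their numerator: the explicit stop-token
fraction (Ter/X in the protein description; 31/41 = 75.6% on the
packaged catalog) and the biological truncating fraction that also
counts stop-less frameshifts (33/41 = 80.5%). A consistency check
compares `ceil(cdna_start/3)` with the protein residue for every
entry; codon-boundary insertions/duplications legitimately differ by
one, and one packaged row (`c.11102G > T` / `p.Glu3668Ter`) is
internally inconsistent in its source — mismatches are reported, never
silently corrected.

## Small-sample statistics

Group summaries are median and IQR (inclusive linear interpolation;
for n = 2 the quartiles degenerate to min/max, matching how such
tables print "median (low–high)"). Displayed values use half-up
decimal rounding at 2 dp, since binary-float `round()` half-even
disagrees with printed tables (28.075 → 28.08).

The Mann–Whitney U test is exact by full enumeration of all
`C(n1+n2, n1)` labelings of the pooled values, with midranks for ties;
the two-tailed p is the null probability of a U at least as far from
its mean `n1·n2/2` as observed (distribution-based two-tailedness,
which equals doubling one tail under the symmetric null). Deviations
are compared in doubled-integer units so float equality never decides
a tail. Above a pooled-size cap (default 12) the tie-corrected normal
approximation is used and labeled. A design consequence the module
makes explicit: for group sizes (2, 5) the smallest achievable exact
two-tailed p is 2/21 ≈ 0.095, so no such comparison can reach p <
0.05 — any smaller published p for that design must have used a
different procedure (duplicate wells as points, one-tailed, or an
approximation).

## Synthetic families

The generator emulates the assumed statistical structure, not real
genomes: each gene is a single-exon, plus-strand transcript on one
synthetic chromosome (minus-strand logic is exercised separately by
hand-built transcripts in the tests, including a two-exon minus-strand
surrogate that reproduces the worked example's genomic↔cDNA
coordinates); each gene is one locus with two parental haplotypes and
no internal recombination, with free recombination between genes.
Background variants are coding SNVs carried per parental haplotype
with probability `af ~ Beta(0.5, 10)` — mostly rare, some above the
0.01 threshold so the MAF filter is exercised — and the realized `af`
is written to the frequency table (the table is truth, not an
estimate). The causal gene carries a planted novel stop-gain on one
paternal haplotype (a codon forced to TAC, one substitution from TAA)
and a novel 1-bp frameshift insertion on one maternal haplotype.
Affected children inherit both causal haplotypes, unaffected children
at most one, via per-child rejection sampling (capped, erroring with
advice if the cap is hit). Genotype error is a symmetric flip to an
adjacent dosage state (het → either homozygote equiprobably,
homozygote → het), applied once to the observed matrix; missingness
follows. Both callers share the observed matrix and differ only by
private false positives drawn from disjoint position pools, so the
consensus intersection recovers exactly the true call set. Everything
is deterministic, byte for byte, under a fixed seed.

Defaults mirror the motivating design: father, mother, one unaffected
and two affected children; 20 genes × 5 background variants (102
variant sites per family) — small enough that the full recovery
experiment (100 replicates of simulate + prioritize) runs in seconds,
large enough for every filter stage to see traffic. What passing these
simulations shows is that the *logic* is correct under its own
assumptions; they say nothing about caller error modes, linkage
disequilibrium, population structure, or annotation errors on real
genomes.

## Known limitations

- Trim-only normalization in the pipeline (see above): callers that
  emit differently left-shifted homopolymer indels would need a
  reference-backed normalization pass first.
- One family per run; consanguinity loops beyond self-ancestry are not
  detected.
- Consequence annotation ignores conservation scores, protein domains,
  and dbSNP beyond the ID column; "conserved TFBS" is a plain interval
  overlap against a user-supplied site file.
- HGVS descriptions are not validated against a transcript sequence
  (no real transcript is shipped), and genome↔CDS projection of
  catalog entries is out of scope.
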