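"""Synthetic nuclear families with a planted compound-het causal pair.

The generator emulates the study design the inheritance models assume:
a two-generation family (two parents, affected and unaffected children)
genotyped at background variants segregating at known population allele
frequencies, plus one causal gene carrying a trans-configured pair of
novel truncating variants — one on a paternal haplotype, one on a
maternal haplotype. Affected children inherit both causal haplotypes;
unaffected children inherit at most one (rejection sampling). Two
imperfect caller views are emitted, each adding private false-positive
records, so that the consensus intersection recovers exactly the true
call set.

Model simplifications (documented, deliberate): each gene is a single
locus with no internal recombination, transmission is independent
between genes, all simulated genes lie on the + strand of one synthetic
chromosome, and genotype error is a symmetric flip to an adjacent
dosage state. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .pedigree import Pedigree, parse_ped
from .prioritize import RunConfig, run_prioritization
from .variants import GenotypeCall, VariantRecord, write_vcf


class SimulationError(RuntimeError):
    pass


_STOP_CODONS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_REJECTION_CAP = 10_000


@dataclass
class SimConfig:
    n_genes: int = 20
    variants_per_gene: int = 5
    background_af_beta: tuple[float, float] = (0.5, 10.0)
    causal_gene: int | str = "random"
    n_affected_children: int = 2
    n_unaffected_children: int = 1
    genotype_error_rate: float = 0.0
    missing_rate: float = 0.0
    caller_private_fp_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("genotype_error_rate", "missing_rate", "caller_private_fp_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise SimulationError(f"{name} outside [0,1]: {rate}")
        if self.n_affected_children < 1:
            raise SimulationError("need at least one affected child")
        if self.variants_per_gene < 2:
            raise SimulationError("need >=2 variants per gene (causal gene holds a pair)")
        if self.n_genes < 1:
            raise SimulationError("need at least one gene")


@dataclass
class SimTruth:
    causal_gene: str
    causal_pair: list[dict]  # two {chrom,pos,ref,alt} variant keys
    parent_of_origin: dict[str, str]  # "chrom:posref>alt" -> parent id
    true_genotypes: dict[str, dict[str, str]]  # variant -> sample -> GT
    config: dict


@dataclass
class SimulatedFamily:
    vcf_a: Path
    vcf_b: Path
    ped: Path
    gene_model: Path
    cds_fasta: Path
    af_table: Path
    truth: SimTruth
    truth_path: Path


# -- sequence and gene-model synthesis --------------------------------------


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG start, internal-stop-free random codons, one terminal stop."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(list(_BASES), size=3))
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


_GT_FROM_DOSAGE = {0: GenotypeCall.HOM_REF, 1: GenotypeCall.HET, 2: GenotypeCall.HOM_ALT}


def _apply_error(
    gt: GenotypeCall, rng: np.random.Generator, error: float, missing: float
) -> GenotypeCall:
    if missing > 0 and rng.random() < missing:
        return GenotypeCall.MISSING
    if error > 0 and rng.random() < error:
        if gt is GenotypeCall.HET:
            return GenotypeCall.HOM_REF if rng.random() < 0.5 else GenotypeCall.HOM_ALT
        if gt in (GenotypeCall.HOM_REF, GenotypeCall.HOM_ALT):
            return GenotypeCall.HET
    return gt


def simulate_family(config: SimConfig, out_dir: str | Path) -> SimulatedFamily:
    """Write a complete synthetic input set into ``out_dir`` and return it.

    Outputs: caller A/B VCFs, PED, GTF gene model, spliced-CDS FASTA,
    allele-frequency TSV, and a truth JSON (planted pair, phase, and
    pre-error genotypes).
    """
    rng = np.random.default_rng(config.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # family: parents I-1/I-2, then unaffected then affected children
    father, mother = "I-1", "I-2"
    children = []
    for i in range(config.n_unaffected_children):
        children.append((f"II-{i + 1}", False))
    for i in range(config.n_affected_children):
        children.append((f"II-{config.n_unaffected_children + i + 1}", True))
    ped_lines = ["# synthetic family", f"FAM1\t{father}\t0\t0\t1\t1", f"FAM1\t{mother}\t0\t0\t2\t1"]
    for i, (cid, affected) in enumerate(children):
        sex = "2" if i % 2 == 0 else "1"
        ped_lines.append(f"FAM1\t{cid}\t{father}\t{mother}\t{sex}\t{2 if affected else 1}")
    ped_path = out / "family.ped"
    ped_path.write_text("\n".join(ped_lines) + "\n")
    pedigree = parse_ped(ped_path)
    sample_ids = pedigree.sample_ids

    # genes: single-exon + strand transcripts on one synthetic chromosome
    chrom = "chr1"
    n_codons = max(60, 4 * config.variants_per_gene)
    utr = 50
    gene_span = 3 * n_codons + 2 * utr
    genes = []
    for g in range(config.n_genes):
        start = 100_000 + g * (gene_span + 10_000)
        genes.append(
            {
                "name": f"GENE{g + 1:02d}",
                "tid": f"TX{g + 1:02d}",
                "tx_start": start,
                "tx_end": start + gene_span - 1,
                "cds_start": start + utr,
                "cds_end": start + utr + 3 * n_codons - 1,
                "cds": _random_cds(rng, n_codons),
            }
        )
    if config.causal_gene == "random":
        causal_idx = int(rng.integers(config.n_genes))
    else:
        causal_idx = int(config.causal_gene)
    causal = genes[causal_idx]

    # guarantee a stop-gain site in the causal gene: force an internal
    # codon to TAC (Tyr), one substitution away from the TAA stop
    stopgain_codon = n_codons // 3
    cds = causal["cds"]
    causal["cds"] = cds[: 3 * stopgain_codon] + "TAC" + cds[3 * stopgain_codon + 3 :]

    # background variant sites: distinct CDS offsets per gene
    a, b = config.background_af_beta
    variants: list[dict] = []
    reserved = {3 * stopgain_codon, 3 * stopgain_codon + 1, 3 * stopgain_codon + 2}
    for gi, gene in enumerate(genes):
        n_offsets = config.variants_per_gene
        pool = [i for i in range(3, 3 * (n_codons - 1)) if not (gi == causal_idx and i in reserved)]
        offsets = sorted(rng.choice(pool, size=n_offsets, replace=False))
        for off in offsets:
            ref = gene["cds"][off]
            alt = _BASES[int(rng.integers(3))]
            if alt >= ref:  # pick among the three non-ref bases
                alt = _BASES[(_BASES.index(alt) + 1) % 4]
            af = float(np.clip(rng.beta(a, b), 1e-4, 0.999))
            variants.append(
                {
                    "gene_idx": gi,
                    "pos": gene["cds_start"] + int(off),
                    "ref": ref,
                    "alt": alt,
                    "af": af,
                    "causal": False,
                }
            )

    # the planted pair: a stop-gain SNV (paternal) and a 1-bp frameshift
    # insertion (maternal), both novel (absent from the AF table)
    sg_off = 3 * stopgain_codon + 2  # third base of the forced TAC codon
    causal_sg = {
        "gene_idx": causal_idx,
        "pos": causal["cds_start"] + sg_off,
        "ref": "C",
        "alt": "A",  # TAC -> TAA
        "af": None,
        "causal": True,
    }
    ins_off = 3 * (stopgain_codon + 5)  # downstream, inside the CDS
    ins_ref = causal["cds"][ins_off]
    causal_ins = {
        "gene_idx": causal_idx,
        "pos": causal["cds_start"] + ins_off,
        "ref": ins_ref,
        "alt": ins_ref + _BASES[int(rng.integers(4))],
        "af": None,
        "causal": True,
    }
    variants.extend([causal_sg, causal_ins])
    variants.sort(key=lambda v: v["pos"])

    # parental haplotype carriage: 4 haplotypes (father 0/1, mother 0/1)
    for v in variants:
        if v["causal"]:
            carrier = [False, False, False, False]
            if v is causal_sg:
                carrier[0] = True  # father haplotype 0
            else:
                carrier[2] = True  # mother haplotype 0
            v["haps"] = carrier
        else:
            v["haps"] = [bool(rng.random() < v["af"]) for _ in range(4)]

    # transmission: one paternal + one maternal haplotype per child per
    # gene; the causal gene is rejection-sampled against the phenotype
    child_haps: dict[str, dict[int, tuple[int, int]]] = {}
    for cid, affected in children:
        picks: dict[int, tuple[int, int]] = {}
        for gi in range(config.n_genes):
            if gi != causal_idx:
                picks[gi] = (int(rng.integers(2)), int(rng.integers(2)))
                continue
            for attempt in range(_REJECTION_CAP):
                fh, mh = int(rng.integers(2)), int(rng.integers(2))
                got_both = fh == 0 and mh == 0
                if affected and got_both:
                    break
                if not affected and not got_both:
                    break
            else:
                raise SimulationError(
                    "rejection sampling exceeded its cap; relax the family "
                    "configuration (fewer constrained children)"
                )
            picks[gi] = (fh, mh)
        child_haps[cid] = picks

    def true_dosage(v: dict, sample: str) -> int:
        h = v["haps"]
        if sample == father:
            return int(h[0]) + int(h[1])
        if sample == mother:
            return int(h[2]) + int(h[3])
        fh, mh = child_haps[sample][v["gene_idx"]]
        return int(h[fh]) + int(h[2 + mh])

    true_gts = {
        _vkey(chrom, v): {s: _GT_FROM_DOSAGE[true_dosage(v, s)] for s in sample_ids}
        for v in variants
    }

    # observed matrix: symmetric genotype error then missingness, shared
    # by both callers (the callers differ only in private false positives)
    observed = {
        key: {
            s: _apply_error(g, rng, config.genotype_error_rate, config.missing_rate)
            for s, g in gts.items()
        }
        for key, gts in true_gts.items()
    }

    def record(v: dict, gts: dict[str, GenotypeCall]) -> VariantRecord:
        return VariantRecord(
            chrom=chrom, pos=v["pos"], ref=v["ref"], alt=v["alt"], genotypes=dict(gts)
        )

    true_records = [record(v, observed[_vkey(chrom, v)]) for v in variants]

    # private false positives per caller, drawn from a disjoint position
    # pool well away from the genes so the two callers never collide
    n_true = len(true_records)
    fp_counts = [int(rng.binomial(n_true, config.caller_private_fp_rate)) for _ in range(2)]
    fp_pool = rng.choice(
        np.arange(1_000, 50_000), size=sum(fp_counts), replace=False
    )
    fp_records: list[list[VariantRecord]] = [[], []]
    cursor = 0
    for which in (0, 1):
        for _ in range(fp_counts[which]):
            pos = int(fp_pool[cursor])
            cursor += 1
            ref = _BASES[int(rng.integers(4))]
            alt = _BASES[(_BASES.index(ref) + 1 + int(rng.integers(3))) % 4]
            gts = {
                s: (GenotypeCall.HET if rng.random() < 0.5 else GenotypeCall.HOM_REF)
                for s in sample_ids
            }
            fp_records[which].append(
                VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=gts)
            )

    vcf_a_path, vcf_b_path = out / "caller_a.vcf", out / "caller_b.vcf"
    for path, fps, label in (
        (vcf_a_path, fp_records[0], "sim_caller_a"),
        (vcf_b_path, fp_records[1], "sim_caller_b"),
    ):
        recs = sorted(true_records + fps, key=lambda r: (r.chrom, r.pos, r.ref, r.alt))
        write_vcf(recs, pedigree, path, source=label)

    # gene model + CDS FASTA + AF table
    gtf_path = out / "genes.gtf"
    with open(gtf_path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g["name"]}"; transcript_id "{g["tid"]}";'
            fh.write(
                f"{chrom}\tsim\texon\t{g['tx_start']}\t{g['tx_end']}\t.\t+\t.\t{attrs}\n"
            )
            fh.write(
                f"{chrom}\tsim\tCDS\t{g['cds_start']}\t{g['cds_end']}\t.\t+\t0\t{attrs}\n"
            )
    fasta_path = out / "cds.fa"
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g['tid']}\n{g['cds']}\n")
    af_path = out / "af.tsv"
    with open(af_path, "w") as fh:
        fh.write("# chrom\tpos\tref\talt\taf\n")
        for v in variants:
            if v["af"] is not None:
                fh.write(f"{chrom}\t{v['pos']}\t{v['ref']}\t{v['alt']}\t{v['af']:.6f}\n")

    truth = SimTruth(
        causal_gene=causal["name"],
        causal_pair=[
            {"chrom": chrom, "pos": v["pos"], "ref": v["ref"], "alt": v["alt"]}
            for v in (causal_sg, causal_ins)
        ],
        parent_of_origin={
            _vkey(chrom, causal_sg): father,
            _vkey(chrom, causal_ins): mother,
        },
        true_genotypes={
            key: {s: g.value for s, g in gts.items()} for key, gts in true_gts.items()
        },
        config=asdict(config),
    )
    truth_path = out / "truth.json"
    truth_path.write_text(json.dumps(asdict(truth), indent=2, sort_keys=True) + "\n")

    return SimulatedFamily(
        vcf_a=vcf_a_path,
        vcf_b=vcf_b_path,
        ped=ped_path,
        gene_model=gtf_path,
        cds_fasta=fasta_path,
        af_table=af_path,
        truth=truth,
        truth_path=truth_path,
    )


def _vkey(chrom: str, v: dict) -> str:
    return f"{chrom}:{v['pos']}{v['ref']}>{v['alt']}"


# -- recovery experiment ----------------------------------------------------


def recovery_experiment(
    config: SimConfig,
    n_replicates: int,
    seeds: list[int],
    work_dir: str | Path,
    run_config: RunConfig | None = None,
) -> dict:
    """Simulate + prioritize over many seeds; report recovery of the
    planted pair.

    Sensitivity is the fraction of replicates in which the planted pair
    appears among the compound-het candidates; false-candidate load is
    the mean number of non-planted candidate pairs per replicate.
    """
    if n_replicates < 1:
        raise SimulationError("need at least one replicate")
    if n_replicates != len(seeds):
        raise SimulationError("n_replicates must equal the number of seeds")
    work = Path(work_dir)
    hits, false_counts, per_seed = 0, [], []
    for seed in seeds:
        from dataclasses import replace

        sim = simulate_family(replace(config, seed=int(seed)), work / f"rep_{seed}")
        report = run_prioritization(
            sim.vcf_a,
            sim.vcf_b,
            sim.ped,
            sim.gene_model,
            sim.cds_fasta,
            sim.af_table,
            config=run_config,
        )
        planted = {
            (v["chrom"], v["pos"], v["ref"], v["alt"]) for v in sim.truth.causal_pair
        }
        found = False
        n_other = 0
        for cand in report.candidates.get("compound_het", []):
            keys = {(v["chrom"], v["pos"], v["ref"], v["alt"]) for v in cand["variants"]}
            if keys == planted:
                found = True
            else:
                n_other += 1
        hits += found
        false_counts.append(n_other)
        per_seed.append({"seed": int(seed), "recovered": found, "false_pairs": n_other})
    return {
        "n_replicates": n_replicates,
        "sensitivity": hits / n_replicates,
        "mean_false_candidates": float(np.mean(false_counts)),
        "per_seed": per_seed,
    }
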