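"""End-to-end family variant prioritization.

Pipeline order: read both callers' VCFs → split multiallelics →
normalize → intersect (consensus) → rare-variant MAF filter →
region/consequence assignment → coding stream (protein-disrupting
consequences, fed to the inheritance models) plus regulatory stream
(upstream/5'UTR variants, checked for TFBS overlap, reported but not
modeled by default) → structured report.

Reports are deterministic given inputs and configuration: no timestamps
are embedded, and provenance is carried as SHA-256 digests of the input
files plus the realized configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import annotation as ann
from . import inheritance as inh
from . import variants as var
from .pedigree import Pedigree, parse_ped

TOOL_VERSION = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    maf_threshold: float = 0.01
    upstream_bp: int = 1000
    models: tuple[str, ...] = ("recessive", "loh", "compound_het")
    strict_missing: bool = True
    include_ambiguous_phase: bool = False
    include_regulatory_in_models: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf_threshold <= 1.0:
            raise ValueError(f"maf_threshold outside [0,1]: {self.maf_threshold}")
        if self.upstream_bp < 0:
            raise ValueError("upstream_bp must be non-negative")
        valid = {m.value for m in inh.Model}
        unknown = set(self.models) - valid
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")
        if not self.models:
            raise ValueError("at least one model must be selected")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "models" in data:
            data["models"] = tuple(data["models"])
        return cls(**data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _variant_dict(v: var.VariantRecord) -> dict:
    return {
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "id": v.id,
    }


def _candidate_dict(c: inh.InheritanceCandidate) -> dict:
    return {
        "model": c.model.value,
        "gene": c.gene,
        "variants": [_variant_dict(v) for v in c.variants],
        "genotype_pattern": c.genotype_pattern,
        "phase_assignment": c.phase_assignment,
    }


@dataclass
class PrioritizationReport:
    counts: dict[str, int]
    candidates: dict[str, list[dict]]
    regulatory: dict
    coding_calls: list[dict]
    discordant_genotypes: dict[str, list[str]]
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)


def run_prioritization(
    vcf_a: str | Path,
    vcf_b: str | Path,
    ped: str | Path,
    gene_model: str | Path,
    cds_fasta: str | Path,
    af_table: str | Path,
    tfbs_bed: str | Path | None = None,
    config: RunConfig | None = None,
) -> PrioritizationReport:
    """Run the full screen over one family and return the report."""
    config = config or RunConfig()

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    pedigree: Pedigree = stage("pedigree", parse_ped, Path(ped))
    set_a = stage("read_vcf_a", var.read_vcf, vcf_a, pedigree, "caller_a")
    set_b = stage("read_vcf_b", var.read_vcf, vcf_b, pedigree, "caller_b")
    # trim-only normalization: the pipeline carries no genome FASTA, so
    # representations are minimized without reference-dependent shifting
    set_a = stage("normalize", lambda rs: [var.left_normalize(r) for r in rs], set_a)
    set_b = stage("normalize", lambda rs: [var.left_normalize(r) for r in rs], set_b)
    consensus = stage("intersect", var.intersect_callsets, set_a, set_b)

    aft = stage("af_table", ann.AlleleFrequencyTable.from_tsv, af_table)
    rare = stage("rare_filter", ann.rare_filter, consensus, aft, config.maf_threshold)

    transcripts = stage("gene_model", ann.read_gene_models, gene_model, cds_fasta)
    calls = stage(
        "assign_region",
        lambda: [ann.assign_region(v, transcripts, config.upstream_bp) for v in rare],
    )
    coding = ann.consequence_filter(calls)
    regulatory_calls = ann.regulatory_stream(calls)

    tfbs_hits: list[var.VariantRecord] = []
    if tfbs_bed is not None:
        trees = stage("tfbs", ann.read_bed, tfbs_bed)
        tfbs_hits = ann.tfbs_overlap([c.variant for c in regulatory_calls], trees)

    model_calls = list(coding)
    if config.include_regulatory_in_models:
        model_calls += regulatory_calls
    model_variants = list(
        {c.variant.key: c.variant for c in model_calls}.values()
    )

    candidates: dict[str, list[dict]] = {}
    if "recessive" in config.models:
        out = stage(
            "recessive_model",
            inh.recessive_model,
            model_variants,
            pedigree,
            config.strict_missing,
        )
        candidates["recessive"] = [_candidate_dict(c) for c in out]
    if "loh" in config.models:
        out = stage(
            "loh_model", inh.loh_model, model_variants, pedigree, config.strict_missing
        )
        candidates["loh"] = [_candidate_dict(c) for c in out]
    if "compound_het" in config.models:
        out = stage(
            "compound_het_model",
            inh.compound_het_model,
            model_calls,
            pedigree,
            config.strict_missing,
            config.include_ambiguous_phase,
        )
        candidates["compound_het"] = [_candidate_dict(c) for c in out]

    discordant = {
        str(r): flagged
        for r in consensus
        if (flagged := var.discordant_samples(r))
    }

    inputs = {
        "vcf_a": str(vcf_a),
        "vcf_b": str(vcf_b),
        "ped": str(ped),
        "gene_model": str(gene_model),
        "cds_fasta": str(cds_fasta),
        "af_table": str(af_table),
    }
    if tfbs_bed is not None:
        inputs["tfbs_bed"] = str(tfbs_bed)

    return PrioritizationReport(
        counts={
            "caller_a": len(set_a),
            "caller_b": len(set_b),
            "consensus": len(consensus),
            "rare": len(rare),
            "coding_retained": len(coding),
            "regulatory": len(regulatory_calls),
            "tfbs_hits": len(tfbs_hits),
        },
        candidates=candidates,
        regulatory={
            "variants": [
                {**_variant_dict(c.variant), "category": c.category.value, "gene": c.gene}
                for c in regulatory_calls
            ],
            "tfbs_hits": [_variant_dict(v) for v in tfbs_hits],
        },
        coding_calls=[
            {
                **_variant_dict(c.variant),
                "gene": c.gene,
                "transcript_id": c.transcript_id,
                "category": c.category.value,
                "cdna_pos": c.cdna_pos,
                "protein_change": c.protein_change,
            }
            for c in coding
        ],
        discordant_genotypes=discordant,
        provenance={
            "tool": "mendelscope",
            "version": TOOL_VERSION,
            "config": {**asdict(config), "models": list(config.models)},
            "input_sha256": {k: _sha256(v) for k, v in inputs.items()},
            "inputs": inputs,
        },
    )


def write_report(
    report: PrioritizationReport, fmt: str = "json", path: str | Path | None = None
) -> str:
    """Render a report as schema-stable JSON or one-candidate-per-row TSV."""
    if fmt == "json":
        text = json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    elif fmt == "tsv":
        rows = ["model\tgene\tvariants\tphase"]
        for model, cands in sorted(report.candidates.items()):
            for c in cands:
                keys = ";".join(
                    f"{v['chrom']}:{v['pos']}{v['ref']}>{v['alt']}" for v in c["variants"]
                )
                phase = (
                    ";".join(f"{k}->{p}" for k, p in sorted(c["phase_assignment"].items()))
                    if c["phase_assignment"]
                    else "."
                )
                rows.append(f"{model}\t{c['gene'] or '.'}\t{keys}\t{phase}")
        text = "\n".join(rows) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text
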