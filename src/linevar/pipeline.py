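"""End-to-end orchestration: hard filter -> partition -> consequences ->
density -> overlap -> prioritize -> concordance, from a single config.

Every stage writes flat TSV/JSON into the run directory, and a manifest
records input checksums, thresholds, and versions, so a rerun with the same
config is byte-identical and each stage remains independently diffable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .core_io import (read_consequence_table, read_flag_table,
                      read_gene_models, read_gerp_table, read_intervals,
                      read_mirnas, read_vcf, vcf_contigs)
from .hard_filter import DEFAULT_THRESHOLDS, FilterThresholds, apply_filters
from .line_partition import chromosome_summary, partition
from .consequence_impact import (biotype_summary, consequence_proportions,
                                 deleterious_missense_keys)
from .density_stats import (DENSE_SPACING_THRESHOLD, HIGH_COUNT_THRESHOLD,
                            HIGH_DENSITY_THRESHOLD, gene_snp_stats,
                            high_count_genes, missense_spacing)
from .feature_overlap import qtl_membership, scan_seed_overlaps
from .prioritizer import (GERP_CANDIDATE_THRESHOLD, annotate_candidates,
                          candidate_summary, gerp_tiers, select_candidates)
from .strain_concordance import panel_from_variants, validate_candidates


@dataclass
class PipelineConfig:
    """Input paths, sample-name mapping, and threshold overrides."""

    vcf: str = ""
    consequences: str = ""
    gerp: str = ""
    genes_gff3: str = ""
    qtls_bed: str = ""
    mirnas_gff3: str = ""
    mirnas_fasta: str = ""
    flags: str = ""
    outdir: str = "run"
    fat_sample: str = "FatLine"
    lean_sample: str = "LeanLine"
    obese_ref_sample: str = "NZO"
    lean_ref_sample: str = "A_J"
    hard_filter: FilterThresholds = DEFAULT_THRESHOLDS
    gerp_candidate_threshold: float = GERP_CANDIDATE_THRESHOLD
    gerp_tier_thresholds: tuple[float, ...] = (2.0, 4.0, 6.0)
    high_count_threshold: int = HIGH_COUNT_THRESHOLD
    high_density_threshold: float = HIGH_DENSITY_THRESHOLD
    dense_spacing_threshold: float = DENSE_SPACING_THRESHOLD
    seed: Optional[int] = None          # synthetic-mode RNG seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        hf = raw.pop("hard_filter", None)
        cfg = cls(**raw)
        if hf:
            cfg.hard_filter = FilterThresholds(**hf)
        return cfg

    def is_canonical(self) -> bool:
        default = PipelineConfig()
        return (self.hard_filter == DEFAULT_THRESHOLDS
                and self.gerp_candidate_threshold
                == default.gerp_candidate_threshold
                and tuple(self.gerp_tier_thresholds)
                == default.gerp_tier_thresholds
                and self.high_count_threshold == default.high_count_threshold
                and self.high_density_threshold
                == default.high_density_threshold
                and self.dense_spacing_threshold
                == default.dense_spacing_threshold)


@dataclass
class PipelineResult:
    outdir: Path
    partition: object
    candidates: list
    concordance: dict
    tiers: dict
    manifest: dict
    truth_recovery: Optional[dict] = None


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run the seven stages in order and write all stage outputs."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    for name in ("vcf", "consequences", "gerp", "genes_gff3", "qtls_bed",
                 "mirnas_gff3", "mirnas_fasta", "flags"):
        p = getattr(config, name)
        if not p or not Path(p).exists():
            raise FileNotFoundError(f"input {name!r} missing: {p}")

    samples = [config.fat_sample, config.lean_sample,
               config.obese_ref_sample, config.lean_ref_sample]
    variants = read_vcf(config.vcf, sample_names=samples)
    contigs = vcf_contigs(config.vcf)
    consequences = read_consequence_table(config.consequences)
    gerp = read_gerp_table(config.gerp)
    genes = read_gene_models(config.genes_gff3)
    qtls = read_intervals(config.qtls_bed)
    mirnas = read_mirnas(config.mirnas_gff3, config.mirnas_fasta)
    flags = read_flag_table(config.flags)

    # 1. hard filter + homozygosity
    line_samples = [config.fat_sample, config.lean_sample]
    passing, report = apply_filters(variants, line_samples,
                                    config.hard_filter)
    pd.DataFrame(
        [{"variant_key": k, "passed": verdict.passed and hom,
          "failed_criteria": ",".join(verdict.failed_criteria),
          "homozygous": hom} for k, verdict, hom in report]
    ).to_csv(outdir / "hardfilter.tsv", sep="\t", index=False)

    # 2. partition
    part = partition(passing, config.fat_sample, config.lean_sample)
    for name, keys in (("fat_private", part.fat_private),
                       ("lean_private", part.lean_private),
                       ("shared", part.shared)):
        (outdir / f"partition_{name}.tsv").write_text(
            "\n".join(sorted(keys)) + ("\n" if keys else ""))
    chrom_table = chromosome_summary(part, passing, chromosomes=contigs)
    chrom_table.to_csv(outdir / "partition_by_chromosome.tsv", sep="\t")

    # 3. consequences
    biotypes = biotype_summary(consequences, part)
    biotypes.to_csv(outdir / "biotype_summary.tsv", sep="\t")
    proportions = consequence_proportions(consequences, part)
    (outdir / "consequence_proportions.json").write_text(
        json.dumps(proportions, indent=1, sort_keys=True) + "\n")
    snp_keys = {v.key for v in passing if v.vtype == "SNP"}
    dmv = deleterious_missense_keys(consequences,
                                    part.line_specific & snp_keys)
    (outdir / "dmv_keys.tsv").write_text(
        "\n".join(sorted(dmv)) + ("\n" if dmv else ""))

    # 4. density
    density = gene_snp_stats(part, passing, genes,
                             count_threshold=config.high_count_threshold,
                             density_threshold=config.high_density_threshold)
    pd.DataFrame([dataclasses.asdict(r) for r in density]).to_csv(
        outdir / "gene_density.tsv", sep="\t", index=False)
    spacing = missense_spacing(
        consequences, genes, part,
        spacing_threshold=config.dense_spacing_threshold)
    pd.DataFrame([dataclasses.asdict(r) for r in spacing]).to_csv(
        outdir / "missense_spacing.tsv", sep="\t", index=False)

    # 5. overlap
    gene_qtl = [{"gene_id": g.gene_id,
                 "qtls_containment": ",".join(qtl_membership(g, qtls)),
                 "qtls_overlap": ",".join(qtl_membership(g, qtls,
                                                         mode="overlap"))}
                for g in genes]
    pd.DataFrame(gene_qtl).to_csv(outdir / "qtl_membership.tsv", sep="\t",
                                  index=False)
    seed_hits = scan_seed_overlaps(passing, mirnas, keys=part.line_specific)
    pd.DataFrame([{
        "variant_key": k, "mature_name": m, "in_seed": res.in_seed,
        "reference_seed": res.reference_seed,
        "mutated_seed": res.mutated_seed or ""} for k, m, res in seed_hits]
    ).to_csv(outdir / "seed_overlaps.tsv", sep="\t", index=False)

    # 6. prioritize
    tiers = gerp_tiers(part, gerp, tuple(config.gerp_tier_thresholds))
    candidates = select_candidates(
        part, gerp, consequences, genes,
        gerp_threshold=config.gerp_candidate_threshold)
    candidates = annotate_candidates(candidates, qtls, flags,
                                     high_count_genes(density), genes)

    # 7. concordance
    sample_map = {"FatLine": config.fat_sample, "LeanLine": config.lean_sample,
                  "NZO": config.obese_ref_sample, "A_J": config.lean_ref_sample}
    panel = panel_from_variants(variants, sample_map)
    candidates, concordance = validate_candidates(candidates, panel)

    audit = {
        "tiers": tiers,
        "summary": candidate_summary(candidates),
        "candidates": [{
            "gene_id": c.gene_id, "gene_symbol": c.gene_symbol,
            "biotype": c.biotype, "flags": sorted(c.flags),
            "triggering_variants": [dataclasses.asdict(t)
                                    for t in c.triggering_variants],
        } for c in candidates],
        "concordance": {k: v for k, v in concordance.items()
                        if k != "verdicts"},
    }
    (outdir / "candidates.json").write_text(
        json.dumps(audit, indent=1, sort_keys=True) + "\n")
    pd.DataFrame([{
        "gene_symbol": c.gene_symbol, "biotype": c.biotype,
        "regulatory": "; ".join(
            f"{t.line[0].upper()}:{t.category.split(':', 1)[1]}"
            for t in c.triggering_variants
            if t.category.startswith("regulatory:")),
        "impact": "; ".join(
            f"{t.line[0].upper()}:{t.category.split(':', 1)[1]}"
            for t in c.triggering_variants
            if t.category.startswith("impact:")),
        "flags": ",".join(sorted(c.flags)),
    } for c in candidates]).to_csv(outdir / "candidate_table.tsv", sep="\t",
                                   index=False)

    manifest = {
        "version": __version__,
        "canonical_thresholds": config.is_canonical(),
        "thresholds": {
            "hard_filter": dataclasses.asdict(config.hard_filter),
            "gerp_candidate": config.gerp_candidate_threshold,
            "gerp_tiers": list(config.gerp_tier_thresholds),
            "high_count": config.high_count_threshold,
            "high_density": config.high_density_threshold,
            "dense_spacing": config.dense_spacing_threshold,
        },
        "samples": sample_map,
        "inputs": {name: {"path": str(getattr(config, name)),
                          "sha256": _sha256(getattr(config, name))}
                   for name in ("vcf", "consequences", "gerp", "genes_gff3",
                                "qtls_bed", "mirnas_gff3", "mirnas_fasta",
                                "flags")},
        "n_variants": len(variants),
        "n_pass": len(passing),
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")

    return PipelineResult(outdir=outdir, partition=part,
                          candidates=candidates, concordance=concordance,
                          tiers=tiers, manifest=manifest)


def run_synthetic(seed: int, outdir: str | Path,
                  synth_config=None) -> tuple[PipelineResult, "object"]:
    """Generate a synthetic bundle, run the pipeline on it, and compare the
    recovered candidate genes against the planted truth."""
    from .synthetic_data import SynthConfig, generate_bundle

    outdir = Path(outdir)
    cfg = synth_config or SynthConfig(seed=seed)
    if cfg.seed != seed:
        cfg = dataclasses.replace(cfg, seed=seed)
    bundle = generate_bundle(cfg, outdir / "inputs")
    pcfg = PipelineConfig(
        vcf=str(bundle.paths["vcf"]),
        consequences=str(bundle.paths["consequences"]),
        gerp=str(bundle.paths["gerp"]),
        genes_gff3=str(bundle.paths["genes_gff3"]),
        qtls_bed=str(bundle.paths["qtls_bed"]),
        mirnas_gff3=str(bundle.paths["mirnas_gff3"]),
        mirnas_fasta=str(bundle.paths["mirnas_fasta"]),
        flags=str(bundle.paths["flags"]),
        outdir=str(outdir / "run"), seed=seed)
    result = run_all(pcfg)
    recovered = {c.gene_id for c in result.candidates}
    validated = {c.gene_id for c in result.candidates
                 if "MGI_validated" in c.flags}
    truth = bundle.truth
    result.truth_recovery = {
        "candidate_genes_match": recovered == truth.candidate_genes,
        "validated_genes_match": validated == truth.validated_genes,
        "false_positives": sorted(recovered - truth.candidate_genes),
        "false_negatives": sorted(truth.candidate_genes - recovered),
    }
    return result, bundle
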