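"""Generator contracts: determinism, exact quotas, planted structure."""

import dataclasses

import pytest

from linevar.core_io import Zygosity, read_vcf
from linevar.hard_filter import classify
from linevar.consequence_impact import ImpactClass, impact_class
from linevar.synthetic_data import (SAMPLES, SynthConfig, TruthSet,
                                    generate_bundle)


def small_config(**kw):
    base = dict(seed=3, n_variants_total=800, n_genes=40,
                n_planted_candidates=4, n_decoys_per_class=2)
    base.update(kw)
    return SynthConfig(**base)


def test_identical_seed_is_byte_identical(tmp_path):
    b1 = generate_bundle(small_config(), tmp_path / "a")
    b2 = generate_bundle(small_config(), tmp_path / "b")
    for k in b1.paths:
        assert b1.paths[k].read_bytes() == b2.paths[k].read_bytes(), k


def test_zero_variant_config_valid_and_empty(tmp_path):
    cfg = SynthConfig(seed=1, n_variants_total=0, n_planted_candidates=0,
                      n_decoys_per_class=0, n_mirnas=0,
                      frac_fail_hard_filter=0.0)
    b = generate_bundle(cfg, tmp_path)
    assert b.variants == [] and b.truth.candidates == []
    assert read_vcf(b.paths["vcf"]) == []


def test_partition_quotas_are_exact(tmp_path):
    cfg = small_config(n_variants_total=1500, frac_fat_private=0.2,
                       frac_lean_private=0.1, frac_shared=0.3)
    b = generate_bundle(cfg, tmp_path)
    labels = list(b.truth.partition_labels.values())
    assert labels.count("fat_private") == 300   # 0.2 * 1500, planted exactly
    assert labels.count("lean_private") == 150
    assert labels.count("shared") == 450


def test_infeasible_configs_rejected(tmp_path):
    with pytest.raises(ValueError, match="more planted candidates"):
        generate_bundle(small_config(n_planted_candidates=99, n_genes=10),
                        tmp_path)
    with pytest.raises(ValueError, match="quota"):
        # private quotas cannot hold the planted candidates and decoys
        generate_bundle(small_config(n_variants_total=20,
                                     frac_fat_private=0.05,
                                     frac_lean_private=0.05), tmp_path)
    with pytest.raises(ValueError, match="sum above 1"):
        SynthConfig(frac_shared=0.6, frac_fat_private=0.3,
                    frac_lean_private=0.3).validate()


def test_planted_candidates_satisfy_selection_rule(bundle):
    by_key = {v.key: v for v in bundle.variants}
    for c in bundle.truth.candidates:
        v = by_key[c["variant_key"]]
        assert bundle.gerp[v.key] > 6.0
        kind, _, detail = c["category"].partition(":")
        if kind == "impact":
            assert impact_class(detail) in (ImpactClass.MODERATE,
                                            ImpactClass.HIGH)
        else:
            assert kind == "regulatory"
        # homozygous-alt in exactly one line
        line_sample = "FatLine" if c["line"] == "fat" else "LeanLine"
        other = "LeanLine" if c["line"] == "fat" else "FatLine"
        assert v.genotypes[line_sample].zygosity is Zygosity.HOM_ALT
        assert v.genotypes[other].zygosity is Zygosity.HOM_REF
        # concordance pattern holds exactly for the validated candidates
        fat, nzo = v.genotypes["FatLine"].allele, v.genotypes["NZO"].allele
        lean, aj = v.genotypes["LeanLine"].allele, v.genotypes["A_J"].allele
        concordant = fat == nzo and lean == aj and fat != lean
        assert concordant == c["validated"]
        assert not (fat == nzo == lean == aj)  # never the degenerate pattern


def test_planted_failures_rejected_and_passes_kept(bundle):
    by_key = {v.key: v for v in bundle.variants}
    assert len(bundle.truth.hard_filter_fail) == round(
        0.1 * bundle.config.n_variants_total)
    for key, criterion in bundle.truth.hard_filter_fail.items():
        verdict = classify(by_key[key])
        assert verdict.failed_criteria == [criterion]  # exactly one criterion
    for key, label in bundle.truth.partition_labels.items():
        if label in ("fat_private", "lean_private", "shared"):
            assert classify(by_key[key]).passed, key


def test_seed_cases_planted_on_both_strands(bundle):
    strands = {case["strand"] for case in bundle.truth.seed_cases}
    assert strands == {"+", "-"}
    for case in bundle.truth.seed_cases:
        assert case["reference_seed"] == "CCAAUGA"
        assert case["mutated_seed"] == "CCAAUGG"


def test_bundle_files_parse_back(bundle):
    from linevar.core_io import (read_consequence_table, read_flag_table,
                                 read_gene_models, read_gerp_table,
                                 read_intervals, read_mirnas)
    variants = read_vcf(bundle.paths["vcf"], sample_names=list(SAMPLES))
    assert len(variants) == len(bundle.variants)
    assert read_consequence_table(bundle.paths["consequences"]) == \
        bundle.consequences
    assert read_gerp_table(bundle.paths["gerp"]) == bundle.gerp
    assert read_gene_models(bundle.paths["genes_gff3"]) == bundle.genes
    assert read_intervals(bundle.paths["qtls_bed"]) == bundle.qtls
    assert read_mirnas(bundle.paths["mirnas_gff3"],
                       bundle.paths["mirnas_fasta"]) == bundle.mirnas
    assert read_flag_table(bundle.paths["flags"]) == bundle.flags
    truth = TruthSet.from_json(bundle.paths["truth"])
    assert truth.candidate_genes == bundle.truth.candidate_genes


def test_y_chromosome_and_par_like_gene_present(bundle):
    assert any(v.chrom == "Y" for v in bundle.variants)
    assert any(g.chrom == "Y" and g.gene_symbol == "ParLike1"
               for g in bundle.genes)


def test_different_seeds_differ(tmp_path):
    b1 = generate_bundle(small_config(seed=3), tmp_path / "a")
    b2 = generate_bundle(small_config(seed=4), tmp_path / "b")
    assert b1.paths["vcf"].read_bytes() != b2.paths["vcf"].read_bytes()
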