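"""GERP tiers and the three-clause candidate-selection rule."""

import numpy as np
import pytest

from linevar.core_io import ConsequenceRecord, GeneModel, Interval
from linevar.consequence_impact import ImpactClass, impact_class
from linevar.line_partition import LinePartition
from linevar.prioritizer import (annotate_candidates, candidate_summary,
                                 gerp_tiers, select_candidates)


def _partition(fat=(), lean=(), shared=()):
    p = LinePartition(fat_private=set(fat), lean_private=set(lean),
                      shared=set(shared))
    p.validate()
    return p


def rec(key, gene="G1", term="missense_variant", reg=None, biotype="protein_coding"):
    return ConsequenceRecord(variant_key=key, gene_id=gene, gene_symbol=gene,
                             transcript_id=None, consequence_term=term,
                             biotype=biotype, regulatory_class=reg)


def test_tier_counts_simple():
    p = _partition(fat=["1_1_A/G", "1_2_A/G", "1_3_A/G"])
    gerp = {"1_1_A/G": 1.0, "1_2_A/G": 2.5, "1_3_A/G": 6.5}
    counts = gerp_tiers(p, gerp)
    assert counts == {"above_2": 2, "above_4": 1, "above_6": 1, "unscored": 0}


def test_tier_empty_gerp_table():
    p = _partition(fat=["1_1_A/G"])
    assert gerp_tiers(p, {}) == {"above_2": 0, "above_4": 0, "above_6": 0,
                                 "unscored": 1}


def test_tiers_match_bruteforce_filter_count():
    rng = np.random.default_rng(17)
    keys = [f"1_{i}_A/G" for i in range(500)]
    p = _partition(fat=keys[:250], lean=keys[250:])
    gerp = {k: float(rng.normal(0, 3)) for k in keys if rng.random() < 0.9}
    counts = gerp_tiers(p, gerp)
    for t in (2.0, 4.0, 6.0):
        expected = sum(1 for k in keys if k in gerp and gerp[k] > t)
        assert counts[f"above_{t:g}"] == expected
    assert counts["unscored"] == sum(1 for k in keys if k not in gerp)
    vals = [counts["above_2"], counts["above_4"], counts["above_6"]]
    assert vals == sorted(vals, reverse=True)  # anti-monotone in threshold


def test_selection_requires_all_three_clauses():
    p = _partition(fat=["1_1_A/G", "1_2_A/G", "1_3_A/G"],
                   shared=["1_4_A/G"])
    gerp = {"1_1_A/G": 6.5, "1_2_A/G": 5.9, "1_3_A/G": 7.0, "1_4_A/G": 8.0}
    consequences = [
        rec("1_1_A/G", gene="G1", term="missense_variant"),          # selected
        rec("1_2_A/G", gene="G2", reg="promoter_flanking_region",
            term="regulatory_region_variant"),                       # gerp low
        rec("1_3_A/G", gene="G3", term="intron_variant"),            # no clause 3
        rec("1_4_A/G", gene="G4", term="missense_variant"),          # shared
    ]
    cands = select_candidates(p, gerp, consequences)
    assert [c.gene_id for c in cands] == ["G1"]
    (t,) = cands[0].triggering_variants
    assert t.category == "impact:missense_variant"
    assert t.line == "fat" and t.gerp_score == 6.5


def test_gerp_threshold_is_strict():
    p = _partition(fat=["1_1_A/G"])
    consequences = [rec("1_1_A/G", reg="promoter")]
    assert select_candidates(p, {"1_1_A/G": 6.0}, consequences) == []
    assert len(select_candidates(p, {"1_1_A/G": 6.000001}, consequences)) == 1


def test_selection_anti_monotone_in_gerp_threshold():
    rng = np.random.default_rng(23)
    keys = [f"1_{i}_A/G" for i in range(100)]
    p = _partition(fat=keys)
    gerp = {k: float(rng.uniform(0, 10)) for k in keys}
    consequences = [rec(k, gene=f"G{i}",
                        term="missense_variant" if i % 2 else
                        "regulatory_region_variant",
                        reg=None if i % 2 else "enhancer")
                    for i, k in enumerate(keys)]
    prev = None
    for t in (2.0, 4.0, 6.0, 8.0):
        genes = {c.gene_id for c in
                 select_candidates(p, gerp, consequences, gerp_threshold=t)}
        if prev is not None:
            assert genes <= prev
        prev = genes


def test_one_variant_two_genes_yields_both():
    p = _partition(lean=["1_1_A/G"])
    gerp = {"1_1_A/G": 7.7}
    consequences = [rec("1_1_A/G", gene="GA", biotype="lncRNA",
                        term="regulatory_region_variant",
                        reg="promoter_flanking_region"),
                    rec("1_1_A/G", gene="GB", biotype="lncRNA",
                        term="regulatory_region_variant",
                        reg="promoter_flanking_region")]
    cands = select_candidates(p, gerp, consequences)
    assert {c.gene_id for c in cands} == {"GA", "GB"}
    s = candidate_summary(cands)
    assert s["n_genes"] == 2 and s["n_regulatory_snps"] == 1


def test_selection_matches_clause_decomposition_on_bundle(bundle):
    from linevar.hard_filter import apply_filters
    from linevar.line_partition import partition
    passing, _ = apply_filters(bundle.variants, ["FatLine", "LeanLine"])
    p = partition(passing, "FatLine", "LeanLine")
    cands = select_candidates(p, bundle.gerp, bundle.consequences,
                              bundle.genes)
    got = {(c.gene_id, t.variant_key) for c in cands
           for t in c.triggering_variants}
    # independent clause-by-clause evaluation over annotation rows
    expected = set()
    for r in bundle.consequences:
        clause1 = r.variant_key in p.line_specific
        clause2 = bundle.gerp.get(r.variant_key, -99) > 6.0
        clause3 = (r.regulatory_class is not None
                   or impact_class(r.consequence_term) in (
                       ImpactClass.MODERATE, ImpactClass.HIGH))
        if clause1 and clause2 and clause3:
            expected.add((r.gene_id, r.variant_key))
    assert got == expected
    # decoys each fail exactly the clause they were built to fail
    selected_keys = {k for _, k in got}
    for keys in bundle.truth.decoys.values():
        assert not (set(keys) & selected_keys)


def test_annotate_candidates_flags():
    g = GeneModel(gene_id="G1", gene_symbol="G1", biotype="protein_coding",
                  chrom="2", start=200, end=800, strand="+")
    cands = select_candidates(
        _partition(fat=["2_500_A/G"]), {"2_500_A/G": 7.0},
        [rec("2_500_A/G")], [g])
    qtls = [Interval("Fob1", "2", 100, 1000)]
    annotate_candidates(cands, qtls, {"G1": {"IMPC_adipose"}}, {"G1"}, [g])
    assert cands[0].flags == {"FOB_QTL", "IMPC_adipose", "high_snp_count"}
    # gene absent from all tables -> empty flags
    cands2 = select_candidates(
        _partition(fat=["2_500_A/G"]), {"2_500_A/G": 7.0},
        [rec("2_500_A/G", gene="G9")])
    annotate_candidates(cands2, [], {}, set())
    assert cands2[0].flags == set()
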