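"""GERP-tier accounting and candidate-gene selection.

A (variant, gene) annotation is selected as a candidate when three clauses
hold simultaneously: the variant is line-specific, its GERP score exceeds the
conservation threshold (default 6, strict), and the annotation is either a
regulatory-feature record or carries a MODERATE/HIGH consequence.  Candidates
aggregate per gene (a variant annotated to two genes triggers both), then get
annotation flags: FOB-QTL containment, flag-table annotations, and membership
in the high-SNP-count gene list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .core_io import ConsequenceRecord, GeneModel, Interval
from .consequence_impact import ImpactClass, impact_class
from .feature_overlap import qtl_membership

GERP_CANDIDATE_THRESHOLD = 6.0
DEFAULT_TIERS = (2.0, 4.0, 6.0)


@dataclass(frozen=True)
class TriggeringVariant:
    variant_key: str
    line: str                      # fat | lean
    category: str                  # "regulatory:<class>" | "impact:<term>"
    gerp_score: float


@dataclass
class CandidateGene:
    gene_id: str
    gene_symbol: str
    biotype: str
    triggering_variants: list[TriggeringVariant] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def categories(self) -> set[str]:
        return {t.category.split(":", 1)[0] for t in self.triggering_variants}


def gerp_tiers(partition, gerp: Mapping[str, float],
               thresholds: tuple[float, ...] = DEFAULT_TIERS
               ) -> dict[str, int]:
    """Counts of line-specific SNPs with GERP strictly above each threshold.

    Variants without a GERP entry are not counted against any tier and are
    tallied under ``unscored``.
    """
    if list(thresholds) != sorted(set(thresholds)):
        raise ValueError("thresholds must be strictly increasing")
    keys = partition.line_specific
    counts = {f"above_{t:g}": 0 for t in thresholds}
    unscored = 0
    for key in keys:
        score = gerp.get(key)
        if score is None:
            unscored += 1
            continue
        for t in thresholds:
            if score > t:
                counts[f"above_{t:g}"] += 1
    counts["unscored"] = unscored
    return counts


def _category_for(record: ConsequenceRecord) -> Optional[str]:
    if record.regulatory_class is not None:
        return f"regulatory:{record.regulatory_class}"
    cls = impact_class(record.consequence_term)
    if cls in (ImpactClass.MODERATE, ImpactClass.HIGH):
        return f"impact:{record.consequence_term}"
    return None


def select_candidates(partition, gerp: Mapping[str, float],
                      consequences: list[ConsequenceRecord],
                      genes: Optional[list[GeneModel]] = None,
                      gerp_threshold: float = GERP_CANDIDATE_THRESHOLD,
                      ) -> list[CandidateGene]:
    """Apply the three-clause selection rule and aggregate per gene."""
    gene_info = {g.gene_id: g for g in (genes or [])}
    by_gene: dict[str, CandidateGene] = {}
    seen: set[tuple[str, str, str]] = set()
    for r in consequences:
        line = partition.line_of(r.variant_key)
        if line not in ("fat", "lean"):
            continue
        score = gerp.get(r.variant_key)
        if score is None or score <= gerp_threshold:
            continue
        category = _category_for(r)
        if category is None:
            continue
        tag = (r.gene_id, r.variant_key, category)
        if tag in seen:
            continue
        seen.add(tag)
        if r.gene_id not in by_gene:
            info = gene_info.get(r.gene_id)
            by_gene[r.gene_id] = CandidateGene(
                gene_id=r.gene_id,
                gene_symbol=info.gene_symbol if info else r.gene_symbol,
                biotype=info.biotype if info else r.biotype,
            )
        by_gene[r.gene_id].triggering_variants.append(TriggeringVariant(
            variant_key=r.variant_key, line=line,
            category=category, gerp_score=score))
    return [by_gene[g] for g in sorted(by_gene)]


def annotate_candidates(candidates: list[CandidateGene],
                        qtls: list[Interval],
                        flag_table: Mapping[str, set[str]],
                        high_count_genes: set[str],
                        genes: Optional[list[GeneModel]] = None,
                        ) -> list[CandidateGene]:
    """Attach FOB-QTL, flag-table, and high-SNP-count flags in place."""
    gene_info = {g.gene_id: g for g in (genes or [])}
    known = set(gene_info)
    for gid in flag_table:
        if known and gid not in known:
            import logging
            logging.getLogger("linevar").warning(
                "flag table names unknown gene %s; ignored", gid)
    for c in candidates:
        model = gene_info.get(c.gene_id)
        if model is not None and qtl_membership(model, qtls):
            c.flags.add("FOB_QTL")
        c.flags |= (set(flag_table.get(c.gene_id, ())) - {"high_snp_count"})
        if c.gene_id in high_count_genes:
            c.flags.add("high_snp_count")
    return candidates


def candidate_summary(candidates: list[CandidateGene]) -> dict[str, int]:
    """Bookkeeping over a candidate list, mirroring the published layout:
    gene counts per category (a gene with both categories counts in both),
    distinct triggering SNPs per category, and biotype tallies.
    """
    reg_genes = {c.gene_id for c in candidates if "regulatory" in c.categories}
    imp_genes = {c.gene_id for c in candidates if "impact" in c.categories}
    reg_snps = {t.variant_key for c in candidates
                for t in c.triggering_variants
                if t.category.startswith("regulatory:")}
    imp_snps = {t.variant_key for c in candidates
                for t in c.triggering_variants
                if t.category.startswith("impact:")}
    all_snps = {t.variant_key for c in candidates
                for t in c.triggering_variants}
    biotypes: dict[str, int] = {}
    for c in candidates:
        biotypes[c.biotype] = biotypes.get(c.biotype, 0) + 1
    return {
        "n_genes": len(candidates),
        "n_regulatory_genes": len(reg_genes),
        "n_impact_genes": len(imp_genes),
        "n_regulatory_snps": len(reg_snps),
        "n_impact_snps": len(imp_snps),
        "n_snps": len(all_snps),
        "n_fob_qtl_genes": sum("FOB_QTL" in c.flags for c in candidates),
        **{f"n_biotype_{b}": n for b, n in sorted(biotypes.items())},
    }
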