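"""Allele concordance of candidate SNPs with independent reference strains.

The obese pair is the Fat selection line plus NZO/HlLtJ; the lean pair is the
Lean line plus A/J.  A candidate SNP is concordant when the allele is shared
within each phenotype pair AND differs between the pairs — identical alleles
across all four strains carry no phenotype signal and are discordant.  Any
absent, heterozygous, or non-single-base allele renders a row not evaluable
(the panel strains are inbred; a het indicates an annotation conflict).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .core_io import Variant, Zygosity
from .prioritizer import CandidateGene

STRAINS = ("FatLine", "NZO", "LeanLine", "A_J")

CONCORDANT = "concordant"
DISCORDANT = "discordant"
NOT_EVALUABLE = "not_evaluable"

_BASES = {"A", "C", "G", "T"}


@dataclass
class StrainAlleleRow:
    variant_key: str
    alleles: dict[str, Optional[str]] = field(default_factory=dict)
    consequence_label: str = ""


def concordance_check(row: StrainAlleleRow) -> str:
    """Classify one allele row: concordant / discordant / not_evaluable."""
    a = {s: row.alleles.get(s) for s in STRAINS}
    if any(v is None or v not in _BASES for v in a.values()):
        return NOT_EVALUABLE
    if (a["FatLine"] == a["NZO"] and a["LeanLine"] == a["A_J"]
            and a["FatLine"] != a["LeanLine"]):
        return CONCORDANT
    return DISCORDANT


def panel_from_variants(variants: list[Variant],
                        sample_map: Mapping[str, str],
                        labels: Optional[Mapping[str, str]] = None
                        ) -> dict[str, StrainAlleleRow]:
    """Build allele rows from a joint VCF's genotype calls.

    ``sample_map`` maps panel roles (FatLine/NZO/LeanLine/A_J) to VCF sample
    names.  Homozygous calls contribute their allele; heterozygous or missing
    calls leave the slot absent.  Indels are excluded (rows stay evaluable
    for SNPs only).
    """
    labels = labels or {}
    panel: dict[str, StrainAlleleRow] = {}
    for v in variants:
        if v.vtype != "SNP":
            continue
        alleles: dict[str, Optional[str]] = {}
        for role in STRAINS:
            sample = sample_map.get(role)
            call = v.genotypes.get(sample) if sample else None
            if call is not None and call.zygosity in (Zygosity.HOM_REF,
                                                      Zygosity.HOM_ALT):
                alleles[role] = call.allele
            else:
                alleles[role] = None
        panel[v.key] = StrainAlleleRow(
            variant_key=v.key, alleles=alleles,
            consequence_label=labels.get(v.key, ""))
    return panel


def validate_candidates(candidates: list[CandidateGene],
                        panel: Mapping[str, StrainAlleleRow]
                        ) -> tuple[list[CandidateGene], dict]:
    """Flag genes whose triggering SNPs segregate with phenotype.

    Sets ``MGI_validated`` on every gene with at least one concordant
    triggering variant (a concordant variant annotated to two genes validates
    both).  The summary counts distinct concordant SNPs by consequence label
    and distinct validated genes.
    """
    verdicts: dict[str, str] = {}
    for c in candidates:
        for t in c.triggering_variants:
            if t.variant_key in verdicts:
                continue
            row = panel.get(t.variant_key)
            verdicts[t.variant_key] = (concordance_check(row) if row
                                       else NOT_EVALUABLE)
    validated_genes = set()
    for c in candidates:
        if any(verdicts[t.variant_key] == CONCORDANT
               for t in c.triggering_variants):
            c.flags.add("MGI_validated")
            validated_genes.add(c.gene_id)

    by_label: dict[str, int] = {}
    seen: set[str] = set()
    for c in candidates:
        for t in c.triggering_variants:
            if verdicts[t.variant_key] != CONCORDANT or t.variant_key in seen:
                continue
            seen.add(t.variant_key)
            row = panel[t.variant_key]
            label = row.consequence_label or t.category.split(":", 1)[1]
            by_label[label] = by_label.get(label, 0) + 1
    summary = {
        "n_concordant_snps": len(seen),
        "n_validated_genes": len(validated_genes),
        "validated_genes": sorted(validated_genes),
        "concordant_by_label": dict(sorted(by_label.items())),
        "verdicts": verdicts,
    }
    return candidates, summary
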