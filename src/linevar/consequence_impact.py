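"""Consequence-term impact classes, deleterious-missense calls, and summaries.

Impact classes follow the Sequence Ontology groupings used by variant-effect
annotation: HIGH terms truncate or restructure the transcript, MODERATE terms
change protein sequence without truncation, and everything else (intronic,
synonymous, regulatory, intergenic, unknown terms) is OTHER for the purposes
of candidate selection.
"""

from __future__ import annotations

from enum import Enum

import pandas as pd

from .core_io import ConsequenceRecord

HIGH_IMPACT_TERMS = frozenset({
    "splice_acceptor_variant",
    "splice_donor_variant",
    "stop_gained",
    "frameshift_variant",
    "stop_lost",
    "start_lost",
    "transcript_amplification",
    "feature_elongation",
    "feature_truncation",
})

MODERATE_IMPACT_TERMS = frozenset({
    "inframe_insertion",
    "inframe_deletion",
    "missense_variant",
    "protein_altering_variant",
})

assert not (HIGH_IMPACT_TERMS & MODERATE_IMPACT_TERMS)

DELETERIOUS_SIFT = frozenset({"deleterious", "deleterious_low_confidence"})


class ImpactClass(Enum):
    HIGH = "HIGH"
    MODERATE = "MODERATE"
    OTHER = "OTHER"


_SEVERITY = {ImpactClass.HIGH: 2, ImpactClass.MODERATE: 1, ImpactClass.OTHER: 0}


def normalize_term(term: str) -> str:
    """Prose spellings ("missense variant") -> SO snake_case."""
    return term.strip().replace(" ", "_")


def impact_class(term: str) -> ImpactClass:
    term = normalize_term(term)
    if term in HIGH_IMPACT_TERMS:
        return ImpactClass.HIGH
    if term in MODERATE_IMPACT_TERMS:
        return ImpactClass.MODERATE
    return ImpactClass.OTHER


def most_severe_class(records: list[ConsequenceRecord]) -> ImpactClass:
    """Per-variant class: the most severe over all transcript annotations."""
    best = ImpactClass.OTHER
    for r in records:
        c = impact_class(r.consequence_term)
        if _SEVERITY[c] > _SEVERITY[best]:
            best = c
    return best


def is_deleterious_missense(r: ConsequenceRecord) -> bool:
    """Missense with a SIFT deleterious call, low-confidence included."""
    return (normalize_term(r.consequence_term) == "missense_variant"
            and r.sift in DELETERIOUS_SIFT)


def _records_by_key(records: list[ConsequenceRecord]
                    ) -> dict[str, list[ConsequenceRecord]]:
    by_key: dict[str, list[ConsequenceRecord]] = {}
    for r in records:
        by_key.setdefault(r.variant_key, []).append(r)
    return by_key


def biotype_summary(records: list[ConsequenceRecord], partition
                    ) -> pd.DataFrame:
    """Counts of variants per (biotype, line-set).

    A variant contributes once per distinct (biotype, set) pair, so a variant
    annotated to two protein-coding transcripts counts once for
    protein_coding, while one annotated to both a protein-coding gene and a
    lncRNA counts in both biotype rows.
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[str, dict[str, int]] = {}
    for r in records:
        line_set = partition.line_of(r.variant_key)
        if line_set is None:
            continue
        tag = (r.biotype, line_set, r.variant_key)
        if tag in seen:
            continue
        seen.add(tag)
        counts.setdefault(r.biotype, dict.fromkeys(
            ("fat", "lean", "shared"), 0))[line_set] += 1
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df.index.name = "biotype"
    return df.sort_index()


def consequence_proportions(records: list[ConsequenceRecord], partition
                            ) -> dict[str, dict[str, float | None]]:
    """Per-line fractions of synonymous, missense, and deleterious missense.

    Denominator for the synonymous/missense fractions is the count of
    line-specific SNP keys in the partition; the deleterious-missense share is
    computed among missense variants.  Variants are deduplicated per key (a
    variant is missense if any of its transcript annotations is), and the
    deleterious call uses any deleterious-annotated missense record.
    Zero-denominator fractions are reported as None.
    """
    by_key = _records_by_key(records)
    out: dict[str, dict[str, float | None]] = {}
    for line, keys in (("fat", partition.fat_private),
                       ("lean", partition.lean_private)):
        n = len(keys)
        syn = mis = dmv = 0
        for key in keys:
            recs = by_key.get(key, [])
            terms = {normalize_term(r.consequence_term) for r in recs}
            if "synonymous_variant" in terms:
                syn += 1
            if "missense_variant" in terms:
                mis += 1
                if any(is_deleterious_missense(r) for r in recs):
                    dmv += 1
        out[line] = {
            "synonymous": syn / n if n else None,
            "missense": mis / n if n else None,
            "dmv_share": dmv / mis if mis else None,
            "n_snps": n, "n_missense": mis, "n_dmv": dmv,
        }
    return out


def deleterious_missense_keys(records: list[ConsequenceRecord],
                              keys: set[str]) -> set[str]:
    """Variant keys in ``keys`` carrying a deleterious missense annotation."""
    return {r.variant_key for r in records
            if r.variant_key in keys and is_deleterious_missense(r)}
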