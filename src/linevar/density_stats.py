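"""Per-gene SNP counts/densities and per-transcript missense spacing.

SNP-to-gene assignment uses the genomic gene span (intronic and UTR hits
count), so the length denominator is ``end - start + 1`` rather than summed
exon length.  Mean missense spacing is protein length divided by missense
count — the reciprocal of density — with the alternative gap-based statistic
available behind a switch.
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

from .core_io import ConsequenceRecord, GeneModel, Variant
from .consequence_impact import normalize_term

HIGH_COUNT_THRESHOLD = 3000        # "at least 3000 SNPs"
HIGH_DENSITY_THRESHOLD = 4.0       # "at least four SNPs per 100 bp"
DENSE_SPACING_THRESHOLD = 25.0     # "intervals of fewer than 25 amino acids"


@dataclass(frozen=True)
class GeneDensityRecord:
    gene_id: str
    line_set: str            # fat | lean | shared
    snp_count: int
    length_bp: int
    density_per_100bp: float
    flag_high_count: bool
    flag_high_density: bool


@dataclass(frozen=True)
class MissenseSpacingRecord:
    transcript_id: str
    gene_id: str
    line_set: str
    missense_count: int
    protein_length_aa: int
    mean_spacing_aa: float
    flag_dense: bool


def gene_snp_stats(partition, variants: list[Variant],
                   genes: list[GeneModel],
                   include_zero: bool = False,
                   count_threshold: float = HIGH_COUNT_THRESHOLD,
                   density_threshold: float = HIGH_DENSITY_THRESHOLD,
                   ) -> list[GeneDensityRecord]:
    """Count SNPs per (gene, line-set) by positional containment.

    A SNP contributes to a gene iff its position lies in [start, end] on the
    same chromosome.  Indels are excluded (SNP statistics only).
    """
    trees: dict[str, IntervalTree] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for g in genes:
        # intervaltree is half-open; +1 makes [start, end] inclusive
        trees.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g.gene_id)

    counts: dict[tuple[str, str], int] = {}
    for v in variants:
        if v.vtype != "SNP":
            continue
        line_set = partition.line_of(v.key)
        if line_set is None:
            continue
        tree = trees.get(v.chrom)
        if tree is None:
            continue
        for hit in tree[v.pos]:
            counts[(hit.data, line_set)] = counts.get((hit.data, line_set), 0) + 1

    if include_zero:
        for g in genes:
            for line_set in ("fat", "lean", "shared"):
                counts.setdefault((g.gene_id, line_set), 0)

    records = []
    for (gene_id, line_set), n in sorted(counts.items()):
        g = gene_by_id[gene_id]
        density = 100.0 * n / g.length_bp
        records.append(GeneDensityRecord(
            gene_id=gene_id, line_set=line_set, snp_count=n,
            length_bp=g.length_bp, density_per_100bp=density,
            flag_high_count=n >= count_threshold,
            flag_high_density=density >= density_threshold,
        ))
    return records


def high_count_genes(records: list[GeneDensityRecord]) -> set[str]:
    return {r.gene_id for r in records if r.flag_high_count}


def missense_spacing(records: list[ConsequenceRecord],
                     genes: list[GeneModel], partition,
                     spacing_threshold: float = DENSE_SPACING_THRESHOLD,
                     use_gap_statistic: bool = False,
                     ) -> list[MissenseSpacingRecord]:
    """Per-transcript mean spacing between line-specific missense variants.

    Transcripts with zero line-specific missense annotations are unscored;
    transcripts lacking a protein length are skipped.  With
    ``use_gap_statistic`` the mean gap between sorted protein positions
    replaces the density reciprocal.
    """
    plen: dict[str, tuple[str, int | None]] = {}
    for g in genes:
        for tid, length in g.transcripts:
            plen[tid] = (g.gene_id, length)

    hits: dict[tuple[str, str], list[ConsequenceRecord]] = {}
    for r in records:
        if normalize_term(r.consequence_term) != "missense_variant":
            continue
        if r.transcript_id is None:
            continue
        line_set = partition.line_of(r.variant_key)
        if line_set not in ("fat", "lean"):
            continue
        hits.setdefault((r.transcript_id, line_set), []).append(r)

    out = []
    for (tid, line_set), recs in sorted(hits.items()):
        if tid not in plen or plen[tid][1] is None:
            import logging
            logging.getLogger("linevar").warning(
                "transcript %s has no protein length; skipped", tid)
            continue
        gene_id, length = plen[tid]
        n = len({r.variant_key for r in recs})
        if use_gap_statistic:
            positions = sorted({r.protein_position for r in recs
                                if r.protein_position is not None})
            if len(positions) < 2:
                continue
            spacing = (positions[-1] - positions[0]) / (len(positions) - 1)
        else:
            spacing = length / n
        out.append(MissenseSpacingRecord(
            transcript_id=tid, gene_id=gene_id, line_set=line_set,
            missense_count=n, protein_length_aa=length,
            mean_spacing_aa=spacing,
            flag_dense=spacing < spacing_threshold,
        ))
    return out
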