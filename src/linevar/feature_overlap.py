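"""QTL-interval membership and strand-aware miRNA seed-region overlap.

QTL membership is full containment for genes (the gene span must lie entirely
inside the interval) and point containment for variants; any-overlap is also
reported as a secondary result.  Seed overlap maps a genomic SNP position to
its 1-based index along the mature miRNA (from the 5' end), complementing
alleles on the minus strand, and reports the mutated seed 7-mer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .core_io import (GeneModel, Interval, MiRNARecord, Variant,
                      reverse_complement)

_RNA = str.maketrans("ACGT", "ACGU")


@dataclass(frozen=True)
class SeedOverlapResult:
    in_mature: bool
    in_seed: bool
    reference_seed: str
    mutated_seed: Optional[str] = None

    def __post_init__(self) -> None:
        if self.in_seed and not self.in_mature:
            raise ValueError("in_seed requires in_mature")
        if (self.mutated_seed is not None) != self.in_seed:
            raise ValueError("mutated_seed defined iff in_seed")
        if self.mutated_seed is not None:
            diffs = sum(a != b for a, b in
                        zip(self.reference_seed, self.mutated_seed))
            if diffs != 1:
                raise ValueError("mutated seed must differ at exactly one base")


def qtl_membership(item: Union[GeneModel, Variant], qtls: list[Interval],
                   mode: str = "containment") -> list[str]:
    """Names of QTL intervals the item belongs to.

    ``mode='containment'`` (primary): a gene is a member iff its whole span
    lies within the interval; a variant iff its position does.
    ``mode='overlap'`` (secondary): any base overlap suffices for genes.
    """
    if isinstance(item, GeneModel):
        lo, hi = item.start, item.end
        chrom = item.chrom
    else:
        lo = hi = item.pos
        chrom = item.chrom
    names = []
    for q in qtls:
        if q.chrom != chrom:
            continue
        if mode == "containment":
            hit = q.start <= lo and hi <= q.end
        elif mode == "overlap":
            hit = lo <= q.end and q.start <= hi
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if hit:
            names.append(q.name)
    return names


def _rna(base: str) -> str:
    return base.translate(_RNA)


def mature_index(pos: int, m: MiRNARecord) -> Optional[int]:
    """1-based index of a genomic position along the mature sequence (5'->3')."""
    if not (m.mature_start <= pos <= m.mature_end):
        return None
    if m.strand == "+":
        return pos - m.mature_start + 1
    return m.mature_end - pos + 1


def seed_overlap(v: Variant, m: MiRNARecord) -> SeedOverlapResult:
    """Locate a SNP within a mature miRNA and report the mutated seed.

    Raises ValueError when the VCF reference base disagrees with the mature
    sequence at the mapped index (annotation inconsistent with coordinates).
    """
    if v.vtype != "SNP":
        raise ValueError(f"seed_overlap requires a SNP, got {v.key}")
    seed = m.seed
    idx = None
    if v.chrom == m.chrom:
        idx = mature_index(v.pos, m)
    if idx is None:
        return SeedOverlapResult(in_mature=False, in_seed=False,
                                 reference_seed=seed)
    ref = v.ref if m.strand == "+" else reverse_complement(v.ref)
    alt = v.alt if m.strand == "+" else reverse_complement(v.alt)
    if m.mature_sequence[idx - 1] != _rna(ref):
        raise ValueError(
            f"{m.mature_name}: mature base {m.mature_sequence[idx - 1]} at "
            f"index {idx} disagrees with VCF ref {ref} ({v.key})")
    lo, hi = m.seed_offsets
    if not (lo <= idx <= hi):
        return SeedOverlapResult(in_mature=True, in_seed=False,
                                 reference_seed=seed)
    seed_pos = idx - lo
    mutated = seed[:seed_pos] + _rna(alt) + seed[seed_pos + 1:]
    return SeedOverlapResult(in_mature=True, in_seed=True,
                             reference_seed=seed, mutated_seed=mutated)


def scan_seed_overlaps(variants: list[Variant], mirnas: list[MiRNARecord],
                       keys: Optional[set[str]] = None
                       ) -> list[tuple[str, str, SeedOverlapResult]]:
    """All (variant_key, mature_name, result) pairs with in_mature true.

    ``keys`` restricts the scan (e.g. to line-specific SNPs).
    """
    out = []
    for v in variants:
        if v.vtype != "SNP":
            continue
        if keys is not None and v.key not in keys:
            continue
        for m in mirnas:
            if v.chrom != m.chrom:
                continue
            res = seed_overlap(v, m)
            if res.in_mature:
                out.append((v.key, m.mature_name, res))
    return out
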