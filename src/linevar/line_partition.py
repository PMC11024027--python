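"""Partition homozygous variants into line-private and shared sets.

A variant (one split (chrom, pos, ref, alt) key) is private to one selection
line when that line is homozygous-alternate and the other homozygous-reference
relative to the reference genome; it is shared when both lines are
homozygous-alternate for the identical alt allele.  The same site carrying
different alts in the two lines therefore yields two private keys, matching
Ensembl variant identity.  Sites homozygous-reference in both lines (called
only because a reference strain in the joint VCF carries the alt) are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .core_io import Variant, Zygosity

_RS_PATTERN = re.compile(r"^rs\d+$")


@dataclass
class LinePartition:
    fat_private: set[str] = field(default_factory=set)
    lean_private: set[str] = field(default_factory=set)
    shared: set[str] = field(default_factory=set)
    dropped: set[str] = field(default_factory=set)
    novel: set[str] = field(default_factory=set)

    @property
    def line_specific(self) -> set[str]:
        return self.fat_private | self.lean_private

    def line_of(self, key: str) -> str | None:
        if key in self.fat_private:
            return "fat"
        if key in self.lean_private:
            return "lean"
        if key in self.shared:
            return "shared"
        return None

    def validate(self) -> None:
        sets = [self.fat_private, self.lean_private, self.shared]
        total = sum(len(s) for s in sets)
        if len(self.fat_private | self.lean_private | self.shared) != total:
            raise ValueError("partition sets are not pairwise disjoint")
        if not self.novel <= (self.line_specific | self.shared):
            raise ValueError("novel keys outside the partition union")


def classify_novelty(v: Variant) -> str:
    """'known' only for dbSNP-style ``rs<digits>`` identifiers."""
    if v.id is not None and _RS_PATTERN.match(v.id):
        return "known"
    return "novel"


def partition(variants: list[Variant], fat_sample: str, lean_sample: str
              ) -> LinePartition:
    """Three-way private/shared split of homozygous calls.

    Input variants are expected to have passed the hard filters and the
    homozygosity requirement; any residual heterozygous or missing call sends
    the variant to ``dropped``.
    """
    p = LinePartition()
    for v in variants:
        for s in (fat_sample, lean_sample):
            if s not in v.genotypes:
                raise KeyError(f"sample {s!r} not genotyped at {v.key}")
        fat = v.genotypes[fat_sample].zygosity
        lean = v.genotypes[lean_sample].zygosity
        if fat is Zygosity.HOM_ALT and lean is Zygosity.HOM_REF:
            p.fat_private.add(v.key)
        elif lean is Zygosity.HOM_ALT and fat is Zygosity.HOM_REF:
            p.lean_private.add(v.key)
        elif fat is Zygosity.HOM_ALT and lean is Zygosity.HOM_ALT:
            # split keys make alt identity implicit: both HOM_ALT on the same
            # record means the identical alt allele
            p.shared.add(v.key)
        else:
            p.dropped.add(v.key)
            continue
        if classify_novelty(v) == "novel":
            p.novel.add(v.key)
    p.validate()
    return p


def chromosome_summary(p: LinePartition, variants: list[Variant],
                       chromosomes: list[str] | None = None) -> pd.DataFrame:
    """Per-chromosome counts of the partition sets plus novelty.

    ``chromosomes`` (e.g. the VCF header contigs) forces all-zero rows for
    chromosomes without variants.  Per-line totals (private + shared) are also
    reported, since published line totals include shared variants.
    """
    by_key = {v.key: v for v in variants}
    chroms = list(chromosomes) if chromosomes else []
    counts: dict[str, dict[str, int]] = {
        c: dict.fromkeys(
            ("fat_private", "lean_private", "shared", "novel"), 0)
        for c in chroms}

    def bump(key: str, col: str) -> None:
        chrom = by_key[key].chrom
        if chrom not in counts:
            counts[chrom] = dict.fromkeys(
                ("fat_private", "lean_private", "shared", "novel"), 0)
        counts[chrom][col] += 1

    for key in p.fat_private:
        bump(key, "fat_private")
    for key in p.lean_private:
        bump(key, "lean_private")
    for key in p.shared:
        bump(key, "shared")
    for key in p.novel:
        bump(key, "novel")
    df = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    df.index.name = "chrom"
    df["fat_total"] = df["fat_private"] + df["shared"]
    df["lean_total"] = df["lean_private"] + df["shared"]
    return df.sort_index()
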