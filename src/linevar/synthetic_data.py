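"""Synthetic input bundle generator with a planted truth set.

The generator emits the complete set of inputs the pipeline consumes — a
joint four-sample VCF (the two selection lines plus the NZO-like obese and
A/J-like lean reference strains), a VEP-style consequence table, a GERP score
table, gene models, QTL intervals, miRNA records, and a gene flag table —
together with a machine-readable truth set.  Everything the pipeline is
supposed to find is planted constructively:

* line-private / shared homozygous variants at exact configured fractions;
* hard-filter failures that each violate exactly one named SNP criterion;
* candidate genes satisfying the full selection rule (line-specific, GERP > 6,
  regulatory or moderate/high impact) with reference-strain alleles matching
  the obese-with-obese / lean-with-lean concordance pattern;
* decoy variants passing exactly two of the three selection clauses, plus one
  candidate whose panel alleles are deliberately discordant, so a pipeline
  that drops any clause fails the recovery check;
* seed-region SNPs in mature miRNAs on both strands, one reproducing the
  CCAAUGA -> CCAAUGG single-base seed substitution pattern.

Output is byte-identical for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from intervaltree import IntervalTree

from .core_io import (GeneModel, GenotypeCall, Interval, MiRNARecord, Variant,
                      ConsequenceRecord, Zygosity, reverse_complement,
                      write_consequence_table, write_flag_table,
                      write_gene_models, write_gerp_table, write_intervals,
                      write_mirnas, write_vcf)

SAMPLES = ("FatLine", "LeanLine", "NZO", "A_J")

_REG_CLASSES = ("promoter", "promoter_flanking_region", "enhancer",
                "CTCF_binding_site", "TF_binding_site",
                "open_chromatin_region")
_IMPACT_TERMS = ("missense_variant", "stop_gained", "inframe_deletion",
                 "protein_altering_variant", "splice_donor_variant")
_BASES = np.array(list("ACGT"))

# one-criterion violations used for planted hard-filter failures
_SNP_FAIL_VALUES = {
    "QD": 1.0, "QUAL": 10.0, "MQ": 30.0, "SOR": 4.5, "FS": 80.0,
    "MQRankSum": -13.5, "ReadPosRankSum": -9.0, "DP": 25.0,
}


@dataclass(frozen=True)
class GerpMixture:
    """Two-component score distribution: a neutral bulk near 0 and a thin
    conserved tail spanning the upper tiers, so the >2 / >4 / >6 tier counts
    are non-trivial but small."""

    bulk_mean: float = 0.0
    bulk_sd: float = 1.0
    tail_frac: float = 0.02
    tail_low: float = 2.0
    tail_high: float = 9.0


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 1
    n_chromosomes: int = 4               # last one is named Y
    chrom_length_bp: int = 1_000_000
    n_genes: int = 60
    n_regulatory_features: int = 30
    n_mirnas: int = 4
    n_qtls: int = 2
    n_variants_total: int = 5000
    frac_shared: float = 0.4
    frac_fat_private: float = 0.2
    frac_lean_private: float = 0.2
    frac_novel: float = 0.2
    frac_fail_hard_filter: float = 0.1
    frac_indel: float = 0.04
    gerp_mixture: GerpMixture = GerpMixture()
    n_planted_candidates: int = 6
    n_decoys_per_class: int = 3

    def validate(self) -> None:
        fracs = (self.frac_shared, self.frac_fat_private,
                 self.frac_lean_private, self.frac_novel,
                 self.frac_fail_hard_filter, self.frac_indel)
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_shared + self.frac_fat_private + self.frac_lean_private > 1:
            raise ValueError("partition fractions sum above 1")
        if min(self.n_chromosomes, self.n_genes, self.n_variants_total,
               self.n_qtls, self.n_mirnas, self.n_planted_candidates,
               self.n_decoys_per_class) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_planted_candidates > self.n_genes:
            raise ValueError("more planted candidates than genes")


@dataclass
class TruthSet:
    seed: int
    partition_counts: dict[str, int] = field(default_factory=dict)
    partition_labels: dict[str, str] = field(default_factory=dict)
    hard_filter_fail: dict[str, str] = field(default_factory=dict)
    candidates: list[dict] = field(default_factory=list)
    decoys: dict[str, list[str]] = field(default_factory=dict)
    seed_cases: list[dict] = field(default_factory=list)
    novel_keys: list[str] = field(default_factory=list)

    @property
    def candidate_genes(self) -> set[str]:
        return {c["gene_id"] for c in self.candidates}

    @property
    def validated_genes(self) -> set[str]:
        return {c["gene_id"] for c in self.candidates if c["validated"]}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SyntheticBundle:
    config: SynthConfig
    truth: TruthSet
    paths: dict[str, Path]
    variants: list[Variant]
    consequences: list[ConsequenceRecord]
    gerp: dict[str, float]
    genes: list[GeneModel]
    qtls: list[Interval]
    mirnas: list[MiRNARecord]
    flags: dict[str, set[str]]


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _chrom_names(n: int) -> list[str]:
    if n <= 1:
        return ["1"]
    return [str(i) for i in range(1, n)] + ["Y"]


def _make_genes(cfg: SynthConfig, rng: np.random.Generator
                ) -> list[GeneModel]:
    chroms = _chrom_names(cfg.n_chromosomes)
    genes: list[GeneModel] = []
    slot = 20_000  # non-overlapping layout grid
    per_chrom: dict[str, int] = dict.fromkeys(chroms, 0)
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        k = per_chrom[chrom]
        per_chrom[chrom] += 1
        start = 10_000 + k * slot
        length = int(rng.integers(2_000, 15_000))
        end = min(start + length, cfg.chrom_length_bp - 1)
        u = rng.random()
        if u < 0.70:
            biotype = "protein_coding"
        elif u < 0.85:
            biotype = "lncRNA"
        elif u < 0.95:
            biotype = "pseudogene"
        else:
            biotype = "IG_V_gene"
        transcripts: list[tuple[str, Optional[int]]] = []
        if biotype == "protein_coding":
            for t in range(int(rng.integers(1, 3))):
                transcripts.append((f"SYNT{i:04d}.{t + 1}",
                                    int(rng.integers(100, 1000))))
        else:
            transcripts.append((f"SYNT{i:04d}.1", None))
        symbol = f"Gene{i:03d}"
        if chrom == "Y" and all(g.chrom != "Y" for g in genes):
            symbol = "ParLike1"  # pseudoautosomal-like Y gene
        genes.append(GeneModel(
            gene_id=f"SYNG{i:04d}", gene_symbol=symbol, biotype=biotype,
            chrom=chrom, start=start, end=end,
            strand="+" if rng.random() < 0.5 else "-",
            transcripts=tuple(transcripts)))
    return genes


def _make_qtls(cfg: SynthConfig, genes: list[GeneModel]) -> list[Interval]:
    chroms = _chrom_names(cfg.n_chromosomes)
    qtls = []
    for i in range(cfg.n_qtls):
        chrom = chroms[i % max(len(chroms) - 1, 1)]  # keep QTLs off Y
        members = [g for g in genes if g.chrom == chrom][:4]
        if not members:
            continue
        start = max(min(g.start for g in members) - 1_000, 1)
        end = max(g.end for g in members) + 1_000
        qtls.append(Interval(name=f"Fob{i + 1}", chrom=chrom,
                             start=start, end=end))
    return qtls


_SEED_7MER = "CCAAUGA"


def _make_mirnas(cfg: SynthConfig, rng: np.random.Generator,
                 genes: list[GeneModel]) -> list[MiRNARecord]:
    """Mature miRNAs placed in intergenic space; the first two carry the
    CCAAUGA seed, one per strand."""
    chroms = _chrom_names(cfg.n_chromosomes)
    mirnas = []
    for i in range(cfg.n_mirnas):
        chrom = chroms[i % len(chroms)]
        start = cfg.chrom_length_bp - 50_000 + i * 200
        if i < 2:
            tail = "".join(rng.choice(list("ACGU"), size=14))
            seq = "U" + _SEED_7MER + tail
            strand = "+" if i == 0 else "-"
        else:
            seq = "".join(rng.choice(list("ACGU"), size=22))
            strand = "+" if rng.random() < 0.5 else "-"
        mirnas.append(MiRNARecord(
            gene_id=f"SYNMIRG{i:02d}", mature_name=f"syn-miR-{i + 1}-3p",
            chrom=chrom, mature_start=start, mature_end=start + len(seq) - 1,
            strand=strand, mature_sequence=seq))
    return mirnas


def _passing_metrics(rng: np.random.Generator) -> tuple[float, dict]:
    """QC values comfortably on the passing side of every criterion."""
    qual = round(float(rng.uniform(60, 2000)), 1)
    metrics = {
        "QD": round(float(rng.uniform(5, 35)), 2),
        "MQ": round(float(rng.uniform(45, 60)), 2),
        "SOR": round(float(rng.uniform(0.2, 2.5)), 2),
        "FS": round(float(rng.uniform(0.0, 20.0)), 2),
        "MQRankSum": (None if rng.random() < 0.3
                      else round(float(rng.uniform(-3, 3)), 2)),
        "ReadPosRankSum": (None if rng.random() < 0.3
                           else round(float(rng.uniform(-3, 3)), 2)),
        "DP": float(int(rng.integers(31, 200))),
    }
    return qual, metrics


def _gt(z: Zygosity, ref: str, alt: str) -> GenotypeCall:
    allele = {Zygosity.HOM_REF: ref, Zygosity.HOM_ALT: alt}.get(z)
    return GenotypeCall(z, allele)


def _genotypes(label: str, ref: str, alt: str, rng: np.random.Generator,
               panel: Optional[tuple[Zygosity, Zygosity]] = None
               ) -> dict[str, GenotypeCall]:
    """Genotypes for the four samples given the planted partition label."""
    HOM_ALT, HOM_REF, HET = Zygosity.HOM_ALT, Zygosity.HOM_REF, Zygosity.HET
    if label == "fat_private":
        fat, lean = HOM_ALT, HOM_REF
    elif label == "lean_private":
        fat, lean = HOM_REF, HOM_ALT
    elif label == "shared":
        fat = lean = HOM_ALT
    elif label == "het":
        if rng.random() < 0.5:
            fat, lean = HET, HOM_REF
        else:
            fat, lean = HOM_REF, HET
    elif label == "panel_only":
        fat = lean = HOM_REF
    else:  # pragma: no cover
        raise ValueError(label)
    if panel is None:
        nzo = HOM_ALT if rng.random() < 0.3 else HOM_REF
        aj = HOM_ALT if rng.random() < 0.3 else HOM_REF
        if label == "panel_only" and nzo is HOM_REF and aj is HOM_REF:
            nzo = HOM_ALT
        panel = (nzo, aj)
    return {
        "FatLine": _gt(fat, ref, alt), "LeanLine": _gt(lean, ref, alt),
        "NZO": _gt(panel[0], ref, alt), "A_J": _gt(panel[1], ref, alt),
    }


def _alleles(rng: np.random.Generator, indel: bool = False
             ) -> tuple[str, str]:
    ref, alt = rng.choice(_BASES, size=2, replace=False)
    if indel:
        if rng.random() < 0.5:
            return str(ref), str(ref) + str(alt)   # insertion
        return str(ref) + str(alt), str(ref)       # deletion
    return str(ref), str(alt)


class _PositionPool:
    """Unique genomic positions, with reservation for planted variants."""

    def __init__(self, chroms: list[str], length: int,
                 rng: np.random.Generator) -> None:
        self.chroms = chroms
        self.length = length
        self.rng = rng
        self.used: set[tuple[str, int]] = set()

    def reserve(self, chrom: str, pos: int) -> int:
        if (chrom, pos) in self.used:
            raise RuntimeError(f"position {chrom}:{pos} already planted")
        self.used.add((chrom, pos))
        return pos

    def draw(self, chrom: Optional[str] = None,
             lo: int = 1, hi: Optional[int] = None) -> tuple[str, int]:
        if chrom is None:
            chrom = self.chroms[int(self.rng.integers(0, len(self.chroms)))]
        hi = hi or self.length
        for _ in range(1000):
            pos = int(self.rng.integers(lo, hi))
            if (chrom, pos) not in self.used:
                self.used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("position pool exhausted")


def plant_candidate(gene: GeneModel, category: str, line: str,
                    rng: np.random.Generator, pool: _PositionPool,
                    rs_id: str, concordant: bool = True
                    ) -> tuple[Variant, list[ConsequenceRecord], float]:
    """Construct one candidate-triggering variant inside ``gene``.

    The variant is homozygous-alt in exactly ``line``; its GERP score is drawn
    from (6, 9]; the annotation is a regulatory-feature record or a
    moderate/high-impact consequence.  Reference-strain alleles follow the
    concordant obese/lean pattern (Fat==NZO != Lean==A_J) unless
    ``concordant`` is false, in which case both reference strains carry the
    reference allele and the row cannot validate.
    """
    if category == "impact" and not gene.transcripts:
        raise ValueError(f"{gene.gene_id} has no transcript for impact category")
    _, pos = pool.draw(chrom=gene.chrom, lo=gene.start, hi=gene.end + 1)
    ref, alt = _alleles(rng)
    gerp = round(float(rng.uniform(6.0 + 1e-6, 9.0)), 2)
    HOM_ALT, HOM_REF = Zygosity.HOM_ALT, Zygosity.HOM_REF
    if not concordant:
        panel = (HOM_REF, HOM_REF)
    elif line == "fat":
        panel = (HOM_ALT, HOM_REF)
    else:
        panel = (HOM_REF, HOM_ALT)
    label = "fat_private" if line == "fat" else "lean_private"
    qual, metrics = _passing_metrics(rng)
    v = Variant(chrom=gene.chrom, pos=pos, id=rs_id, ref=ref, alt=alt,
                qual=qual, metrics=metrics,
                genotypes=_genotypes(label, ref, alt, rng, panel=panel))
    if category == "regulatory":
        reg_class = str(rng.choice(_REG_CLASSES))
        records = [ConsequenceRecord(
            variant_key=v.key, gene_id=gene.gene_id,
            gene_symbol=gene.gene_symbol, transcript_id=None,
            consequence_term="regulatory_region_variant",
            biotype=gene.biotype, regulatory_class=reg_class)]
    else:
        term = str(rng.choice(_IMPACT_TERMS))
        tid, plen = gene.transcripts[0]
        records = [ConsequenceRecord(
            variant_key=v.key, gene_id=gene.gene_id,
            gene_symbol=gene.gene_symbol, transcript_id=tid,
            consequence_term=term, biotype=gene.biotype,
            sift=("deleterious" if term == "missense_variant" else None),
            protein_position=(int(rng.integers(1, plen + 1))
                              if plen and term == "missense_variant" else None))]
    return v, records, gerp


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

def generate_bundle(config: SynthConfig, outdir: str | Path
                    ) -> SyntheticBundle:
    """Generate and write the full synthetic input bundle.

    Deterministic for a fixed ``config.seed``: two runs produce byte-identical
    files.  Raises when the configuration cannot accommodate the planted
    structure (e.g. private-variant quotas smaller than the planted variants).
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    chroms = _chrom_names(config.n_chromosomes)

    genes = _make_genes(config, rng)
    qtls = _make_qtls(config, genes)
    mirnas = _make_mirnas(config, rng, genes)
    truth = TruthSet(seed=config.seed)
    pool = _PositionPool(chroms, config.chrom_length_bp, rng)
    # mature miRNA spans hold only deliberately planted SNPs: a random
    # background allele there would contradict the mature sequence
    for m in mirnas:
        for p in range(m.mature_start, m.mature_end + 1):
            pool.used.add((m.chrom, p))

    gene_tree: dict[str, IntervalTree] = {}
    for g in genes:
        gene_tree.setdefault(g.chrom, IntervalTree()).addi(
            g.start, g.end + 1, g)
    reg_features = []
    for i in range(config.n_regulatory_features):
        chrom = chroms[i % len(chroms)]
        start = int(rng.integers(1, config.chrom_length_bp - 2_000))
        reg_features.append((chrom, start, start + int(rng.integers(200, 2_000)),
                             str(rng.choice(_REG_CLASSES))))

    N = config.n_variants_total
    n_shared = round(config.frac_shared * N)
    n_fat = round(config.frac_fat_private * N)
    n_lean = round(config.frac_lean_private * N)
    n_rest = N - n_shared - n_fat - n_lean
    n_fail = round(config.frac_fail_hard_filter * N)
    if n_fail > n_rest:
        raise ValueError("frac_fail_hard_filter exceeds the non-partitioned "
                         "variant budget")

    variants: list[Variant] = []
    consequences: list[ConsequenceRecord] = []
    gerp: dict[str, float] = {}
    quota_used = {"fat_private": 0, "lean_private": 0, "shared": 0}
    rs_counter = 1_000_000

    def next_rs() -> str:
        nonlocal rs_counter
        rs_counter += 1
        return f"rs{rs_counter}"

    # --- planted candidates -------------------------------------------------
    protein_genes = [g for g in genes if g.biotype == "protein_coding"]
    candidate_genes: list[GeneModel] = []
    need_impact = sum(1 for i in range(config.n_planted_candidates)
                      if i % 2 == 1)
    if len(protein_genes) < need_impact + config.n_decoys_per_class + 1:
        raise ValueError("not enough protein-coding genes for the planted "
                         "structure")
    qtl_gene_ids = {g.gene_id for g in genes
                    if any(q.chrom == g.chrom and q.start <= g.start
                           and g.end <= q.end for q in qtls)}

    used_genes: set[str] = set()

    def take_gene(need_protein: bool, prefer_qtl: bool = False) -> GeneModel:
        src = protein_genes if need_protein else genes
        ordered = sorted(src, key=lambda g: (g.gene_id not in qtl_gene_ids
                                             if prefer_qtl else False,
                                             g.gene_id))
        for g in ordered:
            if g.gene_id not in used_genes:
                used_genes.add(g.gene_id)
                return g
        raise ValueError("gene pool exhausted for planted structure")

    dual_gene: Optional[GeneModel] = None
    for i in range(config.n_planted_candidates):
        category = "impact" if i % 2 else "regulatory"
        line = "fat" if i % 2 == 0 else "lean"
        gene = take_gene(need_protein=(category == "impact"),
                         prefer_qtl=(i == 0))
        v, recs, score = plant_candidate(gene, category, line, rng, pool,
                                         next_rs())
        # the last regulatory candidate is annotated to a second gene,
        # exercising one-SNP-two-genes aggregation
        if (category == "regulatory"
                and i == config.n_planted_candidates - 2
                and config.n_planted_candidates >= 2):
            dual_gene = take_gene(need_protein=False)
            recs.append(dataclasses.replace(
                recs[0], gene_id=dual_gene.gene_id,
                gene_symbol=dual_gene.gene_symbol, biotype=dual_gene.biotype))
        label = "fat_private" if line == "fat" else "lean_private"
        quota_used[label] += 1
        variants.append(v)
        consequences.extend(recs)
        gerp[v.key] = score
        truth.partition_labels[v.key] = label
        for r in recs:
            truth.candidates.append({
                "gene_id": r.gene_id, "gene_symbol": r.gene_symbol,
                "variant_key": v.key, "line": line,
                "category": (f"regulatory:{r.regulatory_class}"
                             if r.regulatory_class
                             else f"impact:{r.consequence_term}"),
                "validated": True,
                "fob_qtl": r.gene_id in qtl_gene_ids,
            })
        candidate_genes.append(gene)

    # one selected-but-discordant candidate: same selection clauses, panel
    # alleles identical across all four strains
    if config.n_planted_candidates > 0:
        gene = take_gene(need_protein=True)
        v, recs, score = plant_candidate(gene, "impact", "fat", rng, pool,
                                         next_rs(), concordant=False)
        quota_used["fat_private"] += 1
        variants.append(v)
        consequences.extend(recs)
        gerp[v.key] = score
        truth.partition_labels[v.key] = "fat_private"
        truth.candidates.append({
            "gene_id": gene.gene_id, "gene_symbol": gene.gene_symbol,
            "variant_key": v.key, "line": "fat",
            "category": f"impact:{recs[0].consequence_term}",
            "validated": False, "fob_qtl": gene.gene_id in qtl_gene_ids,
        })

    # --- decoys: exactly two of the three clauses ---------------------------
    truth.decoys = {"conserved_unannotated": [], "regulatory_low_gerp": [],
                    "conserved_impact_shared": []}
    for j in range(config.n_decoys_per_class):
        line = "fat" if j % 2 == 0 else "lean"
        label = f"{line}_private"

        # (a) line-specific + GERP>6, but intronic with no regulatory class
        gene = take_gene(need_protein=False)
        _, pos = pool.draw(chrom=gene.chrom, lo=gene.start, hi=gene.end + 1)
        ref, alt = _alleles(rng)
        qual, metrics = _passing_metrics(rng)
        v = Variant(chrom=gene.chrom, pos=pos, id=next_rs(), ref=ref, alt=alt,
                    qual=qual, metrics=metrics,
                    genotypes=_genotypes(label, ref, alt, rng))
        variants.append(v)
        consequences.append(ConsequenceRecord(
            variant_key=v.key, gene_id=gene.gene_id,
            gene_symbol=gene.gene_symbol, transcript_id=None,
            consequence_term="intron_variant", biotype=gene.biotype))
        gerp[v.key] = round(float(rng.uniform(6.0 + 1e-6, 9.0)), 2)
        truth.partition_labels[v.key] = label
        quota_used[label] += 1
        truth.decoys["conserved_unannotated"].append(v.key)

        # (b) line-specific + regulatory, but GERP below threshold
        gene = take_gene(need_protein=False)
        v2, recs2, _ = plant_candidate(gene, "regulatory", line, rng, pool,
                                       next_rs())
        gerp[v2.key] = round(float(rng.uniform(2.0, 5.5)), 2)
        variants.append(v2)
        consequences.extend(recs2)
        truth.partition_labels[v2.key] = label
        quota_used[label] += 1
        truth.decoys["regulatory_low_gerp"].append(v2.key)

        # (c) GERP>6 + moderate impact, but shared between the lines
        gene = take_gene(need_protein=True)
        _, pos = pool.draw(chrom=gene.chrom, lo=gene.start, hi=gene.end + 1)
        ref, alt = _alleles(rng)
        qual, metrics = _passing_metrics(rng)
        v3 = Variant(chrom=gene.chrom, pos=pos, id=next_rs(), ref=ref,
                     alt=alt, qual=qual, metrics=metrics,
                     genotypes=_genotypes("shared", ref, alt, rng))
        tid, plen = gene.transcripts[0]
        variants.append(v3)
        consequences.append(ConsequenceRecord(
            variant_key=v3.key, gene_id=gene.gene_id,
            gene_symbol=gene.gene_symbol, transcript_id=tid,
            consequence_term="missense_variant", biotype=gene.biotype,
            sift="deleterious",
            protein_position=int(rng.integers(1, (plen or 100) + 1))))
        gerp[v3.key] = round(float(rng.uniform(6.0 + 1e-6, 9.0)), 2)
        truth.partition_labels[v3.key] = "shared"
        quota_used["shared"] += 1
        truth.decoys["conserved_impact_shared"].append(v3.key)

    # --- seed-region SNPs, one per strand -----------------------------------
    for m in mirnas[:2]:
        lo, hi = m.seed_offsets
        idx = hi  # mutate the final seed base (A -> G): CCAAUGA -> CCAAUGG
        if m.strand == "+":
            pos = m.mature_start + idx - 1
            ref = m.mature_sequence[idx - 1].replace("U", "T")
            alt = "G"
        else:
            pos = m.mature_end - idx + 1
            ref = reverse_complement(m.mature_sequence[idx - 1].replace("U", "T"))
            alt = reverse_complement("G")
        line = "lean" if m.strand == "+" else "fat"
        label = f"{line}_private"
        qual, metrics = _passing_metrics(rng)
        v = Variant(chrom=m.chrom, pos=pos, id=next_rs(), ref=ref, alt=alt,
                    qual=qual, metrics=metrics,
                    genotypes=_genotypes(label, ref, alt, rng))
        variants.append(v)
        gerp[v.key] = round(float(rng.normal(0, 1)), 2)
        truth.partition_labels[v.key] = label
        quota_used[label] += 1
        mutated = m.seed[:-1] + "G"
        truth.seed_cases.append({
            "variant_key": v.key, "mature_name": m.mature_name,
            "strand": m.strand, "reference_seed": m.seed,
            "mutated_seed": mutated,
        })

    for label, used in quota_used.items():
        target = {"fat_private": n_fat, "lean_private": n_lean,
                  "shared": n_shared}[label]
        if used > target:
            raise ValueError(
                f"planted structure needs {used} {label} variants but the "
                f"quota is {target}; increase n_variants_total or fractions")

    # --- background variants -------------------------------------------------
    mix = config.gerp_mixture
    fail_criteria = list(_SNP_FAIL_VALUES)
    n_fail_made = 0

    def background_variant(label: str, force_snp: bool = False,
                           fail_criterion: Optional[str] = None) -> None:
        chrom, pos = pool.draw()
        indel = (not force_snp) and rng.random() < config.frac_indel
        ref, alt = _alleles(rng, indel=indel)
        qual, metrics = _passing_metrics(rng)
        if fail_criterion == "QUAL":
            qual = _SNP_FAIL_VALUES["QUAL"]
        elif fail_criterion is not None:
            metrics[fail_criterion] = _SNP_FAIL_VALUES[fail_criterion]
        novel = rng.random() < config.frac_novel
        vid = None if novel else next_rs()
        v = Variant(chrom=chrom, pos=pos, id=vid, ref=ref, alt=alt,
                    qual=qual, metrics=metrics,
                    genotypes=_genotypes(label, ref, alt, rng))
        variants.append(v)
        if novel:
            truth.novel_keys.append(v.key)
        if fail_criterion is not None:
            truth.hard_filter_fail[v.key] = fail_criterion
            truth.partition_labels[v.key] = "filtered"
        elif label in ("fat_private", "lean_private", "shared"):
            truth.partition_labels[v.key] = label
        else:
            truth.partition_labels[v.key] = "excluded"
        # annotations
        line_specific = (fail_criterion is None
                         and label in ("fat_private", "lean_private"))
        annotated_special = False
        hits = gene_tree.get(chrom, IntervalTree())[pos]
        if hits:
            g: GeneModel = next(iter(hits)).data
            u = rng.random()
            term, sift, ppos, tid = "intron_variant", None, None, None
            if not indel and g.biotype == "protein_coding" and g.transcripts:
                if u < 0.004:
                    term = "missense_variant"
                    sift = ("deleterious" if rng.random() < 0.17
                            else "tolerated")
                    tid, plen = g.transcripts[0]
                    ppos = int(rng.integers(1, (plen or 100) + 1))
                    annotated_special = True
                elif u < 0.011:
                    term = "synonymous_variant"
                    tid = g.transcripts[0][0]
            consequences.append(ConsequenceRecord(
                variant_key=v.key, gene_id=g.gene_id,
                gene_symbol=g.gene_symbol, transcript_id=tid,
                consequence_term=term, biotype=g.biotype,
                sift=sift, protein_position=ppos))
        else:
            for (rc, rs, re_, rclass) in reg_features:
                if rc == chrom and rs <= pos <= re_:
                    near = min(genes, key=lambda g: (g.chrom != chrom,
                                                     abs(g.start - pos)))
                    consequences.append(ConsequenceRecord(
                        variant_key=v.key, gene_id=near.gene_id,
                        gene_symbol=near.gene_symbol, transcript_id=None,
                        consequence_term="regulatory_region_variant",
                        biotype=near.biotype, regulatory_class=rclass))
                    annotated_special = True
                    break
        if not indel:
            # keep unplanted variants out of the candidate surface: anything
            # line-specific carrying a regulatory or impact annotation draws
            # from the neutral bulk only
            if rng.random() < mix.tail_frac and not (line_specific
                                                     and annotated_special):
                score = float(rng.uniform(mix.tail_low + 1e-6, mix.tail_high))
            else:
                # 5.9 keeps every unplanted annotated line-specific variant
                # below the 6.0 selection threshold
                score = min(float(rng.normal(mix.bulk_mean, mix.bulk_sd)), 5.9)
            gerp[v.key] = round(score, 2)

    for label, total in (("fat_private", n_fat), ("lean_private", n_lean),
                         ("shared", n_shared)):
        for _ in range(total - quota_used[label]):
            background_variant(label)
    for i in range(n_fail):
        background_variant("het" if rng.random() < 0.5 else "panel_only",
                           force_snp=True,
                           fail_criterion=fail_criteria[i % len(fail_criteria)])
        n_fail_made += 1
    for _ in range(n_rest - n_fail):
        background_variant("het" if rng.random() < 0.5 else "panel_only")

    truth.partition_counts = {"fat_private": n_fat, "lean_private": n_lean,
                              "shared": n_shared}

    # --- flag table ----------------------------------------------------------
    flag_vocab = ("IMPC_adipose", "GO_keyword", "MP_keyword",
                  "disease_keyword", "expression_diff")
    flags: dict[str, set[str]] = {}
    for c in truth.candidates:
        chosen = {f for f in flag_vocab if rng.random() < 0.4}
        if c["gene_id"] in flags:
            chosen |= flags[c["gene_id"]]
        flags[c["gene_id"]] = chosen
        c["flags"] = sorted(chosen)
    for g in genes[:5]:
        if g.gene_id not in flags:
            flags[g.gene_id] = {f for f in flag_vocab if rng.random() < 0.2}

    # --- write ---------------------------------------------------------------
    chrom_order = {c: i for i, c in enumerate(chroms)}
    variants.sort(key=lambda v: (chrom_order[v.chrom], v.pos, v.alt))
    consequences.sort(key=lambda r: (r.variant_key, r.gene_id,
                                     r.transcript_id or ""))
    gerp = dict(sorted(gerp.items()))

    paths = {
        "vcf": outdir / "variants.vcf",
        "consequences": outdir / "consequences.tsv",
        "gerp": outdir / "gerp.tsv",
        "genes_gff3": outdir / "genes.gff3",
        "genes_bed": outdir / "genes.bed",
        "qtls_bed": outdir / "qtls.bed",
        "mirnas_gff3": outdir / "mirnas.gff3",
        "mirnas_fasta": outdir / "mirnas.fa",
        "flags": outdir / "flags.tsv",
        "truth": outdir / "truth.json",
        "config": outdir / "config.yaml",
    }
    write_vcf(variants, paths["vcf"], samples=list(SAMPLES),
              contigs=[(c, config.chrom_length_bp) for c in chroms])
    write_consequence_table(consequences, paths["consequences"])
    write_gerp_table(gerp, paths["gerp"])
    write_gene_models(genes, paths["genes_gff3"])
    write_intervals([Interval(g.gene_id, g.chrom, g.start, g.end)
                     for g in genes], paths["genes_bed"])
    write_intervals(qtls, paths["qtls_bed"])
    write_mirnas(mirnas, paths["mirnas_gff3"], paths["mirnas_fasta"])
    write_flag_table(flags, paths["flags"])
    truth.to_json(paths["truth"])
    cfg_dict = dataclasses.asdict(config)
    paths["config"].write_text(yaml.safe_dump(cfg_dict, sort_keys=True))

    return SyntheticBundle(config=config, truth=truth, paths=paths,
                           variants=variants, consequences=consequences,
                           gerp=gerp, genes=genes, qtls=qtls, mirnas=mirnas,
                           flags=flags)
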