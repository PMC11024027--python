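"""Domain types and format I/O shared by every pipeline stage.

Internal coordinates are uniformly 1-based inclusive (VCF/Ensembl convention);
BED input is converted at the boundary.  Multi-allelic VCF records are split
into one :class:`Variant` per alternate allele at read time, so a variant is
identified everywhere by the key ``chrom_pos_ref/alt`` (e.g. ``12_13433013_T/A``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam
from Bio import SeqIO

logger = logging.getLogger("linevar")

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

#: Site-level QC annotations consumed by the hard filters.
METRIC_KEYS = ("QD", "MQ", "SOR", "FS", "MQRankSum", "ReadPosRankSum", "DP")

#: Ensembl regulatory-build feature classes eligible for the regulatory clause.
REGULATORY_CLASSES = frozenset({
    "promoter",
    "promoter_flanking_region",
    "enhancer",
    "CTCF_binding_site",
    "TF_binding_site",
    "open_chromatin_region",
})

#: Recognised SIFT calls; anything else is treated as absent.
SIFT_VALUES = frozenset({
    "deleterious",
    "deleterious_low_confidence",
    "tolerated",
    "tolerated_low_confidence",
})

#: Gene-level annotation flags carried by the flag table.
FLAG_VALUES = frozenset({
    "IMPC_adipose",
    "GO_keyword",
    "MP_keyword",
    "disease_keyword",
    "expression_diff",
    "high_snp_count",
})

_DNA = {"A", "C", "G", "T"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class Zygosity(Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    MISSING = "MISSING"


def variant_key(chrom: str, pos: int, ref: str, alt: str) -> str:
    """Canonical variant identifier, ``chrom_pos_ref/alt``."""
    return f"{chrom}_{pos}_{ref}/{alt}"


def parse_variant_key(key: str) -> tuple[str, int, str, str]:
    chrom, pos, alleles = key.rsplit("_", 2)
    ref, alt = alleles.split("/")
    return chrom, int(pos), ref, alt


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypeCall:
    """A per-sample call for one (site, alt) after multi-allelic splitting.

    ``allele`` is the called allele string and is defined only for homozygous
    calls; heterozygous and missing calls carry ``None``.
    """

    zygosity: Zygosity
    allele: Optional[str] = None

    def __post_init__(self) -> None:
        homozygous = self.zygosity in (Zygosity.HOM_REF, Zygosity.HOM_ALT)
        if homozygous != (self.allele is not None):
            raise ValueError(
                f"allele must be set iff homozygous, got {self.zygosity} "
                f"with allele={self.allele!r}"
            )


@dataclass
class Variant:
    """One called site with a single alternate allele.

    ``metrics`` distinguishes absence from zero: rank-sum annotations are
    undefined at sites without heterozygous reads, and treating absence as 0
    would silently pass or fail a filter.
    """

    chrom: str
    pos: int
    id: Optional[str]
    ref: str
    alt: str
    qual: Optional[float]
    metrics: dict[str, Optional[float]] = field(default_factory=dict)
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not set(self.ref) <= (_DNA | {"N"}) or not set(self.alt) <= _DNA:
            raise ValueError(f"non-ACGT allele at {self.chrom}:{self.pos}: "
                             f"{self.ref}>{self.alt}")

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "INDEL"

    @property
    def key(self) -> str:
        return variant_key(self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ConsequenceRecord:
    """One variant-by-feature annotation row (VEP-style)."""

    variant_key: str
    gene_id: str
    gene_symbol: str
    transcript_id: Optional[str]
    consequence_term: str
    biotype: str
    sift: Optional[str] = None
    regulatory_class: Optional[str] = None
    protein_position: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sift is not None and self.sift not in SIFT_VALUES:
            raise ValueError(f"unknown SIFT call {self.sift!r}")
        if (self.regulatory_class is not None
                and self.regulatory_class not in REGULATORY_CLASSES):
            raise ValueError(
                f"unknown regulatory class {self.regulatory_class!r}")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_symbol: str
    biotype: str
    chrom: str
    start: int
    end: int
    strand: str
    #: (transcript_id, protein_length_aa or None)
    transcripts: tuple[tuple[str, Optional[int]], ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Interval:
    """A named 1-based inclusive genomic interval (e.g. a Fob QTL)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.name}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class MiRNARecord:
    """A mature miRNA with genomic coordinates and sequence.

    The seed region is mature positions 2-8 inclusive (a 7-mer), the principal
    determinant of target recognition.
    """

    gene_id: str
    mature_name: str
    chrom: str
    mature_start: int
    mature_end: int
    strand: str
    mature_sequence: str
    seed_offsets: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        span = self.mature_end - self.mature_start + 1
        if span != len(self.mature_sequence):
            raise ValueError(
                f"{self.mature_name}: span {span} != sequence length "
                f"{len(self.mature_sequence)}")
        lo, hi = self.seed_offsets
        if hi - lo + 1 != 7:
            raise ValueError(f"{self.mature_name}: seed must be a 7-mer")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.mature_name}: bad strand {self.strand!r}")

    @property
    def seed(self) -> str:
        lo, hi = self.seed_offsets
        return self.mature_sequence[lo - 1:hi]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _zygosity_for_alt(gt: tuple, alt_index: int) -> Zygosity:
    """Classify a GT tuple relative to one split alternate allele.

    A genotype composed of two other alternate alleles (e.g. 1/2 seen from the
    split record of allele 1) is classified HET: the sample is neither
    homozygous for this alt nor homozygous reference, and the downstream
    analysis keeps homozygous calls only.
    """
    if gt is None or any(a is None for a in gt):
        return Zygosity.MISSING
    if all(a == alt_index for a in gt):
        return Zygosity.HOM_ALT
    if all(a == 0 for a in gt):
        return Zygosity.HOM_REF
    return Zygosity.HET


def _round_opt(x, ndigits: int = 4) -> Optional[float]:
    return None if x is None else round(float(x), ndigits)


def read_vcf(path: str | Path, sample_names: Optional[Sequence[str]] = None
             ) -> list[Variant]:
    """Read a VCF into split per-alt :class:`Variant` records.

    Metrics absent from INFO are recorded as ``None``, never 0.  Floats are
    rounded to 4 decimals to erase float32 storage noise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with pysam.VariantFile(str(path)) as vcf:
        header_samples = list(vcf.header.samples)
        if sample_names is None:
            sample_names = header_samples
        else:
            for s in sample_names:
                if s not in header_samples:
                    raise KeyError(
                        f"sample {s!r} not present in VCF header of {path}")
        variants: list[Variant] = []
        for line_no, rec in enumerate(vcf, start=1):
            try:
                variants.extend(_split_record(rec, sample_names))
            except Exception as exc:  # pragma: no cover - defensive
                raise ValueError(
                    f"unparseable VCF record #{line_no} in {path}: {exc}"
                ) from exc
    return variants


def _split_record(rec, sample_names: Sequence[str]) -> list[Variant]:
    out = []
    alts = rec.alts or ()
    info = dict(rec.info)
    metrics: dict[str, Optional[float]] = {}
    for k in METRIC_KEYS:
        v = info.get(k)
        if isinstance(v, tuple):
            v = v[0]
        metrics[k] = _round_opt(v)
    for ai, alt in enumerate(alts, start=1):
        genotypes = {}
        for s in sample_names:
            gt = rec.samples[s].get("GT")
            zyg = _zygosity_for_alt(gt, ai)
            allele = None
            if zyg is Zygosity.HOM_ALT:
                allele = alt
            elif zyg is Zygosity.HOM_REF:
                allele = rec.ref
            genotypes[s] = GenotypeCall(zyg, allele)
        out.append(Variant(
            chrom=rec.chrom, pos=rec.pos,
            id=rec.id, ref=rec.ref, alt=alt,
            qual=_round_opt(rec.qual),
            metrics=metrics.copy(), genotypes=genotypes,
        ))
    return out


_VCF_INFO_DEFS = [
    ("QD", "Float", "Variant confidence standardised by depth"),
    ("MQ", "Float", "RMS mapping quality"),
    ("SOR", "Float", "Strand odds ratio"),
    ("FS", "Float", "Fisher strand bias (phred)"),
    ("MQRankSum", "Float", "Mapping-quality rank-sum (ref vs alt reads)"),
    ("ReadPosRankSum", "Float", "Read-position rank-sum"),
    ("DP", "Integer", "Combined depth"),
]

_GT_STRING = {
    Zygosity.HOM_REF: "0/0",
    Zygosity.HET: "0/1",
    Zygosity.HOM_ALT: "1/1",
    Zygosity.MISSING: "./.",
}


def _fmt(x: float) -> str:
    return f"{x:g}"


def write_vcf(variants: Iterable[Variant], path: str | Path,
              samples: Sequence[str],
              contigs: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Write split variants as bi-allelic VCF 4.2 records (one line per alt)."""
    variants = list(variants)
    if contigs is None:
        seen: dict[str, int] = {}
        for v in variants:
            seen[v.chrom] = max(seen.get(v.chrom, 0), v.pos)
        contigs = [(c, p + 1000) for c, p in seen.items()]
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    for key, typ, desc in _VCF_INFO_DEFS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples))
    for v in variants:
        info_parts = []
        for k in METRIC_KEYS:
            val = v.metrics.get(k)
            if val is None:
                continue
            info_parts.append(f"{k}={int(val)}" if k == "DP" else f"{k}={_fmt(val)}")
        info = ";".join(info_parts) or "."
        gts = "\t".join(_GT_STRING[v.genotypes[s].zygosity] for s in samples)
        qual = "." if v.qual is None else _fmt(v.qual)
        lines.append(f"{v.chrom}\t{v.pos}\t{v.id or '.'}\t{v.ref}\t{v.alt}\t"
                     f"{qual}\t.\t{info}\tGT\t{gts}")
    Path(path).write_text("\n".join(lines) + "\n")


def vcf_contigs(path: str | Path) -> list[str]:
    """Chromosome names declared in the VCF header, in header order."""
    with pysam.VariantFile(str(path)) as vcf:
        return list(vcf.header.contigs)


# ---------------------------------------------------------------------------
# Consequence table (TSV)
# ---------------------------------------------------------------------------

_CONSEQ_COLUMNS = ["variant_key", "gene_id", "gene_symbol", "transcript_id",
                   "consequence", "biotype", "sift", "regulatory_class",
                   "protein_position"]


def read_consequence_table(path: str | Path) -> list[ConsequenceRecord]:
    """Read a VEP-style TSV; unknown SIFT strings become absent (warned)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CONSEQ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"consequence table {path} lacks columns: {missing}")
    records = []
    for row in df.itertuples(index=False):
        sift = row.sift or None
        if sift is not None and sift not in SIFT_VALUES:
            logger.warning("unknown SIFT call %r treated as absent", sift)
            sift = None
        records.append(ConsequenceRecord(
            variant_key=row.variant_key,
            gene_id=row.gene_id,
            gene_symbol=row.gene_symbol,
            transcript_id=row.transcript_id or None,
            consequence_term=row.consequence,
            biotype=row.biotype,
            sift=sift,
            regulatory_class=row.regulatory_class or None,
            protein_position=int(row.protein_position)
            if row.protein_position else None,
        ))
    return records


def write_consequence_table(records: Iterable[ConsequenceRecord],
                            path: str | Path) -> None:
    import pandas as pd

    rows = [{
        "variant_key": r.variant_key,
        "gene_id": r.gene_id,
        "gene_symbol": r.gene_symbol,
        "transcript_id": r.transcript_id or "",
        "consequence": r.consequence_term,
        "biotype": r.biotype,
        "sift": r.sift or "",
        "regulatory_class": r.regulatory_class or "",
        "protein_position": "" if r.protein_position is None
        else str(r.protein_position),
    } for r in records]
    pd.DataFrame(rows, columns=_CONSEQ_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> list[Interval]:
    """Read a 3+-column BED; half-open 0-based becomes 1-based inclusive."""
    intervals = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{line_no}: fewer than 3 BED columns")
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end <= start:
            raise ValueError(f"{path}:{line_no}: BED end {end} <= start {start}")
        name = fields[3] if len(fields) > 3 else f"interval{line_no}"
        intervals.append(Interval(name=name, chrom=chrom, start=start + 1, end=end))
    return intervals


def write_intervals(intervals: Iterable[Interval], path: str | Path) -> None:
    lines = [f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.name}"
             for iv in intervals]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3)
# ---------------------------------------------------------------------------

def _gff3_attrs(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3 (``gene`` rows with ``mRNA`` children).

    A transcript's protein length is carried in its ``protein_length``
    attribute (amino acids); transcripts without one are recorded with None.
    """
    genes: dict[str, dict] = {}
    order: list[str] = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"{path}:{line_no}: expected 9 GFF3 columns")
        chrom, _, ftype, start, end, _, strand, _, raw = f
        attrs = _gff3_attrs(raw)
        if ftype == "gene":
            gid = attrs["ID"]
            genes[gid] = {
                "gene_id": gid,
                "gene_symbol": attrs.get("Name", gid),
                "biotype": attrs.get("biotype", "protein_coding"),
                "chrom": chrom, "start": int(start), "end": int(end),
                "strand": strand, "transcripts": [],
            }
            order.append(gid)
        elif ftype == "mRNA":
            parent = attrs["Parent"]
            if parent not in genes:
                raise ValueError(f"{path}:{line_no}: mRNA before its gene")
            plen = attrs.get("protein_length")
            genes[parent]["transcripts"].append(
                (attrs["ID"], int(plen) if plen else None))
    return [GeneModel(transcripts=tuple(genes[g].pop("transcripts")),
                      **genes[g]) for g in order]


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        lines.append("\t".join([
            g.chrom, "linevar", "gene", str(g.start), str(g.end), ".",
            g.strand, ".",
            f"ID={g.gene_id};Name={g.gene_symbol};biotype={g.biotype}"]))
        for tid, plen in g.transcripts:
            attrs = f"ID={tid};Parent={g.gene_id}"
            if plen is not None:
                attrs += f";protein_length={plen}"
            lines.append("\t".join([
                g.chrom, "linevar", "mRNA", str(g.start), str(g.end), ".",
                g.strand, ".", attrs]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# miRNAs (GFF3 + mature FASTA)
# ---------------------------------------------------------------------------

def read_mirnas(gff3_path: str | Path, fasta_path: str | Path
                ) -> list[MiRNARecord]:
    """Read mature miRNA coordinates (GFF3 ``miRNA`` rows) plus sequences.

    Raises if a mature sequence length disagrees with its coordinates.
    """
    seqs = {rec.id: str(rec.seq).upper().replace("T", "U")
            for rec in SeqIO.parse(str(fasta_path), "fasta")}
    records = []
    for line_no, line in enumerate(Path(gff3_path).read_text().splitlines(),
                                   start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9 or f[2] != "miRNA":
            continue
        attrs = _gff3_attrs(f[8])
        name = attrs["Name"]
        if name not in seqs:
            raise ValueError(f"{gff3_path}:{line_no}: no mature sequence for "
                             f"{name} in {fasta_path}")
        records.append(MiRNARecord(
            gene_id=attrs.get("gene_id", attrs.get("Derives_from", name)),
            mature_name=name, chrom=f[0],
            mature_start=int(f[3]), mature_end=int(f[4]), strand=f[6],
            mature_sequence=seqs[name],
        ))
    return records


def write_mirnas(mirnas: Iterable[MiRNARecord], gff3_path: str | Path,
                 fasta_path: str | Path) -> None:
    gff = ["##gff-version 3"]
    fasta = []
    for m in mirnas:
        gff.append("\t".join([
            m.chrom, "linevar", "miRNA", str(m.mature_start),
            str(m.mature_end), ".", m.strand, ".",
            f"ID={m.mature_name};Name={m.mature_name};gene_id={m.gene_id}"]))
        fasta.append(f">{m.mature_name}\n{m.mature_sequence}")
    Path(gff3_path).write_text("\n".join(gff) + "\n")
    Path(fasta_path).write_text("\n".join(fasta) + "\n")


# ---------------------------------------------------------------------------
# GERP and flag tables
# ---------------------------------------------------------------------------

def read_gerp_table(path: str | Path) -> dict[str, float]:
    """Two-column TSV ``variant_key<TAB>score`` -> mapping."""
    table = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("variant_key"):
            continue
        key, score = line.split("\t")
        table[key] = float(score)
    return table


def write_gerp_table(table: Mapping[str, float], path: str | Path) -> None:
    lines = ["variant_key\tscore"]
    lines += [f"{k}\t{_fmt(v)}" for k, v in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_flag_table(path: str | Path) -> dict[str, set[str]]:
    """TSV ``gene_id<TAB>flag1,flag2`` -> gene -> flag set."""
    table: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("gene_id"):
            continue
        gene_id, raw = (line.split("\t") + [""])[:2]
        flags = {f for f in raw.split(",") if f}
        unknown = flags - FLAG_VALUES
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)} for {gene_id}")
        table[gene_id] = flags
    return table


def write_flag_table(table: Mapping[str, set[str]], path: str | Path) -> None:
    lines = ["gene_id\tflags"]
    lines += [f"{g}\t{','.join(sorted(fl))}" for g, fl in table.items()]
    Path(path).write_text("\n".join(lines) + "\n")
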