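"""GATK-style site-level hard filters and the homozygosity requirement.

SNPs and indels use different criterion sets (indels ignore MQ, MQRankSum and
DP).  An absent metric never triggers its criterion: rank-sum annotations are
undefined at sites without heterozygous reads, and failing on absence would
discard most homozygous-alt sites.  Thresholds are configurable so the module
doubles as a general hard-filter engine; defaults are the study values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core_io import Variant, Zygosity


@dataclass(frozen=True)
class FilterThresholds:
    """Exclusion thresholds; a variant FAILS when the inequality holds.

    ``dp_min`` encodes "coverage depth above 30" strictly: a site fails at
    DP <= 30.  All other criteria fail on the printed strict inequality
    (e.g. QD == 2.0 passes because the exclusion is QD < 2.0).
    """

    snp_qd_min: float = 2.0
    snp_qual_min: float = 30.0
    snp_mq_min: float = 40.0
    snp_sor_max: float = 3.0
    snp_fs_max: float = 60.0
    snp_mqranksum_min: float = -12.5
    snp_readposranksum_min: float = -8.0
    snp_dp_min: float = 30.0

    indel_qd_min: float = 2.0
    indel_qual_min: float = 30.0
    indel_fs_max: float = 200.0
    indel_readposranksum_min: float = -20.0
    indel_sor_max: float = 10.0


DEFAULT_THRESHOLDS = FilterThresholds()


@dataclass
class FilterVerdict:
    passed: bool
    failed_criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.passed != (not self.failed_criteria):
            raise ValueError("passed must be true iff no criterion failed")


def _verdict(failed: list[str]) -> FilterVerdict:
    return FilterVerdict(passed=not failed, failed_criteria=failed)


def classify_snp(v: Variant,
                 thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                 ) -> FilterVerdict:
    """Apply the eight SNP criteria; every violated criterion is named."""
    if v.vtype != "SNP":
        raise ValueError(f"classify_snp called on {v.vtype} {v.key}")
    t = thresholds
    m = v.metrics
    failed = []
    if m.get("QD") is not None and m["QD"] < t.snp_qd_min:
        failed.append("QD")
    if v.qual is not None and v.qual < t.snp_qual_min:
        failed.append("QUAL")
    if m.get("MQ") is not None and m["MQ"] < t.snp_mq_min:
        failed.append("MQ")
    if m.get("SOR") is not None and m["SOR"] > t.snp_sor_max:
        failed.append("SOR")
    if m.get("FS") is not None and m["FS"] > t.snp_fs_max:
        failed.append("FS")
    if m.get("MQRankSum") is not None and m["MQRankSum"] < t.snp_mqranksum_min:
        failed.append("MQRankSum")
    if (m.get("ReadPosRankSum") is not None
            and m["ReadPosRankSum"] < t.snp_readposranksum_min):
        failed.append("ReadPosRankSum")
    if m.get("DP") is not None and m["DP"] <= t.snp_dp_min:
        failed.append("DP")
    return _verdict(failed)


def classify_indel(v: Variant,
                   thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                   ) -> FilterVerdict:
    """Apply the five indel criteria; MQ, MQRankSum and DP are ignored."""
    if v.vtype != "INDEL":
        raise ValueError(f"classify_indel called on {v.vtype} {v.key}")
    t = thresholds
    m = v.metrics
    failed = []
    if m.get("QD") is not None and m["QD"] < t.indel_qd_min:
        failed.append("QD")
    if v.qual is not None and v.qual < t.indel_qual_min:
        failed.append("QUAL")
    if m.get("FS") is not None and m["FS"] > t.indel_fs_max:
        failed.append("FS")
    if (m.get("ReadPosRankSum") is not None
            and m["ReadPosRankSum"] < t.indel_readposranksum_min):
        failed.append("ReadPosRankSum")
    if m.get("SOR") is not None and m["SOR"] > t.indel_sor_max:
        failed.append("SOR")
    return _verdict(failed)


def classify(v: Variant,
             thresholds: FilterThresholds = DEFAULT_THRESHOLDS
             ) -> FilterVerdict:
    """Dispatch on variant type."""
    if v.vtype == "SNP":
        return classify_snp(v, thresholds)
    return classify_indel(v, thresholds)


def homozygous_only(v: Variant, line_samples: list[str]) -> bool:
    """True iff every named sample is homozygous (HET and MISSING excluded)."""
    for s in line_samples:
        if s not in v.genotypes:
            raise KeyError(f"sample {s!r} not genotyped at {v.key}")
        if v.genotypes[s].zygosity not in (Zygosity.HOM_REF, Zygosity.HOM_ALT):
            return False
    return True


def apply_filters(variants: list[Variant], line_samples: list[str],
                  thresholds: FilterThresholds = DEFAULT_THRESHOLDS
                  ) -> tuple[list[Variant], list[tuple[str, FilterVerdict, bool]]]:
    """Filter a variant list; returns (passing variants, per-variant report).

    A variant passes when its hard-filter verdict passes AND all line samples
    are homozygous.  The report lists (variant_key, verdict, homozygous).
    """
    passing = []
    report = []
    for v in variants:
        verdict = classify(v, thresholds)
        hom = homozygous_only(v, line_samples)
        report.append((v.key, verdict, hom))
        if verdict.passed and hom:
            passing.append(v)
    return passing, report
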