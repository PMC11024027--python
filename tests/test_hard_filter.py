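"""Hard-filter verdicts against an independent per-predicate oracle."""

import numpy as np
import pytest

from linevar.core_io import Variant, Zygosity
from linevar.hard_filter import (classify, classify_indel, classify_snp,
                                 homozygous_only)
from conftest import gt, make_variant

# Independent re-statement of each exclusion predicate (metric absent ->
# criterion cannot fire).  Kept deliberately separate from the implementation.
SNP_ORACLE = [
    ("QD", lambda q, m: m["QD"] is not None and m["QD"] < 2.0),
    ("QUAL", lambda q, m: q is not None and q < 30.0),
    ("MQ", lambda q, m: m["MQ"] is not None and m["MQ"] < 40.0),
    ("SOR", lambda q, m: m["SOR"] is not None and m["SOR"] > 3.0),
    ("FS", lambda q, m: m["FS"] is not None and m["FS"] > 60.0),
    ("MQRankSum", lambda q, m: m["MQRankSum"] is not None
     and m["MQRankSum"] < -12.5),
    ("ReadPosRankSum", lambda q, m: m["ReadPosRankSum"] is not None
     and m["ReadPosRankSum"] < -8.0),
    ("DP", lambda q, m: m["DP"] is not None and m["DP"] <= 30.0),
]
INDEL_ORACLE = [
    ("QD", lambda q, m: m["QD"] is not None and m["QD"] < 2.0),
    ("QUAL", lambda q, m: q is not None and q < 30.0),
    ("FS", lambda q, m: m["FS"] is not None and m["FS"] > 200.0),
    ("ReadPosRankSum", lambda q, m: m["ReadPosRankSum"] is not None
     and m["ReadPosRankSum"] < -20.0),
    ("SOR", lambda q, m: m["SOR"] is not None and m["SOR"] > 10.0),
]

_RANGES = {"QD": (0, 40), "MQ": (20, 70), "SOR": (0, 12), "FS": (0, 250),
           "MQRankSum": (-25, 5), "ReadPosRankSum": (-25, 5), "DP": (1, 120)}


def random_metric_vector(rng):
    qual = None if rng.random() < 0.1 else float(rng.uniform(0, 200))
    metrics = {}
    for k, (lo, hi) in _RANGES.items():
        metrics[k] = None if rng.random() < 0.15 else round(
            float(rng.uniform(lo, hi)), 2)
    return qual, metrics


def test_qd_failure_named():
    v = make_variant(metrics={"QD": 1.9, "MQ": 60.0, "SOR": 1.0, "FS": 5.0,
                              "MQRankSum": 0.0, "ReadPosRankSum": 0.0,
                              "DP": 40.0}, qual=50.0)
    verdict = classify_snp(v)
    assert not verdict.passed and verdict.failed_criteria == ["QD"]


def test_dp_boundary_is_strictly_above_30():
    passing = make_variant(metrics={"QD": 5.0, "MQ": 60.0, "SOR": 1.0,
                                    "FS": 5.0, "MQRankSum": 0.0,
                                    "ReadPosRankSum": 0.0, "DP": 31.0})
    assert classify_snp(passing).passed
    at_30 = make_variant(metrics={**passing.metrics, "DP": 30.0})
    assert classify_snp(at_30).failed_criteria == ["DP"]


def test_printed_inequality_boundaries_pass():
    # equality never fails when the exclusion is a strict inequality
    v = make_variant(metrics={"QD": 2.0, "MQ": 40.0, "SOR": 3.0, "FS": 60.0,
                              "MQRankSum": -12.5, "ReadPosRankSum": -8.0,
                              "DP": 31.0}, qual=30.0)
    assert classify_snp(v).passed


def test_absent_rank_sum_passes():
    v = make_variant(metrics={"QD": 5.0, "MQ": 60.0, "SOR": 1.0, "FS": 5.0,
                              "MQRankSum": None, "ReadPosRankSum": None,
                              "DP": 40.0})
    assert classify_snp(v).passed


def test_indel_fs_failure_and_snp_only_criteria_ignored():
    v = make_variant(ref="AT", alt="A",
                     metrics={"QD": 3.0, "MQ": 10.0, "SOR": 2.0, "FS": 250.0,
                              "MQRankSum": -20.0, "ReadPosRankSum": 0.0,
                              "DP": 5.0}, qual=40.0)
    verdict = classify_indel(v)
    assert verdict.failed_criteria == ["FS"]
    ok = make_variant(ref="AT", alt="A",
                      metrics={"QD": 3.0, "MQ": 10.0, "SOR": 2.0, "FS": 10.0,
                               "MQRankSum": -20.0, "ReadPosRankSum": 0.0,
                               "DP": 5.0}, qual=40.0)
    assert classify_indel(ok).passed  # MQ/MQRankSum/DP are SNP-only


def test_vtype_contract_enforced():
    snp = make_variant()
    indel = make_variant(ref="AT", alt="A")
    with pytest.raises(ValueError):
        classify_snp(indel)
    with pytest.raises(ValueError):
        classify_indel(snp)


@pytest.mark.parametrize("vtype,oracle", [("SNP", SNP_ORACLE),
                                          ("INDEL", INDEL_ORACLE)])
def test_verdicts_match_predicate_oracle_on_random_vectors(vtype, oracle):
    rng = np.random.default_rng(42)
    for _ in range(2500):
        qual, metrics = random_metric_vector(rng)
        ref, alt = ("A", "G") if vtype == "SNP" else ("AT", "A")
        v = make_variant(ref=ref, alt=alt, metrics=metrics, qual=qual)
        verdict = classify(v)
        expected = [name for name, pred in oracle if pred(qual, metrics)]
        assert verdict.failed_criteria == expected
        assert verdict.passed == (not expected)


def test_improving_one_metric_never_breaks_a_pass():
    # monotone: nudging any metric toward its passing side preserves a pass
    rng = np.random.default_rng(7)
    better = {"QD": +1, "MQ": +1, "SOR": -0.5, "FS": -5,
              "MQRankSum": +1, "ReadPosRankSum": +1, "DP": +5}
    for _ in range(500):
        qual, metrics = random_metric_vector(rng)
        v = make_variant(metrics=metrics, qual=qual)
        if not classify_snp(v).passed:
            continue
        for k, delta in better.items():
            if metrics[k] is None:
                continue
            improved = dict(metrics, **{k: metrics[k] + delta})
            assert classify_snp(make_variant(metrics=improved,
                                             qual=qual)).passed


def test_homozygous_only_enumerates_all_zygosity_pairs():
    zygs = list(Zygosity)
    for fat in zygs:
        for lean in zygs:
            v = make_variant(fat=fat, lean=lean)
            expected = all(z in (Zygosity.HOM_REF, Zygosity.HOM_ALT)
                           for z in (fat, lean))
            assert homozygous_only(v, ["FatLine", "LeanLine"]) == expected


def test_homozygous_only_unknown_sample_fatal():
    with pytest.raises(KeyError, match="Nope"):
        homozygous_only(make_variant(), ["Nope"])
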