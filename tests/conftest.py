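import pytest

from linevar.core_io import GenotypeCall, Variant, Zygosity
from linevar.synthetic_data import SynthConfig, generate_bundle


def gt(zyg: Zygosity, ref: str, alt: str) -> GenotypeCall:
    allele = {Zygosity.HOM_REF: ref, Zygosity.HOM_ALT: alt}.get(zyg)
    return GenotypeCall(zyg, allele)


def make_variant(chrom="1", pos=100, ref="A", alt="G", vid=None, qual=100.0,
                 metrics=None, fat=Zygosity.HOM_ALT, lean=Zygosity.HOM_REF,
                 nzo=Zygosity.HOM_REF, aj=Zygosity.HOM_REF) -> Variant:
    metrics = metrics if metrics is not None else {
        "QD": 20.0, "MQ": 55.0, "SOR": 1.0, "FS": 2.0,
        "MQRankSum": 0.0, "ReadPosRankSum": 0.0, "DP": 60.0}
    return Variant(
        chrom=chrom, pos=pos, id=vid, ref=ref, alt=alt, qual=qual,
        metrics=metrics,
        genotypes={"FatLine": gt(fat, ref, alt), "LeanLine": gt(lean, ref, alt),
                   "NZO": gt(nzo, ref, alt), "A_J": gt(aj, ref, alt)})


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """One shared synthetic bundle (seed 1, default study conditions)."""
    outdir = tmp_path_factory.mktemp("bundle")
    return generate_bundle(SynthConfig(seed=1), outdir)
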