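"""Format round-trips and boundary-convention conversions."""

import pytest

from linevar.core_io import (ConsequenceRecord, GeneModel, GenotypeCall,
                             Interval, MiRNARecord, Variant, Zygosity,
                             read_consequence_table, read_flag_table,
                             read_gene_models, read_gerp_table,
                             read_intervals, read_mirnas, read_vcf,
                             variant_key, parse_variant_key,
                             write_consequence_table, write_flag_table,
                             write_gene_models, write_gerp_table,
                             write_intervals, write_mirnas, write_vcf)

MINI_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1,length=10000>
##contig=<ID=2,length=10000>
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=DP,Number=1,Type=Integer,Description="x">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tFatLine\tLeanLine
"""


def write_text_vcf(tmp_path, body: str):
    p = tmp_path / "mini.vcf"
    p.write_text(MINI_HEADER + body)
    return p


def test_empty_vcf_yields_empty_list(tmp_path):
    assert read_vcf(write_text_vcf(tmp_path, "")) == []


def test_hom_alt_genotype_mapping(tmp_path):
    p = write_text_vcf(tmp_path, "1\t50\trs7\tA\tG\t99\t.\tQD=12.5;DP=40\tGT\t0/0\t1/1\n")
    (v,) = read_vcf(p)
    assert v.genotypes["LeanLine"].zygosity is Zygosity.HOM_ALT
    assert v.genotypes["LeanLine"].allele == "G"
    assert v.genotypes["FatLine"].allele == "A"
    assert v.metrics["QD"] == 12.5 and v.metrics["DP"] == 40
    assert v.metrics["MQ"] is None  # absent, not zero
    assert v.key == "1_50_A/G"


def test_triallelic_site_splits_and_round_trips(tmp_path):
    body = (
        "1\t100\t.\tA\tG,T\t99\t.\tQD=10;DP=50\tGT\t1/1\t2/2\n"
        "1\t200\trs1\tC\tT\t99\t.\tDP=35\tGT\t0/0\t1/1\n"
        "2\t300\trs2\tG\tGA\t99\t.\tDP=35\tGT\t1/1\t0/0\n")
    variants = read_vcf(write_text_vcf(tmp_path, body))
    assert len(variants) == 4
    g_split, t_split = variants[0], variants[1]
    assert (g_split.chrom, g_split.pos, g_split.ref) == ("1", 100, "A")
    assert {g_split.alt, t_split.alt} == {"G", "T"}
    # sample hom for the *other* alt is neither hom-ref nor hom-alt here
    assert g_split.genotypes["FatLine"].zygosity is Zygosity.HOM_ALT
    assert g_split.genotypes["LeanLine"].zygosity is Zygosity.HET
    assert variants[3].vtype == "INDEL"
    out = tmp_path / "rt.vcf"
    write_vcf(variants, out, samples=["FatLine", "LeanLine"])
    assert read_vcf(out) == variants


def test_missing_sample_is_fatal(tmp_path):
    p = write_text_vcf(tmp_path, "")
    with pytest.raises(KeyError, match="NZO"):
        read_vcf(p, sample_names=["FatLine", "NZO"])


def test_variant_key_round_trip():
    key = variant_key("12", 13433013, "T", "A")
    assert key == "12_13433013_T/A"
    assert parse_variant_key(key) == ("12", 13433013, "T", "A")


def test_variant_invariants():
    with pytest.raises(ValueError):
        Variant(chrom="1", pos=0, id=None, ref="A", alt="G", qual=1.0)
    with pytest.raises(ValueError):
        Variant(chrom="1", pos=1, id=None, ref="A", alt="X", qual=1.0)
    with pytest.raises(ValueError):
        GenotypeCall(Zygosity.HET, allele="A")  # allele only when homozygous


def test_consequence_table_round_trip(tmp_path):
    records = [ConsequenceRecord(
        variant_key=f"1_{i}_A/G", gene_id=f"G{i % 7}", gene_symbol=f"g{i % 7}",
        transcript_id=f"T{i}" if i % 2 else None,
        consequence_term="missense_variant" if i % 3 else "intron_variant",
        biotype="protein_coding",
        sift="deleterious_low_confidence" if i % 3 == 1 else None,
        regulatory_class=None,
        protein_position=i if i % 3 else None) for i in range(1, 101)]
    p = tmp_path / "cons.tsv"
    write_consequence_table(records, p)
    assert read_consequence_table(p) == records


def test_sift_low_confidence_parsed_and_unknown_warned(tmp_path, caplog):
    p = tmp_path / "cons.tsv"
    p.write_text(
        "variant_key\tgene_id\tgene_symbol\ttranscript_id\tconsequence\t"
        "biotype\tsift\tregulatory_class\tprotein_position\n"
        "1_5_A/G\tG1\tg1\tT1\tmissense_variant\tprotein_coding\t"
        "deleterious_low_confidence\t\t10\n"
        "1_6_A/G\tG1\tg1\tT1\tmissense_variant\tprotein_coding\tbogus\t\t11\n")
    recs = read_consequence_table(p)
    assert recs[0].sift == "deleterious_low_confidence"
    assert recs[1].sift is None


def test_consequence_table_missing_column_fatal(tmp_path):
    p = tmp_path / "bad.tsv"
    p.write_text("variant_key\tgene_id\n1_5_A/G\tG1\n")
    with pytest.raises(ValueError, match="lacks columns"):
        read_consequence_table(p)


@pytest.mark.parametrize("bed_line,expected", [
    ("chr2\t0\t10\tFob1", Interval("Fob1", "chr2", 1, 10)),
    ("chr15\t999\t1000\tX", Interval("X", "chr15", 1000, 1000)),
])
def test_bed_coordinate_conversion(tmp_path, bed_line, expected):
    p = tmp_path / "a.bed"
    p.write_text(bed_line + "\n")
    assert read_intervals(p) == [expected]


def test_bed_round_trip_is_byte_identity(tmp_path):
    content = ("chr1\t0\t5000\tFob1\nchr2\t100\t900\tFob2\n"
               "chr3\t10\t20\tFob3\nchrX\t0\t1\tFob4\n")
    p = tmp_path / "qtl.bed"
    p.write_text(content)
    intervals = read_intervals(p)
    assert [iv.name for iv in intervals] == ["Fob1", "Fob2", "Fob3", "Fob4"]
    out = tmp_path / "rt.bed"
    write_intervals(intervals, out)
    assert out.read_text() == content


def test_bed_invalid_interval_names_line(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("chr1\t0\t10\tok\nchr1\t10\t10\tempty\n")
    with pytest.raises(ValueError, match=":2"):
        read_intervals(p)


def test_gene_model_gff3_round_trip(tmp_path):
    genes = [
        GeneModel("G1", "Macrod2l", "protein_coding", "2", 100, 9000, "+",
                  (("T1", 451), ("T2", None))),
        GeneModel("G2", "LncA", "lncRNA", "Y", 50, 400, "-", (("T3", None),)),
    ]
    p = tmp_path / "genes.gff3"
    write_gene_models(genes, p)
    assert read_gene_models(p) == genes


def test_mirna_gff3_fasta_round_trip_and_length_check(tmp_path):
    m = MiRNARecord("MIRG1", "syn-miR-9-3p", "3", 1000, 1021, "-",
                    "UCCAAUGAACGUACGUACGUAC")
    write_mirnas([m], tmp_path / "m.gff3", tmp_path / "m.fa")
    assert read_mirnas(tmp_path / "m.gff3", tmp_path / "m.fa") == [m]
    with pytest.raises(ValueError, match="span"):
        MiRNARecord("MIRG1", "bad", "3", 1000, 1005, "+", "UCCAAUGAACG")


def test_gerp_and_flag_table_round_trips(tmp_path):
    gerp = {"1_5_A/G": 6.52, "2_9_C/T": -1.3}
    write_gerp_table(gerp, tmp_path / "g.tsv")
    assert read_gerp_table(tmp_path / "g.tsv") == gerp
    flags = {"G1": {"IMPC_adipose", "GO_keyword"}, "G2": set()}
    write_flag_table(flags, tmp_path / "f.tsv")
    assert read_flag_table(tmp_path / "f.tsv") == flags
    (tmp_path / "bad.tsv").write_text("gene_id\tflags\nG1\tnot_a_flag\n")
    with pytest.raises(ValueError, match="unknown flags"):
        read_flag_table(tmp_path / "bad.tsv")
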