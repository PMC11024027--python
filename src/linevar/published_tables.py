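"""Published candidate-gene table and strain-allele panel, encoded as data.

This module carries the gene-level prioritization table and the four-strain
allele comparison published for the Fat/Lean divergent-selection mouse lines,
so the selection and concordance machinery can be exercised on the real
worked example.  Only gene symbols, biotypes, per-line entry counts,
regulatory classes, rs identifiers, consequence labels, and alleles were
published; genomic coordinates and per-SNP GERP scores were not, so the
coordinates and scores constructed here are synthetic placeholders chosen
only to satisfy the published facts (every score above the 6.0 threshold,
the two known QTL genes contained in their QTL intervals).
"""

from __future__ import annotations

from .core_io import ConsequenceRecord, GeneModel, Interval, variant_key
from .line_partition import LinePartition
from .strain_concordance import StrainAlleleRow

_CLASS = {
    "P": "promoter",
    "PFR": "promoter_flanking_region",
    "E": "enhancer",
    "CTCFBS": "CTCF_binding_site",
    "TFBS": "TF_binding_site",
    "OCR": "open_chromatin_region",
}

#: One tuple per gene row: (symbol, biotype, entries).  Each entry is
#: (line, kind, classes, rs_id or None); regulatory classes are the published
#: abbreviations; a single SNP annotated with two regulatory classes keeps
#: both in one entry.  ``rs_id`` is set where the published allele panel
#: names the SNP; ``shared_with`` marks the one SNP annotated to two genes.
CANDIDATE_TABLE = [
    ("4930441H08Rik", "lncRNA", [("lean", "regulatory", ["PFR"], "rs31031645")]),
    ("4930595O18Rik", "lncRNA", [("lean", "regulatory", ["PFR"], None)]),
    ("Aff3", "protein_coding", [("lean", "impact", [], "rs30511899")]),
    ("Angpt1", "protein_coding", [("lean", "regulatory", ["TFBS"], None)]),
    ("Atpsckmt", "protein_coding", [("fat", "regulatory", ["TFBS"], None)]),
    ("Cpped1", "protein_coding", [("lean", "regulatory", ["PFR"], None)]),
    ("Erc2", "protein_coding", [("fat", "regulatory", ["E"], None)]),
    ("Gfra1", "protein_coding", [("lean", "regulatory", ["E"], None)]),
    ("Gm17131", "pseudogene",
     [("fat", "regulatory", ["PFR", "CTCFBS"], None)]),
    ("Gm36633", "lncRNA", [("lean", "regulatory", ["PFR"], "rs31031645")]),
    ("Fam237b", "protein_coding", [("lean", "impact", [], "rs31007064")]),
    ("Mast4", "protein_coding", [("lean", "regulatory", ["PFR"], None),
                                 ("fat", "regulatory", ["PFR"], None)]),
    ("Or56b2j", "polymorphic_pseudogene", [("fat", "impact", [], None)]),
    ("Pced1a", "protein_coding", [("fat", "impact", [], "rs33645896")]),
    ("Prr5l", "protein_coding",
     [("lean", "regulatory", ["PFR", "OCR"], None)]),
    ("Serpine2", "protein_coding", [("lean", "regulatory", ["P"], None)]),
    ("Tecrl", "protein_coding", [("fat", "impact", [], "rs31632835")]),
    ("Tmem132d", "protein_coding",
     [("fat", "regulatory", ["PFR", "CTCFBS"], None)]),
    ("Trim24", "protein_coding", [("lean", "impact", [], None)]),
    ("Zfp536", "protein_coding",
     [("lean", "regulatory", ["PFR"], "rs46750862")]),
]

#: Genes published as lying within the body-fat (Fob) QTLs.
FOB_QTL_GENES = ("Pced1a", "Prr5l")

#: The four-strain allele panel: rs id -> (Fat line, NZO/HlLtJ, Lean line,
#: A/J, consequence label).  Every published row follows the concordant
#: obese-with-obese / lean-with-lean pattern.
ALLELE_PANEL = {
    "rs33645896": ("A", "A", "G", "G", "missense variant"),       # Pced1a
    "rs31632835": ("C", "C", "A", "A", "missense variant"),       # Tecrl
    "rs30511899": ("T", "T", "G", "G", "missense variant"),       # Aff3
    "rs31007064": ("T", "T", "C", "C", "missense variant"),       # Fam237b
    "rs46750862": ("G", "G", "A", "A", "promoter flanking region"),  # Zfp536
    "rs31031645": ("A", "A", "G", "G", "promoter flanking region"),
    # rs31031645 is annotated to both 4930441H08Rik and Gm36633
}

_PLACEHOLDER_GERP = 6.5  # published only as "above 6"


def published_candidate_inputs() -> tuple[LinePartition, dict[str, float],
                                          list[ConsequenceRecord],
                                          list[GeneModel], list[Interval]]:
    """Reconstruct selection inputs from the published table.

    Returns (partition, gerp, consequences, genes, qtls) such that running
    the candidate-selection rule reproduces the published table bookkeeping.
    Variant keys reuse published alleles where the panel names them and
    synthetic placeholder alleles elsewhere.
    """
    partition = LinePartition()
    gerp: dict[str, float] = {}
    consequences: list[ConsequenceRecord] = []
    genes: list[GeneModel] = []
    shared_keys: dict[str, str] = {}  # rs id -> variant key already built

    for i, (symbol, biotype, entries) in enumerate(CANDIDATE_TABLE):
        chrom = str(i + 1)
        gene = GeneModel(gene_id=symbol, gene_symbol=symbol, biotype=biotype,
                         chrom=chrom, start=10_000, end=20_000, strand="+",
                         transcripts=((f"{symbol}-201", 500),))
        genes.append(gene)
        for j, (line, kind, classes, rs_id) in enumerate(entries):
            if rs_id in shared_keys:
                key = shared_keys[rs_id]
            else:
                if rs_id in ALLELE_PANEL:
                    fat, _, lean, _, _ = ALLELE_PANEL[rs_id]
                    alt = fat if line == "fat" else lean
                    ref = lean if line == "fat" else fat
                else:
                    ref, alt = "A", "G"
                key = variant_key(chrom, 15_000 + j, ref, alt)
                if rs_id:
                    shared_keys[rs_id] = key
                (partition.fat_private if line == "fat"
                 else partition.lean_private).add(key)
                gerp[key] = _PLACEHOLDER_GERP
            if kind == "regulatory":
                for abbrev in classes:
                    consequences.append(ConsequenceRecord(
                        variant_key=key, gene_id=symbol, gene_symbol=symbol,
                        transcript_id=None,
                        consequence_term="regulatory_region_variant",
                        biotype=biotype, regulatory_class=_CLASS[abbrev]))
            else:
                consequences.append(ConsequenceRecord(
                    variant_key=key, gene_id=symbol, gene_symbol=symbol,
                    transcript_id=f"{symbol}-201",
                    consequence_term="missense_variant", biotype=biotype,
                    sift="deleterious", protein_position=100))
    qtls = [Interval(name=f"Fob{k + 1}",
                     chrom=next(g.chrom for g in genes
                                if g.gene_symbol == symbol),
                     start=5_000, end=25_000)
            for k, symbol in enumerate(FOB_QTL_GENES)]
    partition.validate()
    return partition, gerp, consequences, genes, qtls


def published_strain_panel() -> dict[str, StrainAlleleRow]:
    """The four-strain allele rows keyed by variant key (as built above)."""
    partition, _, consequences, _, _ = published_candidate_inputs()
    key_by_rs: dict[str, str] = {}
    for symbol, biotype, entries in CANDIDATE_TABLE:
        for line, kind, classes, rs_id in entries:
            if rs_id:
                for r in consequences:
                    if r.gene_id == symbol:
                        key_by_rs.setdefault(rs_id, r.variant_key)
    panel = {}
    for rs_id, (fat, nzo, lean, aj, label) in ALLELE_PANEL.items():
        key = key_by_rs[rs_id]
        panel[key] = StrainAlleleRow(
            variant_key=key,
            alleles={"FatLine": fat, "NZO": nzo, "LeanLine": lean, "A_J": aj},
            consequence_label=label)
    return panel
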