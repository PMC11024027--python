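# Methods

## Model and procedure

`linevar` implements a deterministic rule-based prioritization cascade, not
a statistical model. Its object of study is a pair of inbred mouse lines
divergently selected for body-fat percentage from one base population, so
that after ~70 generations each line is essentially homozygous genome-wide
and fixed differences between the lines are candidate carriers of the
selected phenotype. The assumptions this encodes:

* **Joint calling.** The input VCF is joint-called over all four samples
  (Fat line, Lean line, and the two reference strains). Only then is a
  missing call distinguishable from homozygous-reference; single-line VCFs
  are rejected because absence-of-call is otherwise undecidable.
* **Homozygosity.** Residual heterozygous calls in inbred lines are treated
  as noise (or segregating residual variation) and excluded, never
  partitioned.
* **Variant identity.** A variant is a split (chrom, pos, ref, alt) tuple,
  written `chrom_pos_ref/alt`. "Shared" requires the identical alt allele;
  the same site fixed for different alts in the two lines yields two
  private variants. Multi-allelic records are split at read time; a sample
  homozygous for a different alt of the same site is classified HET for the
  split under consideration and therefore excluded by the homozygosity
  rule, which is the behaviour wanted for composite heterozygotes.

## Stage-by-stage choices

**Hard filters.** Thresholds live in a config dataclass so the module is a
general hard-filter engine; defaults are the study values listed in the
README. Two readings were fixed once: "coverage depth above 30" is strict
(DP == 30 fails), while every other criterion follows its printed exclusion
inequality exactly (QD == 2.0 passes because the exclusion is QD < 2.0).
Absent metrics never trigger their criterion: rank-sum annotations are
undefined without heterozygous supporting reads, and failing on absence
would discard most hom-alt sites. DP is read per-site (INFO/DP), not
per-sample.

**Partition.** Indels flow through the partition (per-line indel totals are
reported) but are excluded from all SNP-only downstream stages. The
per-chromosome summary also reports per-line totals (private + shared),
since published line totals include shared variants.

**Impact and DMV.** Impact classes are exact membership in the MODERATE
(inframe insertion/deletion, missense, protein-altering) and HIGH (splice
acceptor/donor, stop gained/lost, start lost, frameshift, transcript
amplification, feature elongation/truncation) term sets after normalizing
prose spellings to SO snake_case; unknown terms are preserved and treated
as OTHER rather than rejected, since the annotation release is not pinned.
Per-variant summaries use the most severe class over transcripts (VEP
"pick" convention); per-transcript analyses (missense spacing) use
per-transcript records. Deleterious-missense calls deduplicate per variant.

**Densities.** The gene length denominator is the genomic span
(end − start + 1), not summed exon length, because intronic SNPs are
counted within genes. Mean missense spacing is protein length divided by
missense count — the reciprocal of density, matching an "average density at
intervals of fewer than 25 aa" reading — with the gap-based alternative
(mean distance between sorted protein positions) behind a switch, default
off. Flag thresholds: count ≥ 3000, density ≥ 4 per 100 bp, spacing
strictly < 25 aa.

**QTL membership.** Genes use full-span containment ("within the QTL");
variants use point containment. Any-overlap is computed as a secondary
column, never for flags.

**Seed overlap.** The seed is mature positions 2–8 (a 7-mer). A genomic SNP
maps to mature index `pos − start + 1` on '+' and `end − pos + 1` on '−',
with alleles complemented on '−'. The mature sequence is checked against
the VCF reference base at the mapped index and any disagreement is fatal —
it means the miRNA annotation and the call set disagree about the genome.

**Selection.** The candidate rule is the conjunction of three clauses:
line-specific, GERP strictly > 6 (consistent with the "above 2 / above 4 /
above 6" tier phrasing), and regulatory-or-MODERATE/HIGH. The regulatory
clause is satisfied by a regulatory-feature annotation regardless of the
transcript consequence; the gene link comes from the annotation row's gene
assignment, so one SNP annotated to two genes triggers both. Aggregation is
per gene (the published table is gene-rowed); SNP-level output is kept for
audit. Because the published entry bookkeeping (14 genes / 13 regulatory
SNPs with one SNP shared between two genes and one gene carrying two) does
not reconcile into a single count, the summary reports distinct-SNP and
per-gene-entry counts separately rather than guessing.

**Concordance.** Concordant means within-phenotype identity AND
between-phenotype difference; rows identical across all four strains are
discordant (no phenotype signal). Absent, heterozygous, or non-single-base
alleles make a row not-evaluable — the panel strains are inbred, so a het
indicates an annotation conflict, and indels/multi-allelic panel rows are
not compared.

## Synthetic data: what it emulates and what it does not

The generator's defaults are the study conditions at desk scale: 5,000
variants over three 1-Mb autosomes plus a Y chromosome (with a
pseudoautosomal-like gene, so sex-chromosome rows are exercised), 60 genes,
fractions 0.4 shared / 0.2 Fat-private / 0.2 Lean-private, 20% novel
(no rs id), 10% hard-filter failures each violating exactly one criterion,
4% indels, a GERP mixture of a N(0,1) bulk plus a 2% conserved tail uniform
on (2, 9], six planted candidates (alternating regulatory/impact and
Fat/Lean), three decoys per two-clause class, and two seed-region SNPs
(one per strand) reproducing the CCAAUGA→CCAAUGG substitution form.
Partition fractions are planted exactly (quota fill), not sampled
per-variant, so downstream counts must match the truth set to the variant.

Planting is constructive: candidates are built to satisfy the rule, and any
unplanted line-specific variant carrying a regulatory or impact annotation
draws its GERP score from the bulk clipped at 5.9, so the planted truth is
the exact selection surface. One extra candidate is planted with
deliberately discordant panel alleles (selected but never validated), and
one regulatory candidate is annotated to two genes.

Deliberately not emulated: linkage structure, mutation-rate or
recombination models, read-level data, realistic chromosome sizes and gene
density, genome-wide consequence composition, and population-scale GERP
distributions. Passing the recovery suite therefore demonstrates that the
pipeline's logic is exact on inputs with known answers — not that the
study's genome-wide counts would be reproduced from raw reads.

## Numerical and degenerate-input choices

Floats read from VCF are rounded to 4 decimals to erase float32 storage
noise, making read→write→read an identity. Zero denominators (no
line-specific SNPs, no missense variants, no protein length) yield absent
fractions or skipped records, never zeros. GERP-unscored variants are
tallied separately, never counted against a tier. Generator output is
byte-identical for a fixed seed; all randomness flows from one
`numpy.random.default_rng(seed)`.

## Problem sizes used in tests and acceptance

Oracle suites use 10^4 randomized metric vectors (hard filter), the full
4×4 zygosity grid (partition), exhaustive allele enumerations (concordance)
and 800-variant × 40-gene random fixtures (density). End-to-end recovery
runs 20 bundle seeds at ~5,000 variants each, a scale at which the whole
suite and the acceptance script each complete in well under a minute.

## Known limitations

* The published candidate-table inputs encode only what the table prints;
  genomic coordinates and exact GERP scores of those SNPs are placeholders
  (every score set above the threshold), so only the table's bookkeeping —
  not its genomic geometry — is reproduced.
* Consequence vocabularies evolve between annotation releases; unknown
  terms are kept but classified OTHER, which understates impact if a newer
  release renames a severe term.
* Per-site DP filtering can hide per-sample dropout in a joint VCF.
* The concordance rule is strict allele matching; it does not model
  identity-by-descent or local phylogeny, so convergent alleles validate.
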