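# g4utr

Selective constraint and functional enrichment analysis of G-quadruplex
motifs in mRNA untranslated regions.

## The problem

Guanine-rich RNA can fold into four-stranded G-quadruplex (G4) structures.
The canonical G4-forming sequence (pG4) is four tracts of three or more
guanines separated by loops of 1–7 nucleotides:

    GGG-N(1–7)-GGG-N(1–7)-GGG-N(1–7)-GGG

pG4 motifs are common in the 5′ and 3′ UTRs of human mRNAs, but whether they
are functional has been hard to establish. If they are, population genetics
predicts concrete signatures: depleted allele frequencies, an excess of rare
(singleton) variants at structurally critical positions, fewer polymorphic
sites than a neutral mutation model expects, and enrichment for regulatory
annotations (cis-eQTLs, RNA-binding-protein binding sites, disease variants,
allelic imbalance in expression).

`g4utr` is a tested, reusable implementation of that integrative analysis for
people working with transcript annotations, gnomAD-style variant tables,
GTEx-style eQTL/expression tables, eCLIP peaks, ClinVar-style tables and
allele-specific read counts. Every stage is exercisable on synthetic data
with planted, known truth, so the statistical machinery can be validated
without any external downloads.

## What it computes

- **Motif discovery** (`g4_annotation`) — canonical pG4 scanning on UTR
  sequences with a documented disambiguation policy (maximal G-runs,
  leftmost non-overlapping matches), tract/gap partition with 5′/central/3′
  guanine labels on trinucleotide tracts, projection through spliced blocks
  to genomic coordinates, CDS-overlap exclusion, constitutive vs alternative
  isoform classification, and a permutation test for the
  alternative:constitutive gene ratio (exact sequential sampling of pG4
  labels conditioned on ≥1 pG4 isoform per gene).
- **Variant filtering** (`variant_filtering`) — gnomAD-style quality filters
  (random-forest probability > 0.40, allele number ≥ 80% of the dataset
  maximum, no segdup/LCR/decoy flags, SNVs only), LOEUF-binned comparator
  transcript matching, and the pooled allele-count Fisher test
  AC/(AN−AC) between region classes.
- **MAPS** (`maps_model`) — the mutability-adjusted proportion of singletons:

      MAPS(class) = observed singleton proportion − E[singleton | context]

  where the expectation is a count-weighted regression of per-context
  singleton proportion on context mutation rate, calibrated on synonymous
  variants, with methylation-binned CpG rates and bootstrap significance
  against a comparator class.
- **Heptamer O/E** (`oe_substitution`) — observed vs expected polymorphic
  sites under a 7-mer-context substitution model, CpG positions masked,
  bootstrap 90% CIs, and an empirical depletion p-value against 25-nt
  windows from constraint-matched UTRs.
- **Enrichment statistics** (`enrichment_stats`) — cis-eQTL enrichment
  (lead / nominal / causal subsets), effect-direction bias in G-tracts vs
  loops, merged CLIP-peak density per kb, per-RBP and pairwise
  hypergeometric tests, knockdown differential-expression odds ratios with
  Benjamini–Hochberg control, and ClinVar variant density in disease genes.
- **Allelic imbalance** (`allelic_imbalance`) — a beta-binomial model of
  reference-allele read counts across heterozygous samples, ML-fitted in a
  numerically exact (ρ, θ) parameterisation, with a likelihood-ratio test
  against the no-bias null ρ = 0.5 (χ², 1 df).
- **Synthetic data** (`synthetic_data`) — generators for all of the above
  with planted truth: motif coordinates, per-class singleton excess δ,
  substitution-rate thinning, enrichment odds multipliers, and ASE (ρ, φ).

## Worked example

Generate a synthetic dataset, scan it, and test a variant for allelic
imbalance:

```bash
$ g4 simulate --out sim --seed 11
wrote 578 transcripts to sim

$ g4 scan --fasta sim/utrs.fa --annot sim/annotation.tsv \
          --out-bed motifs.bed --out-tracts tracts.tsv --out-isoforms iso.tsv
541 motifs written to motifs.bed

$ head -2 motifs.bed
chr2    2229    2252    G0001|G0001.0|5p    4    -
chr2    521     547     G0001|G0001.0|3p    4    -

$ g4 ase --counts counts.tsv
variant  n_samples  rho_hat  dispersion       lrt      p_value
    rsA         30 0.781775         0.0 86.884317 1.150581e-20
    rsB         30 0.524941         0.0  3.139967 7.639537e-02
```

The BED name is `gene|transcript|side` and the score is the motif's G-tract
count. In the ASE table, `rsA` was simulated with a true reference fraction
ρ = 0.8 and is called decisively imbalanced (ρ̂ ≈ 0.78, LRT p ≈ 10⁻²⁰),
while `rsB` (ρ = 0.5) is not. Every motif in `motifs.bed` matches the
generator's truth file `sim/truth_motifs.tsv` exactly, and the isoform
classifications in `iso.tsv` match `sim/truth_genes.tsv`.

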