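# Methods

This note documents the models, numerical choices and open design decisions
behind `g4utr`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Canonical pG4 scanning

The scanner searches sense-strand UTR sequence for the canonical pattern of
four G-tracts (runs of ≥3 guanines) separated by loops of 1–7 nucleotides.
A text pattern of this shape is ambiguous in two ways: a run of more than
three guanines can be split into alternative tract assignments, and
candidate matches can overlap. The implementation commits to one policy:

- G-tracts are always *maximal* runs (a run of 4+ guanines is one tract, not
  several overlapping ones). Nothing is lost by this: two tracts carved out
  of one run would need a zero-length loop, which the pattern forbids.
- Matches are reported greedily left to right without overlap. A reported
  motif consumes its four runs and the search resumes at the next run.

`N` bases break runs and count as loop characters; a motif containing `N`
inside a tract is impossible by construction. The same policy is pinned by a
brute-force oracle in the test suite (independent run enumeration over all
4-tuples of consecutive runs), so any change to the policy is a test
failure, not a silent drift. Whether overlapping matches should instead be
counted separately is genuinely open; the greedy policy mirrors ordinary
regex text-search semantics and is the package's own decision.

Coordinates are 0-based half-open everywhere internally; GTF-style 1-based
inclusive coordinates are converted at the I/O boundary, BED is emitted on
output. On the minus strand, transcript offset 0 maps to the highest genomic
coordinate. CDS overlap is tested against the coding blocks of the *whole*
annotation set, not only the motif's own gene, and CDS-overlapping motifs
are excluded from all gene- and variant-level analyses.

A gene "has a pG4" on a UTR side iff at least one protein-coding isoform
carries at least one non-CDS-overlapping motif there; unique genomic motifs
are distinct sets of genomic blocks. Gene-level classification
(constitutive: all isoforms carry one; alternative: some do) is invariant to
transcript input order.

## Isoform-label permutation test

The null model for the alternative:constitutive gene ratio permutes the
pooled pG4/non-pG4 transcript labels while keeping each gene's isoform count
and the global number of pG4 transcripts fixed, conditioned on every gene
retaining at least one pG4 isoform, uniformly over all valid assignments.
Rejection sampling is hopeless at scale (the conditioning event is
exponentially rare), so the sampler draws per-gene pG4 counts sequentially
and exactly: gene *g* receives *j* labels with probability proportional to
C(n_g, j) times the number of valid completions for the remaining genes,
read off suffix products of the generating polynomials (1+x)^{n_g} − 1
(max-normalized per suffix; only within-suffix ratios are used). The test
suite verifies the sampled distribution against exhaustive enumeration on
small fixtures. The p-value (1 + #{null ratio ≥ observed}) / (n_iter + 1) is
one-sided for an *excess* of alternative genes and, because the ratio is
discrete, conservative rather than exactly uniform under the null — the
suite checks validity (P(p ≤ x) ≤ x), not exact uniformity.

On the default synthetic preset this p is ≈ 1: the generator plants *more*
constitutive genes than the constrained-uniform null expects, so the
one-sided excess-of-alternative statistic is unremarkable there. That is a
property of the generator's inclusion defaults, not of the test.

## Variant filters and the allele-frequency test

Filters: random-forest probability strictly greater than 0.40 ("did not
exceed 40%" excluded), allele number ≥ 80% of the dataset maximum AN, no
segdup/LCR/decoy flag, biallelic SNVs only (multi-allelic records are
decomposed first; each ALT judged independently). The AN maximum is computed
per chromosome type (autosome vs X) from the input table itself, since a
global maximum would mis-calibrate X-linked records; a scalar override is
accepted. Filtering is idempotent.

The depletion test pools AC and AN per region class and runs a two-sided
Fisher exact test on [[ΣAC_a, ΣAN_a−ΣAC_a], [ΣAC_b, ΣAN_b−ΣAC_b]]. The
exact test conditions on allele-level exchangeability; its type-I error is
checked in simulation at that level (binomially drawn allele counts under a
shared frequency). Pooling heterogeneous sites introduces clumping the test
does not model, which is inherent to this statistic, not an implementation
artefact.

LOEUF matching draws one comparator transcript per target, without
replacement, from the same LOEUF bin (default width 0.1 — the source data
give no matching granularity; 0.1 balances bin occupancy against fidelity
and is exposed in configuration). Targets are processed in a seeded random
order so bin exhaustion cannot systematically favour early targets; an
exhausted bin widens to the nearest non-empty bin with a warning.

## MAPS

MAPS for a variant class is the observed singleton proportion minus the
mean predicted singleton proportion, where the prediction is an ordinary
least-squares fit of per-context singleton proportion on context mutation
rate over synonymous (assumed-neutral) variants. Choices:

- The regression is weighted by per-context variant count (the alternative,
  unweighted, is a config option). With count weights and an intercept, the
  training set's own MAPS is exactly 0 — a structural invariant the tests
  assert at 1e−12.
- Contexts are keyed by (trinucleotide, alt, methylation bin); methylation
  bins apply only at CpG dinucleotides: none/low < 0.2, intermediate
  0.2–0.6 (both endpoints inclusive, following the printed intervals), high
  > 0.6; non-CpG or missing levels fall in a separate bin.
- Predictions are clamped to [0, 1]; clamping events are logged.
- Variants in G-tracts longer than three guanines are positionally
  ambiguous and are excluded from positional (5′/central/3′) analyses.

Significance against a comparator class (position-matched non-pG4 GGG/CCC
variants by default, all-UTR variants selectable) uses bootstrap resampling
of both classes (comparator resample sized to the class); p is the
proportion of paired resamples with class MAPS ≤ comparator MAPS. Under the
null this p is asymptotically uniform (it converges to Φ of a standard
normal deviate); the acceptance suite checks uniformity with a
Kolmogorov–Smirnov statistic at the 1% critical value on 200 null
simulations with 1500 variants per class and 400 bootstrap iterations.

## Heptamer observed/expected model

Each position's expected polymorphism probability is the sum of the three
per-alternative substitution probabilities for its reference 7-mer context.
The table is strand-symmetrized on load (each entry averaged with its
reverse complement; toggleable) since the source model is strand-collapsed.
Because the model carries no methylation adjustment, any position that is
the C or the G of a CG dinucleotide on either strand is masked from both
observed and expected counts. Positions whose 7-mer contains `N` (or lacks
a full context at sequence edges) are dropped and logged. A polymorphic
site counts once regardless of its number of alternative alleles, and all
polymorphic sites count regardless of frequency.

Ratios get bootstrap 90% CIs by resampling positions with replacement at
the original class size; iterations with zero resampled expectation are
discarded and logged. The depletion test against background draws
fixed-length windows (default 25 nt, 5000 windows) from constraint-matched
UTR regions, bootstraps target and background in paired draws, and reports
p = proportion of draws with target ratio ≥ background ratio, so small p
means depletion. (Defining p through the opposite tail would assign p ≈ 1
to a depleted region; this package uses the tail consistent with "small p =
constraint".)

G-tracts and loop (gap) sequences are evaluated as separate region classes,
positions pooled across motifs within a class.

## Beta-binomial allelic imbalance

Reference-read counts k_i out of n_i across heterozygous samples are
modelled beta-binomially with mean ρ and overdispersion φ. Writing
θ = φ/(1−φ), the pmf takes the rising-factorial form

    P(k|n) = C(n,k) · Π_{j<k}(ρ+jθ) · Π_{j<n−k}(1−ρ+jθ) / Π_{j<n}(1+jθ)

which reduces *exactly* to the binomial at θ = 0. The usual α/β
parameterisation (α = ρ(1−φ)/φ) routes through differences of log-gamma
values of order 1/φ and loses all precision near the binomial boundary;
the rising-factorial form is computed with prefix sums in O(max depth) and
is exact there (the suite checks agreement with the closed-form binomial
likelihood to 1e−8, and with the independent α/β implementation at moderate
dispersion to 1e−9).

The alternative model maximises over (logit ρ, log θ) by Nelder–Mead from a
moment-based start plus a balanced restart; the null fixes ρ = 0.5 and
re-estimates the dispersion by bounded 1-D profiling (fixing it to the
alternative's estimate is a config option). The LRT statistic
2(ℓ_alt − ℓ_null) is referred to χ²(1); MLEs pinned at the low-dispersion
bound are reported as φ = 0 with a boundary flag, and p-values stay on the
χ²(1) scale with that flag rather than switching to a boundary mixture.
Samples need a configurable minimum total depth (default 1; the source
analyses state none).

## Enrichment statistics

All 2×2 odds ratios are ad/bc with Woolf (log-OR normal) 95% CIs; zero
cells receive the Haldane–Anscombe +0.5 correction for the CI and are
flagged. Fisher p-values are exact (verified against rational-arithmetic
enumeration for tables with totals ≤ 200). Lead-eQTL ties at equal minimal
p break by smallest genomic coordinate (logged). CLIP peaks are merged into
unique binding sites before counting; the density test's chi-square is
evaluated, as configured, at 2 degrees of freedom by default with a 1-df
option — a 2×2 comparison conventionally has 1 df, and the 2-df default is
kept purely as the documented configuration of this analysis. The density
contingency is peak counts vs non-peak base counts per class. The per-RBP
test is an upper-tail hypergeometric against all UTR peaks, significant at
Bonferroni-corrected p < 0.001 with module membership additionally
requiring ≥ 20 unique pG4-overlapping sites. ClinVar density restricts to
variants spanning ≤ 40 nt, excludes Benign/Likely-benign annotations, and
subsets to disease-associated genes (≥ 1 Pathogenic/Likely-pathogenic
variant); membership of boundary variants is unambiguous because all
intervals are half-open.

## Synthetic data: what it emulates, and what it does not

The generator's defaults define the desk-scale study conditions: 200 genes,
1–5 isoforms each, UTRs of 100–2000 nt, pG4 planted per UTR side at rate
0.6, ~60% of multi-isoform pG4 genes alternative; variant layer with
singleton probability a + b·μ(context) + δ_class (a = 0.30, b = 3.0 on
arbitrary-unit rates in [0.01, 0.1]; δ = 0.10 for central guanines, 0.04
for flank guanines, 0 for loops and background — a graded constraint
profile with the central position most constrained); eQTL/knockdown
enrichment planted on the odds scale (so odds ratios estimate the planted
multiplier directly: ×2 eQTL, ×2 knockdown), CLIP density ×6, ClinVar
density ×1.5; ASE at ρ = 0.8, φ = 0.05, 84 samples at ~50× depth — sample
sizes and effect magnitudes a practitioner would recognise from the
corresponding public resources.

Background UTR sequence is rejection-sampled (guanine weight 0.20) until it
contains no unplanted canonical motif, and planted motifs are re-scanned to
confirm they are recovered exactly, so truth files are complete by
construction. Isoforms of a gene share a genomic locus and differ by
alternative transcription start (5′) or polyadenylation (3′) points, which
is how non-pG4 isoforms exclude the motif; this realises shared genomic
motif coordinates across carrier isoforms but does not emulate internal
splicing of UTRs (projection through multi-block UTRs is tested on
hand-built fixtures instead). All randomness uses numpy's default
PCG64 generator, recorded with the seed in the output metadata; identical
config and seed give byte-identical outputs.

What passing these tests shows: the scanner is exact against enumeration;
the estimators are unbiased and the tests calibrated *under the generative
assumptions* (independent sites, context-linear singleton probabilities,
odds-scale enrichment, beta-binomial counts). What it does not show:
robustness to linkage disequilibrium, mapping bias, annotation error,
population structure, or mutation-rate model misspecification — none of
which the generator emulates.

## Problem sizes in tests and the acceptance script

The suite runs the scanner-vs-oracle comparison on 1000 random sequences;
MAPS checks at 1e5 variants per class; O/E coverage on 500 replicates of
1500 positions with 500 bootstrap iterations; LRT calibration on 1000 null
variants; enrichment recovery on 100 replicates per test. The acceptance
script runs the full pipeline once at the default preset, with 2000
bootstrap/permutation iterations per test and a heptamer table mean
cumulative rate of 0.08 so the O/E stage rests on a few hundred expected
events; its CLIP stage uses 3 peaks/kb background density so the fold
estimate rests on a few hundred peaks. These sizes are the package's chosen
desk scale; every stochastic quantity it reports carries its `n`.

## Known limitations

- The scanner deliberately ignores non-canonical G4s (2-quartet, bulged,
  long-loop) and scoring schemes (G4Hunter, cGcC); constraint estimates for
  G4 biology as a whole are therefore conservative.
- The MAPS regression is linear in the context rate; a saturating model
  might fit highly mutable CpG-transition contexts better. Predictions are
  clamped rather than re-modelled.
- The beta-binomial LRT treats samples as exchangeable and ignores
  per-sample genotype uncertainty; WASP-style mapping-bias correction is
  assumed upstream.
- The O/E empirical null resamples positions, not haplotypes; linked
  selection inflates its confidence at short distances on real data.
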