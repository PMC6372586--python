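# Methods

This note documents the models, estimators and design choices behind
`fgfrscreen`, and what the synthetic benchmark does and does not
demonstrate.

## 1. Consensus merging

The unit of analysis is the normalized biallelic variant key
(chrom, 1-based pos, ref, alt). Normalization uppercases alleles, trims
shared leading/trailing bases with position adjustment, splits
multi-allelic records upstream, and left-aligns indels through repeat
tracts when a reference window is supplied. Within a sample, the calls of
all callers reporting a key are merged into one consensus call:

- `caller_count` — number of distinct callers reporting the key;
- `depth`, `alt_depth` — medians across reporting callers, halves rounded
  up (deterministic tie-break). The median is robust to a single caller's
  depth-counting dialect (e.g. whether duplicates or MQ0 reads are
  counted), and the paired rounding preserves `alt_depth ≤ depth` because
  order statistics respect pointwise domination;
- `vaf = alt_depth / depth`, recomputed from the consensus counts so the
  identity `vaf · depth = alt_depth` holds exactly.

## 2. Filter cascade

Filters append reason codes; a call passes iff its reason set is empty,
every operation is idempotent, and nothing is dropped silently (off-target
calls are the one short-circuit: they leave the screen's scope immediately
with the single reason `OFF_TARGET` and are not further evaluated).
Site-level exclusions are strict inequalities — fewer than 2 callers,
coverage < 100 reads, < 20 alt reads — so boundary values pass.

**Recurrent artifacts.** Deep amplicon sequencing produces systematic
low-frequency errors (polymerase misincorporation early in PCR, context-
specific sequencing error) that recur across unrelated samples at low VAF.
For each key, the samples carrying it below `artifact_max_vaf` (2%) are
counted over the *pre-filter* cohort (more conservative: single-caller and
low-coverage occurrences still count toward recurrence); at ≥ 10 such
samples all of them are flagged. Occurrences at or above 2% VAF at the
same site are never flagged by this rule — the rule targets amplification
noise, and a co-located genuine somatic event should survive.

**Run bias.** A variant whose carriers concentrate in one sequencing run
is a batch artifact. We build the R×2 run × carrier/non-carrier table and
compute a two-sided exact p: Fisher's exact test for two runs; for more
runs, exact enumeration of the multivariate hypergeometric distribution
while the carrier total is ≤ 50, otherwise a chi-square statistic with a
seeded permutation p (10,000 resamples). "Two-sided" uses the
probability-mass criterion (every table no more likely than the observed
one), the same convention as `scipy.stats.fisher_exact`; the R×2
enumeration was validated against brute-force enumeration of carrier
subsets. The default α = 0.001 is deliberately conservative: with
hundreds of keys tested per cohort, a loose α would discard real variants
that happen to cluster by chance.

**Consequence.** Substitutions are mapped through explicit CDS segment
models (reverse-complementing on the minus strand), the affected codon is
re-translated, and synonymous or non-coding changes are excluded when the
screen is restricted to non-synonymous variants (the default). The
annotator was validated against a full-CDS-translation oracle on random
multi-exon transcripts of both strands. Indels pass normalization and
site filters but their protein consequence is not evaluated
(`UNEVALUATED`); under the non-synonymous restriction they are excluded —
a documented limitation, acceptable for a substitution-hotspot screen.

**Germline heuristic.** The screen has no matched normals, so germline
status is approximated two ways: membership in a supplied SNP list
(`KNOWN_SNP`), and a cohort-prevalence heuristic (`LIKELY_GERMLINE`): a
key carried by > 10% of the cohort with per-sample VAF in the heterozygous
[0.40, 0.60] or homozygous [0.90, 1.00] band. A germline polymorphism at
population frequency q appears in ≈ 2q(1−q) of samples at VAF ≈ 0.5,
so common polymorphisms trip the rule while rare somatic events (one
carrier in hundreds, arbitrary VAF) never do. Both flags are advisory
exclusions, configurable and off-switchable; neither decides
pathogenicity. A truly rare germline variant in a single patient is
indistinguishable from a somatic event under this design — the same
ambiguity any unmatched-tumor screen carries.

## 3. IC50 estimation

Each condition's survival curve is `mean(signal at dose d) / mean(drug-free
signal of the same condition)`. Normalizing to the condition's own
zero-dose control is what corrects combination conditions for single-agent
cytotoxicity of the modulators; the modulators' own kill fractions are
reported separately as `1 − control/untreated`. Survival above 1 (growth
stimulation) is permitted.

The IC50 is the dose where survival crosses 0.5, taken from the first
bracketing pair scanning from the lowest dose (non-monotone noisy curves
read left-to-right, like the assay plots); an exact 0.5 at a measured dose
returns that dose; curves entirely above (below) 0.5 are censored
`ABOVE_MAX` (`BELOW_MIN`) at the range boundary, and folds involving a
censored IC50 are reported as undefined rather than guessed.

Interpolation is linear in **logit(survival) against log10(dose)**. For a
Hill curve S = 1/(1+(d/IC50)^h) the logit is exactly linear in log-dose,
so the estimator is exact on noise-free sigmoid curves for any slope —
the property test verifies recovery within 10% across h ∈ [0.5, 4] on the
assay's six-point grid, where plain linear interpolation of survival can
err by ~50% at steep slopes on this wide (7.9×) dilution spacing. Plain
linear interpolation remains available (`interp="linear"`); both schemes
agree on symmetric brackets. With a survival floor B > 0 the logit of S is
no longer exactly linear and accuracy degrades as the 50% crossing moves
into the flat tail (B → 0.5) — an identifiability limit of any two-point
method, not specific to this estimator. Full four-parameter logistic
fitting with confidence intervals is out of scope by design: the assay's
definition is the 50%-of-control crossing, not a fitted midpoint.

Replicates are averaged before interpolation for the per-line IC50;
per-replicate IC50s (each replicate normalized to its own control well)
are retained for the paired test. Responsiveness is an FGF2/CTRL fold
≥ 1.5 (configurable; the underlying biology reported is a 2–3× shift, so
1.5 splits the observed bimodality), and reversal is a FGF2+AZD/CTRL fold
within 0.25 of 1. Because a two-point interpolated IC50 ratio at 4
replicates and ~4% signal noise has a standard deviation around 0.15, the
per-line reversal flag is noise-sensitive; panel-level statements should
use the mean reversal fold across responsive lines, which is stable.

## 4. Wilcoxon matched-pairs test

Zero differences are dropped, tied absolute differences get mid-ranks, and
for up to 25 informative pairs the two-sided p is exact: the fraction of
all 2^m sign assignments whose rank sum deviates from the null centre
m(m+1)/4 at least as far as observed. The distribution is computed by
dynamic programming over doubled (integer) ranks — identical to full
enumeration, verified against it exhaustively for m ≤ 10 and against
`scipy.stats.wilcoxon` exact p where ties are absent. Beyond 25 pairs a
normal approximation with tie correction and continuity correction is
used. Because replicate counts per cell line differ in practice, the
panel reports the test under both defensible pairings — one pair per
replicate and one pair per line.

## 5. Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the pipeline assumes:

- **Depths**: gamma-Poisson (negative binomial) around the amplicon mean
  (default mean 1000×, shape 100 — deep targeted sequencing with modest
  overdispersion; the study's true per-sample depth distribution is
  unpublished, so this is a stand-in).
- **Callers**: a caller reports a site iff its binomial alt count reaches
  its detection floor (floors 2–5 reads across the four caller labels),
  plus independent caller-specific false positives at 2×10⁻⁵ per target
  base per sample with VAF ~ U(0.001, 0.05) — the simplest model that
  makes single-caller exclusion informative.
- **Artifacts**: recurrent low-VAF keys shared by a configurable number of
  samples; run-restricted keys for batch effects; high-prevalence
  VAF≈0.5 keys for germline structure.
- **Plates**: survival S(d) = B + (1−B)/(1+(d/IC50)^h) with the condition
  IC50 shifted by the FGF2 fold and restored under the inhibitor when the
  line is reversible; signal = untreated level × (1 − single-agent kill) ×
  S(d) + Gaussian noise (sd 0.04 of the untreated level, truncated at 0 —
  noise on the survival scale, without modelling plate optics).

The packaged scenario fixes the study conditions: 481 primary, 28 relapse
and 12 cell-line samples over two runs; the four reported variants (VAFs
0.285/0.408/0.084/0.529 at depth 1000) in four distinct primary samples;
240 distinct decoy variants spanning every failure reason, with parameter
margins ≥ 3σ from each threshold a class must not trip; and an eight-line
panel with five reversible 2.5-fold responders at 4 replicates. Gene
models are synthetic: random stop-free CDS of the true protein lengths
(822/821/806 aa) with the variant codons pinned to the wild-type
triplets, built once with a fixed internal seed so coordinates are stable;
FGFR2 is placed on the minus strand to exercise orientation handling. The
user seed drives all stochastic draws.

**What passing does not show.** The benchmark cannot validate behaviour it
does not model: alignment and realignment artifacts, PCR chimeras,
strand bias, UMI structure, contamination, CNV-distorted VAFs, or real
caller disagreement patterns (real callers differ in more than a
detection floor). Recovery of the designed truth demonstrates that the
cascade implements its rules correctly and that the rules separate the
designed signal/noise classes — not that the thresholds are optimal for
any particular real data set.

## 6. Numerical and reproducibility choices

- Medians: halves rounded up; exact-test ties compared with a 10⁻⁹
  relative tolerance; interpolation clamps survival to (ε, 1−ε), ε=10⁻⁹,
  before the logit.
- Coordinates: variants 1-based (VCF convention); BED targets 0-based
  half-open; containment honored exactly at boundaries.
- Every stochastic step (simulators, permutation p-values) takes an
  explicit seed; reports carry the seed and a hash of the effective
  configuration, and equal seed + configuration reproduce outputs
  byte-identically (timestamps excluded).
- Problem sizes in the test suite (cohort of 521 samples, ~2,600 caller
  rows, 1,000-substitution annotator checks, exhaustive sign enumeration
  to n = 10) were chosen to exercise every code path while keeping the
  default suite fast.
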