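# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of the pipeline.

## Differential aggregation from LFQ intensities

The input is a MaxQuant-style protein-group table. Zeros are non-detections
and are stored as missing; contaminant and decoy ("reverse") rows are removed
before anything else. Intensities are log2-transformed and proteins detected
in fewer than two replicates of *both* conditions are dropped (the ">1
repeats in either condition" prefilter).

**Imputation.** LFQ missingness is missing-not-at-random: a cell is missing
because the intensity fell below the detection limit. Missing cells in
sample *j* are drawn from `N(mu_j − downshift·sd_j, (width·sd_j)²)` with
`downshift = 1.8` and `width = 0.3` (the widely used defaults for
left-censored proteomics imputation, exposed in `ImputationConfig`), where
`mu_j`/`sd_j` are the observed per-sample statistics. The draw is repeated
`n_draws = 100` times and the completed matrices averaged cell-wise before
testing. Averaging first and testing once (rather than combining 100 test
statistics) is the documented convention of this pipeline. The standard
normal deviate for cell (i, j) in draw d is a pure function of
(seed, d, i, j), so results do not depend on iteration order or on which
cells happen to be missing. A sample with fewer than two observed values
falls back to global statistics, with a warning.

**Testing and calling.** Per-protein two-sided t-tests compare case vs
control columns of the averaged matrix. The default is **Student's
pooled-variance** test: with four replicates a side, per-group variance
estimates are extremely noisy, and Welch's Satterthwaite degrees of freedom
(≈ 3 on imputation-mixed rows) cost real power without a compensating
robustness benefit at this sample size; pooling is also the common practice
in proteomics differential analysis. Welch is available via
`equal_var=False`. p-values are Benjamini–Hochberg adjusted (step-up,
clipped at 1). Calls use inclusive thresholds — p_adj ≤ 0.05 and
|log2 FC| ≥ 1 — plus the anti-artifact gate that the called side must have
≥ 2 *detected* (non-imputed) replicates. Inclusive rather than strict
inequalities are used throughout this stage; the RNA-seq stage uses strict
cutoffs (below), matching the respective conventions of each analysis.

**A known property of averaged imputation.** For proteins observed in some
but not all replicates, the imputed values sit near a global low-intensity
constant, which inflates within-group variance and biases the group mean
low. Under a true null this keeps the procedure conservative at the call
level (the detection gate blocks the classic presence/absence false
positives), but raw p-values of the partially-detected class deviate from
uniformity. The deviation shrinks as the detection transition becomes
sharper relative to between-protein intensity spread; see the generator
notes below.

## Fraction classification

Labels are mutually exclusive and assigned in precedence order: `increased`
and `decreased` from the calls; `baseline` for proteins detected in ≥ 2
replicates of both conditions with p_adj > 0.05 (a called protein is never
baseline); remaining aggregate-detected proteins become `other_aggregate`;
proteins seen only in the WCL become `nia`. The partition property (every
id labeled exactly once) is enforced and tested. Cross-experiment
consistency is summarized as the mean over ordered pairs of |A∩B|/|A|, a
directional overlap suited to "how much of experiment A recurs in B".

## Supersaturation and LLPS propensity

`sigma = log10(abundance + pseudocount) + z`, with `pseudocount = 1` (so a
zero-abundance protein contributes exactly its standardized propensity) and
`z` the propensity score standardized by the mean/SD of the WCL reference
set. The threshold tau is the median sigma of the WCL reference; the
"supersaturated" flag is `sigma > tau`, which is invariant under any
strictly monotone transform applied jointly to sigma and tau. Abundance
defaults to transcript CPM (mean across samples); protein-level abundance
(LFQ or imported NSAF) can be substituted wherever an abundance mapping is
accepted.

Imported predictor tables (TANGO, CamSol, catGRANULE, PScore, NSAF) are
authoritative when provided. The built-in predictors are intentionally
simple sliding-window scorers (window 7) over shipped per-residue scales:
the aggregation scale rewards hydrophobic/β-prone residues and penalizes
charge and proline; the LLPS scale rewards disorder-promoting composition
and R/G/Y/F. The per-protein summary is mean(positive windows) ×
fraction(positive windows), rewarding both intensity and extent of
high-scoring regions. These are rough composition heuristics for ranking
within synthetic or exploratory data — they are **not** reimplementations
of the published predictors and should not be compared numerically to them.

## Enrichment and figure-level statistics

Membership enrichment uses a 2×2 Pearson chi-square without Yates
correction (df = 1), appropriate for the large counts of proteome
fractions; a zero margin raises an error recommending an exact test. The
background defaults to the NIA fraction and is configurable. Kruskal–Wallis
uses the tie-corrected H with a chi-square reference; an all-identical
input returns H = 0, p = 1 by convention. Dunn's post-hoc z-statistics use
pooled ranks with the tie term Σ(t³−t)/(12(N−1)) and Bonferroni family-wise
adjustment over all pairs (Šidák by flag). The Wilcoxon signed-rank test
drops zero differences, uses average ranks, and computes the exact
two-sided p for n ≤ 25 by dynamic programming over doubled ranks (identical
to enumerating all 2^n sign assignments, including tied ranks); above that
a tie-corrected normal approximation without continuity correction is used.
Planned pairwise Student t-tests are Bonferroni-adjusted
(p_adj = min(1, m·p)).

## RNA-seq differential expression

Counts from a 3′-end protocol are filtered (count > 1 in ≥ 2 samples) and
normalized as prior-damped logCPM with `prior_count = 2` scaled
proportionally to library size. Testing uses a **common-dispersion**
negative-binomial likelihood-ratio test: a single dispersion estimated by
method of moments (average over genes of max(0, (s² − m)/m²) with pooled
within-group variance), per-gene rate MLEs under null (one rate,
library-size offsets) and alternative (rate per group) found by Newton
iteration (closed-form at equal library sizes or zero dispersion), LR
referred to chi-square(1). logFC is the unshrunk log2 ratio of fitted
rates over the control group. Calls use strict cutoffs |logFC| > 1,
FDR < 0.05. This deliberately replaces gene-wise empirical-Bayes dispersion
machinery to keep the stage self-contained and exactly testable; an
externally computed DE table is accepted as a drop-in. No TMM/composition
normalization is applied — library-size offsets only, which suits 3′-end
counts. At eight samples the LRT is mildly liberal (measured type-I error
≈ 0.052 at nominal 0.05 on matched-dispersion nulls); the dispersion-0 path
reduces exactly to the Poisson LRT.

## The synthetic-data generator

The generator encodes a threshold model: treatment lowers the cell's
aggregation threshold, so the proteins closest to it — the most
supersaturated — aggregate first. Per protein, abundance is log-normal
(log10 CPM ~ N(1.5, 1), a typical expressed-gene CPM spread), propensity
z ~ N(0, 1), sigma = log10(abundance+1) + z, and aggregation in a condition
is Bernoulli with probability logistic((sigma − tau)/steepness). Defaults:
tau_control = 3.5 (≈ 8% of the proteome constitutively aggregating),
tau_treated = 2.8, steepness = 0.25 (probabilistic boundary, so borderline
proteins exist). A shared latent uniform per protein nests the treated
aggregator set over the control set; `n_gainers` plants an exact number of
treatment gainers (sampled proportionally to their logistic gain
probability), which makes sensitivity exactly measurable. The planted
scenario used throughout validation is 2000 proteins, 150 gainers, 4 vs 4
replicates, effect 2 log2 units.

Observed log2 intensity is affine in log10 abundance (slope log2(10)) plus
N(0, 0.3²) replicate noise — about a 20% CV, typical of LFQ. Aggregating
proteins gain `effect_size` log2 units in that condition's aggregate
fraction. Detection is Bernoulli with probability
logistic((log2 intensity − 20)/0.25): a sharp transition, consistent with a
detection-limit mechanism operating on log intensity, which produces the
presence/absence structure characteristic of aggregate fractions — the
aggregate-fraction offset (15) puts the average non-aggregator about two
log2 units below the detection midpoint, so non-aggregators are mostly
missing there, while the WCL offset (19) keeps most proteins detected.
The sharpness matters: a soft detection curve creates a large
partially-detected class whose imputed values distort raw p-values (see
above), whereas real aggregome data are dominated by clear presence/absence.
Transcript counts are negative-binomial with mean proportional to
abundance × library size (dispersion 0.05, library 5e6) and identical
across conditions — the generator deliberately encodes that the aggregation
signal is not transcription-driven. Annotation sets are drawn without
replacement with an odds multiplier on treatment gainers; the realized odds
ratio is recorded.

**What the generator does not emulate:** correlated missingness across
samples, batch effects or run-order drift, per-sample detection-limit
variation (deliberately omitted for test stability), peptide-level rollup
artifacts, protein sequences (propensities are drawn, not computed from
sequence), shared-peptide protein-group ambiguity, and transcript–protein
abundance divergence. Passing the synthetic benchmarks therefore shows the
statistics behave correctly under the stated model, not that the pipeline
is robust to every artifact of real acquisitions.

## Validation scenarios and problem sizes

The acceptance benchmarks run at the scale of the study conditions: the
null and planted scenarios use 2000 proteins with 4 vs 4 replicates (the
planted recovery averages 5 independent seeds; per-seed sensitivity has a
binomial sd of ≈ 0.03 at 150 planted effects, so means over seeds are the
stable summary); NB calibration uses 5000 matched-dispersion null genes;
enrichment calibration uses 200 replicate annotation sets; the determinism
check runs the full pipeline twice at 600 proteins and compares SHA-256
checksums of every output. All scenario seeds derive from a single entry
seed via `SeedSequence`.

## Degenerate inputs and tie-breaks

Zero-variance t-test rows: t = 0, p = 1 when means agree, p = 0 otherwise.
Empty gene sets are retained with a warning. Medians of even-length vectors
use the midpoint. All-zero count genes: p = 1, logFC = 0. A fraction with
no scored proteins is omitted from score summaries with a warning. Unknown
residues score 0 in the windowed predictors. BH adjustment errors on
p-values outside [0, 1] rather than clipping silently.

## Known limitations

- The common-dispersion NB test under-models genes with atypical
  dispersion; it is a documented simplification, not an edgeR replacement.
- The built-in propensity scales are composition heuristics; conclusions
  about real proteins should use imported predictor scores.
- Raw p-values from the averaged-imputation t-test are exactly uniform only
  for fully-observed proteins; the detection gate, not the p-value, is the
  guard against presence/absence artifacts.
- Identifier reconciliation is by first accession and case-insensitive
  symbol matching; cross-species homolog mapping must be supplied
  explicitly.
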