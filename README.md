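# aggregome

Analysis pipeline for **genotoxic-stress-induced protein aggregation**:
differential-aggregation calling from label-free proteomics of SDS-insoluble
fractions, classification of the proteome into aggregating / baseline / NIA
fractions, supersaturation and liquid-liquid phase-separation (LLPS)
propensity scoring, annotation-set enrichment, and a simplified RNA-seq
differential-expression stage — together with a synthetic-data generator that
plants a recoverable ground truth for every stage.

## Who this is for

Proteomics groups that isolate detergent-insoluble "aggregome" fractions
(e.g. the 1% SDS-resistant pellet after sequential extraction) from treated
and untreated cells, quantify them by MaxQuant label-free quantification
(LFQ), and want a tested, reproducible route from `proteinGroups.txt` to
called aggregation changes, fraction definitions and metastability
statistics.

## The model and statistics at the core

**Differential aggregation.** LFQ intensities are log2-transformed; zeros are
non-detections. Missingness in LFQ data is missing-not-at-random (MNAR): low
intensities fall below the detection limit. Missing cells in sample *j* are
imputed from a downshifted Gaussian

&nbsp;&nbsp;&nbsp;&nbsp;x ~ N(μ_j − 1.8 σ_j, (0.3 σ_j)²)

where μ_j, σ_j are the observed mean and SD of that sample; the draw is
repeated 100 times and the completed matrices averaged before per-protein
two-sided t-tests with Benjamini–Hochberg correction. A protein is called
**up** when p_adj ≤ 0.05, log2 fold change ≥ 1 **and** it was detected (not
imputed) in ≥ 2 case replicates; **down** is the mirror image.

**Fractions.** *increased*/*decreased* come from the calls; the *baseline
aggregating fraction* is detected in ≥ 2 replicates of both conditions with
p_adj > 0.05 (constitutive aggregation, unchanged by treatment); *NIA* ("not
identified as aggregating") proteins appear only in the whole-cell lysate
(WCL), never in any aggregate fraction, and serve as the enrichment
background.

**Supersaturation.** A protein expressed highly relative to its intrinsic
aggregation propensity is supersaturated and aggregation-vulnerable:

&nbsp;&nbsp;&nbsp;&nbsp;σ = log10(abundance + 1) + z

with abundance in transcript CPM and z the propensity score standardized
against the WCL reference. Proteins above the WCL-median iso-σ line are
flagged supersaturated. Propensity scores are imported (TANGO, CamSol,
catGRANULE, PScore tables) or computed by deliberately simple built-in
windowed predictors shipped as labelled approximations.

**Enrichment and figure statistics.** 2×2 Pearson chi-square (no continuity
correction) of set membership in a fraction vs the NIA background;
Kruskal–Wallis with Dunn's post-hoc z-tests; exact Wilcoxon matched-pairs
signed-rank (n ≤ 25 by enumeration); Student t-tests with Bonferroni
correction.

**RNA-seq.** Genes need count > 1 in ≥ 2 samples; prior-damped logCPM
normalization; a common-dispersion negative-binomial likelihood-ratio test
(method-of-moments dispersion, library-size offsets); calls at |logFC| > 1
and FDR < 0.05.

**Synthetic ground truth.** The generator operationalizes a threshold model
of aggregation: each protein aggregates with probability
logistic((σ − τ)/s), and "treatment" lowers τ. Observation layers add
replicate noise, an intensity shift for aggregating proteins, MNAR
detection, negative-binomial transcript counts and annotation sets with
planted enrichment — so sensitivity and false-discovery rate of every stage
are measurable.

## Worked example

Run the numbered analysis scripts from the repository root:

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_differential_aggregation.py --seed 1
python analysis/03_classify_fractions.py
python analysis/04_metastability.py
python analysis/05_enrichment.py
python analysis/06_rnaseq_de.py
```

which prints, among other lines:

```
planted: 2000 proteins, 150 treatment gainers, planted annotation odds ratio 5.67
planted: tested 1100 proteins, calls {'ns': 958, 'up': 140, 'down': 2}; sensitivity 0.920, empirical FDR 0.014 (150 planted gainers)
fraction sizes: {'increased': 140, 'decreased': 2, 'baseline': 853, 'other_aggregate': 105, 'nia': 839}
WCL-median saturation threshold tau = 1.632
  increased: n=140, median sigma 2.870
  nia: n=839, median sigma 0.828
Kruskal-Wallis H=662.4, p=1.45e-144
increased x planted_set: 48/140 in set vs 61/839 of background, OR 6.65, chi2 88.5, p 5.08e-21
tested 1949 genes at common dispersion 0.0603: 0 up, 0 down (expression is unchanged by design)
```

Reading this: of 150 proteins whose aggregation truly increased, 138 were
called (sensitivity 0.92) with 2 false calls among 140 (empirical FDR
0.014); the called *increased* fraction is far more supersaturated than the
NIA background (median σ 2.87 vs 0.83, Kruskal–Wallis p ≈ 1e-144); the
annotation set planted at odds 5 is detected at chi-square p ≈ 5e-21; and
the RNA-seq stage correctly finds no expression changes, confirming the
aggregation signal is not transcription-driven.

The same stages are available as a CLI (`aggregome simulate | diff-agg |
classify | metastability | enrich | rnaseq-de | stats | run-all`); `run-all`
drives everything from a YAML config and writes a manifest with SHA-256
checksums of every input and output.

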