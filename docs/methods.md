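# Methods

## The analysis

`mirglia` implements an integrative screen for candidate miRNA:mRNA
regulatory interactions in a two-condition activation experiment, the
design used for microglial polarization studies: resting cells (M0),
LPS-driven classical activation (M1) and IL-4-driven alternative activation
(M2a), with three array replicates per condition and paired mRNA/miRNA
log2 expression matrices measured on the same samples.

The screen runs in five stages:

1. **Differential expression.** For each contrast (treated vs M0) every
   feature gets a two-sided Student's t-test on log2 expression with pooled
   variance (a Welch option exists for unequal variances), log2 fold change
   as the difference of group means, a signed linear fold
   (|fold| = 2^|log2FC|, sign from the log2FC, 0 → 1), and a
   Benjamini–Hochberg q computed across all tested features. Default
   significance conventions: genes p < 1e-4, miRNAs p < 0.05, heatmap-style
   selection q < 1e-7; all configurable.
2. **miRNA shortlist.** Differentially expressed miRNAs are kept only if
   well expressed: mean expression on linear scale (2^(mean log2 across all
   samples)) strictly greater than 50% of the platform's
   highest-expressing reference miRNA (miR-709 in microglia). The linear
   scale is a package choice; the comparison scale is not dictated by the
   convention the rule comes from.
3. **Correlation screen.** For each shortlisted miRNA, Pearson r against
   every gene across the pooled samples of the contrast's two conditions
   (n = 6 by default). Pooling only the contrast's samples — rather than
   all nine arrays — is a deliberate choice: each interactome is
   contrast-specific; `all_samples=True` switches to the full design.
   Zero-variance gene profiles get r = 0 with a degenerate flag rather
   than an undefined correlation. Candidates must pass |r| > 0.5 and DE
   p < 1e-4, both strict inequalities.
4. **Database intersection and direction classification.** Candidates are
   intersected with two independent predicted-target databases (GMT input,
   e.g. miRanda-like and TargetScan-like exports); only the triple
   intersection enters the interactome. Each record carries the
   correlation ("correlation factor"), the log2 fold change, the DE
   p-value ("power" — the term is ambiguous in published tables of this
   shape; interpreting it as the correlation's significance instead is a
   one-line switch since both are carried through), and a direction:
   inversely correlated (r < 0, the canonical repression mode) or
   positively correlated. Tables are sorted positive block first, then
   inverse, by descending |log2FC| with alphabetical tie-break. Overlap
   statistics (fraction of correlated-and-DE genes found in each database
   and in both) are reported alongside.
5. **Enrichment.** Interactome genes are tested for over-representation in
   user-supplied annotation collections with a one-sided hypergeometric
   test, using the measured genes (the expression matrix's symbols) as the
   universe — only measured genes could have entered the query. BH across
   the collection, ranking by −log10(p), pooled across miRNAs with
   duplicate set names kept as separate rows, and the conventional
   significance line at −log10(0.05) = 1.30. This replaces proprietary
   knowledge-base scoring with a transparent statistic, so absolute
   p-values are not comparable to curated-network tools; the workflow
   shape and threshold convention are what is reproduced. Activation
   z-scores and causal direction of networks are out of scope.

Symbol hygiene underpins all set operations: gene symbols are upper-cased
(array annotations, prediction databases and curated tables disagree on
case), miRNA ids keep the `miR-` stem convention with species prefixes
stripped and star forms (`miR-191*`) preserved as distinct features.

## The synthetic data generator

`simulate.generate_dataset` produces paired matrices, sample sheet, two
prediction databases, an annotation collection and a `SyntheticTruth`
record from one config and seed. The generative model, per feature and
sample of condition c:

    mirna = baseline + effect_c + N(0, noise_sd)
    gene  = baseline + effect_c + Σ_edges β·(mirna − mirna_baseline) + N(0, noise_sd)

A gene downstream of an edge inherits the miRNA's condition shift scaled by
β *and* its per-sample noise, which is what makes planted edges
recoverable by correlation at n = 6. Repressive edges (β < 0) emulate
canonical miRNA repression; activating edges (β > 0) the positively
correlated candidates that observational screens also surface (in the kind
of data this emulates, roughly 40% of candidate targets correlate
positively).

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| design | M0/M1/M2a × 3 replicates | the study design the pipeline targets |
| noise_sd | 0.2 log2 units | makes n=3 t-tests at p<1e-4 attainable for marker-scale planted folds; no error model is dictated by the emulated data, so log-normal (additive Gaussian on log2) is used |
| presets | il6_like 425× (M1), chi3l3_like 38.85× (M2a), mir155_like 9.69× (M1), mir145_like 2.66× (M2a) | headline effect magnitudes of the emulated study, named so recovery reports read naturally |
| reference miRNA | miR-709-like, baseline 11 log2 | anchors the 50%-of-reference shortlist rule; program miRNAs draw baselines in 10.0–10.8 so they are shortlist-eligible, generic miRNAs in 3–8 so they are not |
| edges per program | 8 repressive (β ≈ −0.9) + 5 activating (β ≈ +0.7), ×U(0.8,1.2) jitter | ~60/40 inverse/positive split, matching the direction ratio the screen is meant to classify |
| db_sensitivity / db_noise | 0.9 / 5 decoys per miRNA | imperfect, partially disjoint prediction databases |
| decoy annotation sets | 5, size-matched to the true program sets | keeps enrichment calibration honest |

Sizes (200 genes × 30 miRNAs by default, 60 × 12 in the recovery
benchmark) are desk-scale; effect recovery is per-feature and does not
depend on panel size, and the benchmark keeps 200 seeded replicates cheap.

**A note on the noise regime.** A regulatory target's variance is roughly
(1+β²)·noise_sd², and a pooled t-test at n = 3 needs |t| ≳ 15.5 for
p < 1e-4 (df = 4). At noise_sd 0.2 the marker genes (pure condition
effects) clear the filter easily but edge-propagated targets sit near the
boundary, so the end-to-end worked example in `analysis/` generates its
dataset at noise_sd 0.1, where the planted program traverses the whole
funnel. Array data summarised over ~40 probes per gene has replicate noise
closer to that regime; the generator does not otherwise model probe-level
physics, batch effects or normalization artifacts.

What passing tests on synthetic data do *not* show: recovery of real-array
results. Real arrays have heteroskedastic, feature-dependent noise,
correlated genes beyond the planted edges, and prediction databases whose
errors are not independent; the generator's planted truth certifies the
pipeline's logic (filters, intersections, classification, calibration),
not biological discovery.

## Numerical choices and degenerate inputs

- Features constant in both groups: t = 0, p = 1 when means coincide
  (fold 1, neither up nor down); t = ±∞, p = 0 when they differ (the
  zero-noise limit). Both carry a `degenerate` flag.
- BH uses the standard step-up with monotonicity enforcement
  (statsmodels `fdr_bh`); order-preserving and verified against the
  brute-force definition.
- Correlations are clipped to [−1, 1] against floating-point drift;
  zero-variance profiles get r = 0, degenerate.
- Hypergeometric tails use the survival function (no 1−CDF cancellation).
- All sorts use stable mergesort with documented tie-breaks (gene symbol
  alphabetical), so outputs are byte-reproducible.
- Empty candidate sets propagate as empty tables, and overlap fractions
  over an empty candidate set are NaN with an `undefined` flag rather
  than a silent zero.

## Known limitations

- The t-test is unmoderated; at n = 3 per group an empirical-Bayes
  variance moderation (limma-style) would be more powerful. Out of scope
  by design.
- Correlation at n = 6 has a heavy null tail (P(|r| > 0.5) ≈ 0.31 under
  independence), which is why the screen requires the conjunction with
  the strict DE filter and dual-database prediction support; the
  correlation threshold alone is not evidence.
- Probe-to-gene collapsing is not performed: inputs are assumed to be
  one row per gene symbol.
- Enrichment p-values depend entirely on the supplied annotation
  collections; with proprietary knowledge bases out of scope, counts of
  "altered networks" from such tools cannot be reproduced.
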