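# Methods

This note documents the models, estimators, and design choices behind
`pallidyn`, and what the synthetic cohorts do and do not establish about real
recordings.

## Spike trains and featurization

A neuron is a strictly increasing sequence of spike times on the half-open
window [0, duration), labelled with unit, patient and gene. All metrics are
computed from the ISI sequence or the binned spike indicator; a metric that
cannot be computed is NaN ("undefined"), never zero — in particular burst and
oscillation summary statistics exist only for neurons in which the phenomenon
was detected, so cohort summaries of those columns pertain exclusively to
bursting/oscillatory neurons.

**Firing regularity.** The score is log10 of the maximum-likelihood gamma
shape fitted to the ISIs (scipy, location fixed at 0). It is 0 for Poisson
firing, ~1 for shape-10 (clockwork-like) firing, negative for bursty trains.
Recovery error is < 0.02 in log10 units at 2,000 ISIs across shapes 0.5–10
(measured by the test suite). Exactly constant ISIs make the MLE diverge; the
score is capped at 6.0 (shape 10^6) so downstream tables stay finite. The
gate is 10 ISIs; below it the score is undefined.

**Local variation** uses the standard squared-difference form over adjacent
ISI pairs; it is scale-invariant and equals 3 E[((I1−I2)/(I1+I2))^2]
(expectation ≈ 1 for Poisson).

**Burst index and asymmetry index** are mean(ISI)/mode(ISI) and its
reciprocal, with the mode taken as the center of the maximal histogram bin
(5 ms default bins; lowest bin wins ties; a constant-ISI train uses the
single value as its mode). These are histogram estimators: for very flat ISI
densities (e.g. gamma shape ≈ 2) the mode estimate carries a few-bin bias,
which the tests tolerate explicitly.

**Burst detection** is a Poisson-surprise scan. Candidates are runs of
(min_spikes − 1 = 2) consecutive ISIs shorter than half the mean ISI. The
window end is extended while the surprise improves (with a 10-spike lookahead
over transient dips) and the start trimmed likewise. The surprise of a window
anchored at a spike is S = −log10 P(Poisson(rT) ≥ k), where r is the train's
mean rate, T the window span, and k the number of spikes *after* the anchor —
the renewal process restarts at the anchoring spike, so the anchor itself is
not evidence. The tail is evaluated through the regularized incomplete gamma
function. Windows with S ≥ 5 (default) are bursts. Under these defaults the
detector finds ≥ 95% of planted 200 Hz/12-spike bursts on a 5 spikes/s
background and flags ≤ 5% of homogeneous Poisson trains at S ≥ 10; detection
depends on ISIs only and is invariant to time offsets.

**Pauses.** Events are ISIs ≥ 250 ms. The pause index and pause ratio use the
classical 50 ms split (counts and summed durations of long vs short ISIs);
pause frequency is event count per summed event duration; the time and spike
proportions are relative to the recording duration and ISI count. If no ISI
is ≤ 50 ms the index/ratio are undefined (logged).

**Oscillations.** The 1 ms-binned indicator's Welch spectrum (nperseg 4096,
0.24 Hz resolution) is compared per band — delta [1,4), theta [4,8), alpha
[8,12), beta [12,30), gamma [30,100] Hz — with the 95th percentile of the
band-peak distribution over 100 ISI-shuffled surrogates (shuffling preserves
rate and ISI distribution, destroying temporal order). Flagged bands report
the observed peak frequency; peak error is < 0.2 Hz for planted 5/10/20 Hz
modulation at depth 0.8 and 60 s. Per-band false positives run at the nominal
~5% (bounded at 10% plus Monte-Carlo margin in the tests). Gates: ≥ 2 s,
≥ 50 spikes. Surrogate seeds derive deterministically from the global seed
and the unit id, so featurization is reproducible.

**Discharge classification.** A neuron is *bursting* if detected burst
density ≥ 0.1 bursts/s or ≥ 2% of spikes fall in bursts; otherwise *tonic*
if firing regularity ≥ 0.15, else *irregular*. Exactly one label holds.
Under these defaults ≥ 90% of shape-10 renewal trains are tonic and ≥ 80% of
Poisson trains irregular (a few percent of genuinely cluster-bearing Poisson
trains are called bursting — an irreducible property of the surprise
statistic at S_min = 5).

## Synthetic cohorts

The generator emulates intraoperative pallidal recordings under general
anesthesia. Building blocks, each a pure function of parameters + seed
(counter-based seed splitting makes cohorts order-independent):

- gamma-renewal trains (shape κ sets regularity; CV = 1/√κ);
- Poisson-placed, non-overlapping burst epochs (geometric spike counts, mean
  12; intra-burst rate 120–250 Hz) merged onto the background, with planted
  windows kept as ground truth;
- deleted-spike pause windows (Poisson placement, exponential lengths);
- sinusoidal rate modulation, by thinning for Poisson trains and by
  time-rescaling of the integrated intensity for regular renewal trains
  (both preserve the mean rate; the time-rescaling construction passes a
  KS check of the rescaled-ISI exponentiality).

Per-gene cohorts draw each neuron's regime from the gene's target fractions
of tonic/irregular/bursting discharge, its base rate from a truncated normal
around the published firing-rate mean/SD (floor 3 spikes/s), and give
oscillatory neurons shallow (depth 0.35) modulation at a band drawn
low-frequency-first (40/30/20/10% across delta/theta/alpha/beta). Choices
that matter and why:

- *Default duration 20 s* — a typical intraoperative segment length; the
  source recordings' durations are not published.
- *Regime shape bands*: tonic 10^U(0.6, 1.2); irregular 10^U(0.0, 0.12)
  (kept at or above Poisson, because sub-Poisson gamma firing is genuinely
  bursty and would leak into the bursting class); bursting background
  10^U(−0.3, 0) plus planted bursts at 0.3 bursts/s, with the base rate
  reduced by the expected burst contribution so the mean rate stays on
  target (within 2 SE at 200 neurons).
- *Shallow modulation* (depth 0.35) — deep sinusoidal drive concentrates
  spikes into periodic clusters that the surprise detector rightly calls
  bursts, which would contaminate the planted discharge fractions.
- *Per-gene fractions* (`data/gene_fractions_synthetic.csv`) are constructed,
  not published: they encode the cohort's reported qualitative constraints
  (which genes are tonicity-rich, which exceed 30% bursting, the reported
  oscillatory percentages) *plus* the reported significance structure — the
  bursting-rich block is significantly above every remaining gene — which
  requires the planted blocks to be separated beyond sampling and
  classification noise at ~150 neurons/gene.

What the synthetic cohorts do not reproduce: recording noise and sorting
errors, non-stationary anesthesia depth, within-patient correlation of
neurons, GPi/GPe differences, and realistic joint distributions of all 28
metrics (only firing rate and regime structure are calibrated). Passing
tests therefore establish that the *pipeline* recovers planted structure at
cohort scale, not that real data contain that structure.

## Statistics

Continuous features: Kruskal–Wallis across the nine genes, Holm-corrected
over the feature family; Mann–Whitney U for the 36 gene pairs, Holm-corrected
within each feature's pairwise family (families chosen to match how the
results are presented; whether the source corrected across features, pairs,
or both jointly is not stated). Binary flags: omnibus 9×2 chi-square with
Cramér's v, pairwise Fisher exact with odds ratios. Effect sizes are attached
only when the corrected p ≤ 0.05; the omnibus Cohen's d is taken between the
two extreme-median genes (a single d needs a two-group reduction, and the
extremes mirror the group-contrast narrative). Undefined cells are excluded
listwise per feature. Holm and Benjamini–Hochberg go through statsmodels and
are verified against brute-force definitions by property tests.

Stratification: the one-sided Fisher alternative is always "the
lower-fraction gene has the smaller proportion". Groups form greedily over
fraction-sorted genes; a gene starts a new group when it is FDR-significantly
above every member of the current group (deterministic; a significance
pattern contradicting the ordering is flagged non-transitive). The boundary
threshold raises k_low by 1 per step at fixed n_low, testing uncorrected
within the trace (correction applies across the partition's pair family, not
inside the scan), and reports the first non-significant fraction; the
convention is recorded in the estimate's metadata. The headline threshold is
taken at the boundary below the top (phenomenon-rich) group. The p-trace is
non-decreasing in k_low (checked numerically over a grid).

Jensen–Shannon distances use 30 equal-width bins over the pooled 1st–99th
percentile range shared across genes, base-2 logs (distance in [0, 1]),
genes with < 5 defined neurons excluded per feature; per-feature matrices
are summed (sum vs mean is a pure rescaling for UPGMA topology). UPGMA is
implemented directly (lexicographic tie-breaks, ultrametric heights = half
the average between-cluster distance, Newick output) and is cross-checked
against scipy average-linkage and a brute-force reference in the tests.

PCA: undefined cells are imputed as 0 *and* the binary phenomenon flags are
included as features, so absence is explicitly encoded rather than silently
averaged; features are z-scored, constants dropped. The high-loading set
applies the 0.5 cut to correlation loadings (eigenvectors scaled by component
standard deviations) — on orthonormal eigenvectors the cut would select
nothing once the feature count grows. Pairwise separability is the
Calinski–Harabasz score on PC1–PC2 with k = 2 (infinite when the within-group
dispersion is exactly zero).

Clinical: percent change = 100·(post − pre)/pre on BFMDRS-M scores; group
medians (the median, not the mean, reproduces the printed −13.6%/−51.6%
contrast from the packaged table); one-sided exact Mann–Whitney U (H1: the
tonic-gene group improves less; both groups are under n = 30, so the exact
null is the default, and the asymptotic variant agrees to 0.001 here).
Spearman correlations use label-permutation p values
(1 + #{|ρ_perm| ≥ |ρ_obs|})/(n_perm + 1), n_perm = 10,000 by default,
BH-corrected across the correlation table.

Decoding: random forest (500 trees default, balanced class weights),
gradient boosting (0.1 learning rate, inverse-prevalence sample weights),
and their soft-voting combination, each inside a pipeline whose
standardization is fit per training fold (no leakage); stratified 5-fold CV;
prevalence-weighted AUC (ordinary AUC for two classes); OVR adds balanced
accuracy, weighted F1 and the fold-summed confusion matrix. The chance
threshold is the 95th percentile of the AUC over label-shuffle iterations
with full retraining. Hyperparameters are unpublished; the defaults above
are fixed here and exposed in `DecodeConfig`. Note that literal duplicated
feature vectors under opposite labels are *anti*-learned via twin
memorization; indistinguishability checks therefore use i.i.d. samples from
one distribution.

## Problem sizes

The test suite and acceptance script run at reduced but statistically
adequate sizes chosen once: 150 neurons/gene × 10 cohorts for stratification
recovery (the scale of the real cohort, ~190 neurons/gene), 100 neurons/gene
for decoding contrasts with 60-tree forests, 200 Poisson trains for
burst-detector specificity, 40 trains for oscillation false positives, and
60 s / depth 0.8 trains for oscillation peak accuracy.

## Known limitations

- Several per-metric definitions (regularity, burst/pause detectors, the
  oscillation significance procedure, the discharge decision rule) are
  documented stand-ins for unpublished extraction code; on the deposited
  recordings the pipeline's absolute values may deviate even where the
  qualitative structure agrees.
- The oscillation test's power at 20 s segments and depth 0.35 modulation is
  limited; realized oscillatory fractions in synthetic cohorts fall below
  the planted targets.
- Fisher-partition recovery of the bursting block requires cohort-scale
  samples; at 40–60 neurons/gene the pairwise tests lack power and the
  partition collapses to fewer groups.
- The clinical contrast rests on 8 vs 23 patients; the exact test is
  reported, but no multiplicity correction spans the three follow-up
  horizons (only the 1-year horizon is analyzed by default).
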