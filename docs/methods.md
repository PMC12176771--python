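# Methods

This note documents the models, conventions, and numerical choices behind
`gawlab`, and what its synthetic-data tests do and do not demonstrate.

## Scientific setting

Functional dysphonia impairs vocal-fold vibration without structural change,
so its assessment rests on voice quality. The auditory-perceptual RBH scale
rates Roughness, Breathiness, and overall Hoarseness H = max(R, B) on
{0, 1, 2, 3}, but is subjective and coarse. High-speed videoendoscopy (HSV,
≥ 4000 frames/s) captures true intra-cycle vocal-fold motion; segmenting the
glottis in every frame yields the glottal area waveform (GAW), a per-frame
area time series whose left/right partial waveforms follow from a midline
split. `gawlab` turns GAWs into 48 quantitative parameters, selects a
minimal-optimal subset, and trains probabilistic classifiers whose posterior
probability of the class H ≥ 2 serves as a continuous severity score
ŷ ∈ [0, 1] (0 = normal, 1 = severe hoarseness). Per-modality models
(videoendoscopic, acoustic, clinical) combine into equal-weight ensembles by
averaging ŷ.

## GAW extraction

* **Segmentation stand-in.** Synthetic frames are thresholded at a fraction
  of the frame maximum and the largest connected component is kept. This
  replaces a learned glottis segmenter, which is out of scope here; the rest
  of the pipeline only sees binary masks.
* **Midline.** The first principal axis of the glottal pixels pooled over
  all frames, anchored at their centroid. A static (not per-frame) midline
  matches a single anatomical axis and stabilizes the partial GAWs.
  Degenerate clouds (≤ 2 pixels, isotropic covariance) raise a flagged error
  rather than guessing an axis. Pixels exactly on the midline alternate
  sides by scan parity so left + right equals the total exactly.
* **Trimming.** Analyses use 250 ms of sustained phonation (1000 frames at
  4 kHz), skipping the first 100 ms of onset when the recording allows —
  the standard minimum for ≥ 20 phonation cycles at habitual pitch.
* **Cycle segmentation.** A global F0 is the autocorrelation-peak lag of the
  mean-removed total GAW inside a 50–500 Hz search range. Oscillation peaks
  are found on a lightly smoothed copy (window T0/8), constrained to be
  ≥ 0.6 T0 apart and above mid-range so noise bumps on the closed-phase
  plateau are not mistaken for cycles. Cycles run minimum-to-minimum:
  closure instants are the sharpest landmarks of a GAW. Each boundary is the
  first sample attaining the raw minimum between adjacent peaks; a minimum
  on the final sample is treated as the (exclusive) record end so a signal
  ending exactly at closure keeps its last full cycle.

  *Known limitation:* when the closed phase is long, flat, and noisy, the
  closure instant is intrinsically ambiguous; boundary placement then
  wanders across the plateau and inflates the period-perturbation measures
  above their configured levels. This mirrors real GAW analysis and is why
  those measures are validated on noiseless input against generator truth.

## The 48 glottal parameters

The canonical order and names are in `gawlab.features.FEATURE_NAMES`; the
same order is the CSV schema. The cited literature defines these quantities
by name with varying formulations; the forms implemented here are normative
for this package:

* **Fundamental frequency** — per-cycle f_i = 1/T_i, mean and sample std
  (n − 1 denominator everywhere).
* **Perturbation** — mJit = mean |T_{i+1} − T_i| (s); PVI = 100·mJit /
  mean T; TP_i = min/max of consecutive periods; mShim = mean
  |A_{i+1} − A_i| / mean A; AVI = 100·mShim; AP_i = min/max of consecutive
  amplitudes; EPF = mean |E_{i+1} − E_i| / mean E with E_i the within-cycle
  energy Σ a[n]².
* **Glottal dynamics** — per cycle, the open phase is where the area exceeds
  cycle min + 5% of the cycle range (the baseline fraction is
  configurable); opening runs to the cycle maximum and closing from it.
  OQ/CQ are cycle fractions, SQ = opening/closing, PQ the fraction above
  90% of the range, GAI = mean/max, GGI = min/max (incomplete closure).
* **Mechanical** — ALR_i = A_i / glottal length; STF_i = mean |dA/dt| / A_i;
  AQ_i = A_i / max |dA/dt| in the closing phase. The glottal length is the
  97.5th-percentile per-frame extent along the midline when masks are
  available and must be supplied for GAW-only input.
* **Symmetry** — PA_i is the signed left-minus-right peak-time offset as a
  cycle fraction wrapped to [−0.5, 0.5]; PAI_i = |lag| / T_i at the maximum
  of the circular normalized cross-correlation of the two half-waveforms.
* **Noise** — computed on the mean-removed, peak-normalized total GAW. CPM
  is the cepstral peak in the quefrency band of the F0 range (cepstrum of
  the dB spectrum); CPPS averages, over 256-sample frames (hop 64) smoothed
  across 5 frames and 11 quefrency bins, the cepstral peak height above a
  linear quefrency regression. HI is the spectral-energy fraction within
  ±1 DFT bin of the harmonics k·F0 (bandwidth configurable); HNR the dB
  ratio of harmonic to non-harmonic energy. WMC is the maximum circular
  normalized cross-correlation between consecutive cycles resampled to 100
  points. NNE and SNR are per-window (5 cycles, 50% hop) noise-to-total and
  harmonic-to-noise dB ratios; their std is across windows. SF is the
  geometric/arithmetic mean ratio of the Welch power spectrum (256-sample
  segments), whose averaging makes white noise read ≈ 1 rather than the
  single-periodogram value e^{−γ}.
* **Nyquist-plane** — the analytic signal (FFT Hilbert transform of the full
  normalized GAW) embeds each cycle as a closed orbit. TC_i = 1 − RMS
  distance from the pointwise mean orbit after per-cycle centering,
  normalization, and resampling to 100 points (clipped to [0, 1]);
  WTV_i = std/mean of the radial coordinate along the *raw* cycle samples —
  resampling is deliberately not applied here because linear interpolation
  adds chord ripple to a perfect circle, which would make a pure sinusoid
  read nonzero.

Numerical conventions: denominators are guarded at machine scale (1e−12);
WMC is clipped at 1 against FFT round-off; constant signals, zero-range
cycles, and windows longer than the signal raise typed errors annotated
with the feature family.

## Synthetic data

The generators define the conditions every stage is tested under.

* **GAW synthesis.** Periods T_i = (1/f0)(1 + jitter·ε_i) and peak areas
  A_i = amplitude(1 + shimmer·η_i), ε, η standard normal, one interleaved
  pair per cycle so sweeps share common random numbers. Each cycle holds a
  closed phase at gap·amplitude followed by a squared-sine pulse whose
  rise/fall split is the speed ratio (so SQ is controlled directly); the
  closed-first layout puts closure minima exactly at cycle starts, making
  detection sample-exact on noiseless input. Intra-cycle phase comes from
  integer sample offsets, so equal-period cycles are bit-identical and the
  zero-perturbation fixed points (mJit = PVI = mShim = EPF = 0,
  TP = AP = WMC = 1) hold exactly. Left and right halves are circularly
  shifted by ±phase_lag/2 of a period; white Gaussian noise scaled to the
  target SNR is added per side (the optical/segmentation noise of real
  recordings has no documented spectrum, so white is the minimal choice),
  halves are clipped at zero and recombined.
* **Mask rendering.** A lens (elongated ellipse, default 6:1) rasterized by
  selecting whole tie-groups of pixels in order of anisotropic radius until
  the count is nearest round(a[n]); symmetric tie-groups keep the two half
  areas exactly equal at rotation 0, and the count deviation is bounded by
  a boundary tie-group (a few pixels).
* **Cohorts.** Each subject draws an H level from the configured weights
  (default 0.4/0.3/0.2/0.1, skewed toward mild as in clinical populations)
  and a latent severity s uniform in that level's cell. The observed rating
  is H = clamp(round(3s + N(0, rater_sd))) — the simplest rater model
  consistent with the known label uncertainty — and R, B are drawn so that
  H = max(R, B). A revisit fraction of subjects (default 0.1) contributes a
  second visit at s shifted by N(0, 0.3), feeding the paired-change
  analysis. Modality blocks read s through independent block latents
  (sd 0.15), so the blocks carry partially independent information — the
  premise of ensemble gains. Within the glottal block, the five informative
  features (WTV_mean, NNE_std, HI, GGI_std, CQ_std — the clinically
  selected set) each read severity through their *own* channel latent
  (sd 0.18) plus small measurement noise: they are complementary
  characterizations of vocal-fold irregularity, not copies; the remaining
  43 columns are noise, including three highly correlated pairs that
  exercise redundancy pruning. The clinical block draws VHI monotone in s
  and constructs VRQOL by regression on the realized VHI with residual
  variance chosen in closed form to hit the target Pearson correlation
  (default −0.949, the value observed on paired questionnaires); VHI/VRQOL
  are left unclipped so the coupling is exact in expectation. Fast mode
  draws feature columns directly from these links; full mode synthesizes a
  GAW per visit (and, in mask mode, routes it through rendered frames)
  before feature extraction.

What passing tests show — and do not. The generator emulates the
*statistical structure* of the study data: severity-graded perturbation,
incomplete closure, asymmetry, noise, inter-block redundancy, repeat
visits, rater noise. It does not emulate camera motion, segmentation
artifacts, non-white noise, rater drift, or the real feature-to-severity
link, so passing recovery and dominance tests demonstrates correctness of
the algorithms under known ground truth, not clinical performance.

## Cohort handling

Labels binarize at H ≥ 2 (moderate/severe). Missing VRQOL is imputed by
ordinary least squares on the VHI fitted on complete pairs. The hold-out
split reserves every multi-visit subject for the test set (their ordered
visit pairs feed the change analysis), then greedily tops the test set up
toward a uniform H histogram, always taking the currently most
under-represented level among the remaining single-visit subjects and
substituting H = 2 when H = 3 is exhausted; subjects are never split across
sets. The greedy rule is this package's operationalization of "as even as
possible" — no reference algorithm exists.

## Feature selection

Omnibus Kruskal–Wallis across H levels screens at p ≤ 0.05 (non-parametric,
since the features are not normal across levels). Relevance is the mean of
four min-max-normalized scores: the KW statistic, ReliefF (k = 10
neighbors, Manhattan distance on min-max-scaled features, multiclass miss
weighting by class priors), |Spearman ρ(feature, H)|, and mutual
information after equal-frequency 10-bin discretization. The degenerate
normalization (all scores equal) maps every feature to 1. Redundancy
pruning groups features by connected components of the |Spearman ρ| ≥ 0.9
graph and keeps the most relevant member per group (ties lexicographic);
truncation keeps the top 10. The embedded stage ranks by |standardized
coefficients| (linear models) or total information-gain importance
(gradient-boosted trees) and grows prefixes of that ranking while the mean
negative log loss over a seeded stratified 5-fold CV still improves,
stopping at the first non-improvement. CV folds are stratified by the
binary label at visit level (subject grouping inside the wrapper was left
open by the source material; visit-level stratification was chosen and is
noted here).

## Modeling

The roster spans logistic regression, linear/RBF SVMs (Platt-calibrated
probabilities), a decision tree, AdaBoost, LogitBoost (gradient boosting
with log loss on decision stumps), and XGBoost-, LightGBM-, and
HistGradientBoosting-based gradient-boosted trees. All training
standardizes with the training mean/std (also for trees — harmless and
uniform), weights classes by w_k = n/(2 n_k), and chooses hyperparameters
by exhaustive search over small declared grids on an inner stratified
3-fold CV minimizing mean log loss (ties keep the earlier grid point).
The outer evaluation is a seeded stratified 5-fold CV in which
standardization and grid search see only the fold's training rows; every
visit receives exactly one out-of-sample ŷ, and per-fold scaler means are
retained as an audit trail. The decision threshold is fixed at 0.5 with
ties positive. Ensembles average member probabilities with equal weights;
learned weights are deliberately out of scope.

## Evaluation

Accuracy/sensitivity/specificity come from explicit confusion counts with
sensitivity on the positive class H ≥ 2. AUC uses the rank (Mann–Whitney)
formulation with average-rank tie handling. Severity correlation is
Spearman ρ(ŷ, H); the paired-change analysis correlates Δŷ with ΔH over a
subject's ordered visit pairs and requires ≥ 3 pairs. Confidence intervals
are percentile bootstrap (default 10,000 visit-level resamples, 95%),
redrawing resamples that lose a class; the percentile method was chosen
over BCa since only the resample count and level are prescribed.
Correlations undefined by zero variance are reported as flagged NaNs.

## Problem sizes

The test suite runs the selection-recovery sweep at 50 seeded cohorts of
400 visits, the ensemble-dominance sweep at 30 seeded cohorts of 500
visits, and the end-to-end pipeline at ~400 visits — sizes at which the
planted effects are comfortably detectable while the whole suite stays
fast on a single CPU. The acceptance script regenerates a 250 ms GAW and a
518-visit cohort, matching the sizes the reported quantities refer to.
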