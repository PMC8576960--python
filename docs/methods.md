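# Methods

This note documents the models and procedures implemented in `pafscreen`,
the defaults chosen where the underlying methods admit alternatives, and the
limits of what the synthetic experiments demonstrate.

## Signal model and delineation

A record is a single-lead ECG sample series (mV) with its sampling rate;
the reference regime is 128 Hz, 30 minutes, lead II. R-peaks are detected by
a derivative–square–moving-window-integration scheme (5–15 Hz band-pass,
150 ms integration window, peaks above 30 % of the 99th-percentile energy,
200 ms refractory period, refinement to the raw-signal maximum within
±75 ms). Detections implying instantaneous rates outside 20–300 bpm are
discarded. The detector is the conventional baseline, not a contribution;
it recovers ground-truth beat positions within ±3 samples on noiseless
synthetic records.

P-waves are delineated in a fixed window **[250, 60] ms before each R-peak**.
The baseline is the median of the window's first 20 ms; the P-peak is the
window maximum above baseline (minimum amplitude 0.02 mV); onset and offset
are the last/first crossings of 5 % of the local P amplitude on either side
of the peak. Beats whose window leaves the record (or sits within 300 ms of
a record boundary), or whose P-wave is too small or truncated, are dropped —
never imputed. Per-beat PW/PA/PD are aggregated to the subject level by the
**median**, for robustness against occasional delineation outliers. These
window and threshold choices are deterministic implementation policy; they
are exposed in the configuration.

## Gaussian P-wave fitting by HTGA

Each baseline-subtracted P-wave segment (D ≥ 4 points) is fitted with
y(i) = A·exp(−((i−C)/W)²), i = 1…D (1-based sample coordinates), by
minimising the sum of squared errors. The optimiser is a hybrid
Taguchi-genetic algorithm:

* population 50, 100 generations, crossover rate 0.8, mutation rate 0.1,
  binary tournament selection — conventional GA settings, all
  config-overridable;
* **Taguchi crossover**: for each mating pair the rows of the L4(2³)
  orthogonal array (levels: parent 1's vs parent 2's gene per factor) are
  evaluated; each row's SSE maps to a signal-to-noise ratio
  η = −10·log₁₀(SSE + 10⁻¹²) (the ε guards log 0 at perfect fits); each
  factor takes the level with the larger mean η, ties keeping parent 1's
  gene;
* per-gene Gaussian perturbation mutation (sd = 10 % of the bound range,
  clipped to bounds) and elitism (the incumbent best replaces the worst
  child each generation), so the best-ever SSE is non-increasing;
* default search bounds per segment: A ∈ [0, 2·max|value|], C ∈ [1, D],
  W ∈ [0.5, D].

Determinism is guaranteed under a fixed seed. On noiseless synthetic
segments the fitter recovers (A, C, W) with median relative error well below
2 % and never exceeds 1.05× the minimum of a 21³ grid search over the same
bounds (both are standing tests). A note on the crossover operator: the
SNR-selected child is *not* guaranteed to be the best of the 2³ possible
factor combinations; measured against brute force it is the best or
second-best in ≳70 % of random parent pairs and in the top half in ≳95 % —
the population-level search, not the single crossover, delivers the global
fit. Raw (not amplitude-normalised) P-waves are fitted. Within the
per-subject pipeline the fit is applied to an evenly spaced subsample of at
most 30 beats (config `max_fitted_beats`) and aggregated by the median,
matching the delineation policy; this keeps a 100-subject study at
30-minute records to minutes of compute while the median is already stable
at that many beats per subject.

## HRV parameters

All statistics use the sample (n−1) variance convention.

**Time domain** — mean RR, SDNN, mean/SD of instantaneous HR
(60000/RR), MinHR/MaxHR as the min/max of *per-minute-windowed* mean HR
(instantaneous extremes for records under 1 min), RMSSD, NN50
(|ΔRR| > 50 ms), pNN50 with the successive-difference-pair denominator
(n−1; the "all intervals" convention is a config switch), and the geometric
measures on an RR histogram with bin width 1/128 s = 7.8125 ms (the sampling
resolution; configurable): triangular index = N / mode height, and TINN by
exhaustive search over triangle base endpoints on the bin grid minimising
squared error against the histogram, ties toward the narrower base.

**Frequency domain** — the RR tachogram (interval value anchored at the time
of the terminating beat) is cubic-spline resampled at 4 Hz, mean-removed and
estimated by (a) Welch: Hann window, 256-sample (64 s) segments, 50 %
overlap, per-segment mean detrend; and (b) Burg AR of order 16
(`statsmodels` Burg estimator). Band powers integrate the PSD by the
trapezoidal rule with interpolated band edges over VLF 0–0.04, LF 0.04–0.15,
HF 0.15–0.4 Hz. TP is defined as the power over [0, 0.4] Hz (= VLF+LF+HF),
which makes nLF = LF/(TP−VLF) and nHF = HF/(TP−VLF) sum to one by
construction. The feature table uses the Welch estimate by default
(config-selectable); LF/HF with zero HF power is reported missing (NaN),
never infinite.

**Nonlinear** — Poincaré SD1/SD2 from the 45°-rotated lag-1 return map
(SD1² + SD2² equals the total pair variance exactly); ApEn (Pincus,
self-matches included) and SampEn (Richman–Moorman, self-matches excluded)
with m = 2 and r = 0.2·SDNN of the analysed series, Chebyshev distance; DFA
by integrating the mean-centred series, least-squares line detrending per
non-overlapping box, α1 over boxes of 4–16 beats and α2 over 16–64 beats.
Both entropies are verified against naive O(n²) double-loop implementations
to 1e−9. Note that α1 over 4–16-beat boxes carries the well-known small-box
upward bias: for white noise at n = 2000 the per-seed estimate spans roughly
0.55–0.60 (mean ≈ 0.585), so sanity checks on α1 are asserted on the
across-seed mean.

## Feature vector

31 named slots in a fixed canonical order (PW, PA, PD, A, C, W, then the 11
time-domain, 7 frequency-domain and 7 nonlinear parameters). Missing values
— e.g. the six P-wave slots on a record whose P-waves cannot be delineated —
are carried as NaN, never silently zeroed. Imputation happens only inside
cross-validation: per-feature medians fitted on the training folds and
applied to both folds, so the held-out fold never leaks into the imputer.

## Ensembles

Base learner: a CART tree with cost-complexity pruning; the complexity
parameter (default 0.1, 100 members) maps to scikit-learn's `ccp_alpha`.
(In rpart semantics cp is the pruning α normalised by the root-node risk;
the two agree up to that scale factor — either way the default prunes
aggressively, yielding shallow, diverse members.) Trees are scale-invariant,
so no feature scaling is applied; the logistic meta-learner sees layer-1
scores in [0, 1], which need none either.

* **Bagging** — bootstrap resample of size n per member; a member whose
  accuracy on its own resample is ≤ 0.5 is discarded and redrawn (up to 50
  redraws, then a training error). Majority vote; the PAF vote fraction is
  the score; ties break toward PAF (screening favours sensitivity).
* **AdaBoost** (M1-style completion of the weighted-bootstrap recipe) —
  uniform initial weights; per round, a weighted bootstrap resample trains a
  member whose *weighted* accuracy on the full training set must exceed 0.5
  (same redraw budget); with weighted error ε the correct samples' weights
  are multiplied by β = ε/(1−ε) and renormalised to sum 1; the member votes
  with weight log(1/β). A perfect member (ε = 0) has β floored at 1e−10 so
  its vote weight is large but finite and training continues. Single-class
  resamples are redrawn. On signal-free data the weight distribution can
  become adversarial enough that no resample beats 0.5 within the budget; the
  weights are then reset to uniform (the standard resampling-boosting
  fallback) and the budget granted once more before a training error is
  raised; the reset count is recorded in the model diagnostics.
* **Stacking** — layer-1 set {bagging, adaboost} by default (config-driven);
  their scores feed a logistic-regression meta-model. The meta-model is
  trained on **out-of-fold** layer-1 scores (stratified 5-fold) to avoid
  target leakage; a naive in-sample variant is available behind a config
  flag. Final layer-1 models are refit on all training data. Meta
  probability ≥ 0.5 predicts PAF.

All three trainers are bit-reproducible under a fixed seed. Trained models
serialise to joblib bundles (members, weights, meta coefficients).

## Evaluation

Stratified tenfold cross-validation under a fixed seed (fold count reduced
with a warning when a class has fewer than 10 subjects). Metrics are
computed on the confusion matrix **pooled across folds** — with a
100-subject cohort this matches the two-decimal granularity of a published
comparison table better than per-fold averaging — and per-fold accuracies
are reported for transparency. AUROC is the normalised Mann–Whitney U on the
pooled held-out scores (ties get half credit), equivalent to trapezoidal
integration of the ROC curve. F1 is computed under both conventions:
positive-class (harmonic mean of PPV and sensitivity) and negative-class
(harmonic mean of NPV and specificity); the headline `F1` column follows the
negative-class convention used by the comparison table this package
reproduces, and both are always reported.

## Synthetic data: what it does and does not show

The generator renders each beat as parameterised bumps: the P-wave is an
*exact* Gaussian (so the HTGA stage has analytic ground truth), the QRS a
tall narrow peak with small negative Q/S lobes, the T a wide low Gaussian;
the R-peak sits 300 ms into each beat, the P centre 160 ms before the R,
inside the delineation search window. RR structure is
mean + LF (0.1 Hz) + HF (0.25 Hz) sinusoids + AR(1) noise (φ = 0.9), with a
"shuffle fraction" that permutes part of the noise, raising entropy and
flattening serial correlation without changing the amplitude distribution.
Additive white measurement noise has sd 0.01 mV.

The frozen default study conditions are two cohorts of 50 subjects, 128 Hz,
1800 s records. The PAF class has lower/wider P-waves
(amplitude 0.10 ± 0.02 vs 0.15 ± 0.02 mV; width parameter 33 ± 4 vs
24 ± 3 ms), shorter mean RR (820 ± 40 vs 900 ± 40 ms), an LF-shifted
spectral balance (LF 45 ± 8 vs 30 ± 6 ms; HF 18 ± 5 vs 35 ± 6 ms), larger
erratic variability (AR noise 32 ± 6 vs 18 ± 4 ms) and shuffle fraction 0.5
vs 0 — a stylised rendering of atrial-substrate and autonomic signatures
described in the PAF-screening literature, with effect sizes around 1.5–2
between-subject standard deviations. These values are part of the package's
versioned conditions; changing them is a breaking change to the test suite.

Passing the end-to-end tests on this cohort demonstrates that the pipeline
*as wired* — delineation through ensembles through cross-validation —
detects class structure of this kind and size without leakage, and that a
null cohort (identical class distributions) yields chance-level accuracy.
It does **not** demonstrate clinical performance: real inter-episode PAF
ECG has biphasic and notched P-waves, ectopy, artefacts, non-stationary
autonomic tone and far messier class overlap than the generator produces.
Running on real WFDB records is supported but unvalidated here.

## Numerical and degenerate-input policy

* Zero-variance series: entropies are 0 by convention; Poincaré ratio and
  LF/HF with zero denominators are NaN (missing), never ±inf.
* SampEn with zero m- or (m+1)-length match counts is NaN (undefined).
* The AR spectrum clips numerically negative PSD values at 0.
* Fiducial ordering (onset < peak < offset < R) is enforced structurally.
* All randomness flows from explicit integer seeds; stage seeds are derived
  deterministically (subject seeds via CRC32 of the subject id, kept < 2³¹).

## Known limitations

* The QRS detector and delineator are tuned for clean, upright-P,
  lead-II-like morphology; inverted or biphasic P-waves are out of scope.
* Single-Gaussian P model only; no multi-Gaussian/biphasic fitting, and no
  gradient polish after the HTGA.
* No ectopy/artefact rejection beyond delineation-stage beat dropping.
* AR spectral decomposition into per-pole component powers, Lomb–Scargle of
  the uneven RR series, SDANN-type windowed statistics, multiscale entropy
  and feature-importance analysis are all out of scope.
* WFDB support covers single-segment records, formats 16 and 212, all
  channels in one signal file.
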