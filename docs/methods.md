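# Methods

## Problem and pipeline

`phasesleep` quantifies how inter-channel phase coupling in scalp EEG changes
across wakefulness (W) and the NREM sleep stages (N1, N2, N3), and how much
sleep-stage information those coupling patterns carry. The pipeline is:

1. **Preprocess** — average reference; zero-phase Butterworth band-pass into
   four gapped bands (delta 1–3.5, theta 4.5–7, alpha 8–12, beta 13–30 Hz);
   Hilbert analytic signal on the whole continuous stage segment; cut into
   non-overlapping 10 s epochs.
2. **Connectivity** — six phase-coupling metrics (COH, iCOH, PLV, ciPLV,
   PLI, wPLI) per channel pair, epoch and band, assembled into symmetric
   matrices and band-major feature vectors (4 × C(n,2) entries; 1740 for the
   30-channel montage).
3. **Statistics** — one value per subject and stage (grand mean over pairs
   and epochs) enters a Friedman test per metric × band (24 tests,
   Bonferroni α = 0.05/24 ≈ 0.00208), with Nemenyi post-hoc pairwise
   comparisons gated on omnibus significance. A Shapiro–Wilk screen
   motivates the nonparametric route.
4. **Classification** — per metric, gradient-boosted trees classify the
   stage of each 10 s epoch under subject-wise 80/20 splits (default 30
   splits, 11 train / 3 test of 14 subjects), tuned by grid search with
   subject-grouped 5-fold cross-validation. Accuracies, confusion matrices
   and normalised feature importances are aggregated over splits; a one-way
   ANOVA with Tukey HSD compares metrics.

## Metric definitions and conventions

All metrics are time averages ⟨·⟩ over one 10 s epoch of functionals of the
per-sample cross spectrum `S_ij(t) = A_i A_j exp(+i(φ_i − φ_j))` between
analytic signals:

| metric | definition | sensitive to |
|---|---|---|
| COH | \|⟨S_ij⟩\| / √(⟨S_ii⟩⟨S_jj⟩) | amplitude + zero lag |
| iCOH | Im(⟨S_ij⟩ / √(⟨S_ii⟩⟨S_jj⟩)) | amplitude, lag only |
| PLV | \|⟨e^{iΔφ}⟩\| | zero lag, phase only |
| ciPLV | \|⟨Im e^{iΔφ}⟩\| / √(1 − ⟨Re e^{iΔφ}⟩²) | lag only, phase only |
| PLI | \|⟨sign Im S_ij⟩\| | lag sign |
| wPLI | \|⟨Im S_ij⟩\| / ⟨\|Im S_ij\|⟩ | lag, noise-robust |

Conventions (all documented choices, not the only defensible ones):

- **Cross-spectrum sign**: the exponent carries +i(φ_i − φ_j); a channel
  leading by a quarter cycle gives iCOH = +1. Only iCOH's sign depends on
  this. Feature vectors keep the signed iCOH (information-preserving); its
  symmetric matrix mirrors the i<j value.
- **Degenerate inputs**: sign(0) = 0 in PLI, with |Im S| below 10⁻¹² of
  the pair's mean |S| counted as zero (zero-lag coupling leaves
  floating-point residue whose sign is noise); a vanishing denominator in
  wPLI or ciPLV yields 0 (continuous limit of the noise-free zero-lag
  case); zero-power channels give NaN with a warning. Samples with zero
  analytic amplitude are excluded from phase metrics; epochs with more than
  1% such samples are dropped from feature tables.
- **Filtering**: the band-pass is designed by `scipy.signal.butter` with
  order 6 (six poles per band edge) and applied forward–backward
  (`sosfiltfilt`), so the effective magnitude response is squared and the
  net group delay is zero.
- **Analytic signal**: Hilbert transform over the full continuous segment
  (FFT length padded to the next fast size), phase wrapped to (−π, π].
- **Edge handling**: each synthetic segment carries a 2 s pad at both ends
  that the preprocessing chain trims after filter + Hilbert, so transients
  never enter an epoch while the nominal duration still yields
  `floor(duration / 10)` epochs. For unpadded external data an explicit
  trim shortens the epoched duration instead.

## Synthetic cohort generator

The generator reproduces the statistical structure the analysis assumes —
not biophysics. Per stage and band, a narrowband common source (band-passed
Gaussian noise, so coupling is graded rather than saturating at 1) is mixed
into every channel of a schematic 2-D 30-label 10-10 montage with
distance-decaying, **dipolar** (signed) lead-field weights; each channel
receives the source rotated by a per-channel phase lag; independent 1/f
noise is added per channel; N2 receives ~1 s sigma-band (13–15 Hz) bursts
shared across channels, emulating sleep spindles.

Key parameters (defaults in parentheses):

- `coupling_strength[band]` ∈ [0,1]: mixing weight of the band's source.
  Stage defaults encode alpha falling with sleep depth
  (0.80/0.50/0.30/0.15 for W/N1/N2/N3), delta rising (0.10/0.25/0.50/0.80),
  beta raised in N2 via bursts; theta a weak flat background.
- `source_gain` (3.0): amplitude of a fully-coupled source relative to the
  unit-SD channel noise; chosen so that default-stage coupling produces
  pair-mean PLV well above, but not saturating, the 10 s null level.
- `source_lag[band]` (propagation-like, up to `lag_scale` = 0.6 rad,
  proportional to distance from the source): nonzero lags give the
  lag-sensitive metrics (iCOH, ciPLV, PLI, wPLI) genuine signal; setting
  all lags to zero reproduces a pure volume-conduction scenario in which
  only COH and PLV respond.
- `mixing` ("dipolar"): signed lead field. The dipolar pattern matters:
  with same-sign weights the source is mostly common-mode and average
  referencing would cancel it, as it cancels any common-mode signal.
  A "uniform" mode (identical source into every channel) exists for
  controlled tests.
- `coupling_jitter_sd` (0.10): per-subject truncated-normal multiplicative
  jitter of coupling strengths, giving the between-subject variance that
  makes subject-wise splits meaningful.
- `burst_rate` (4/min in N2), `burst_amplitude` (2.0), `noise_sd` (1.0).
- Cohort defaults: 14 subjects × 4 stages, 200 s segments (or the
  reference per-subject length table, 56 segments totalling 11376 s),
  250 Hz, 30 channels.

What the generator does **not** emulate: realistic K-complex/vertex-wave
morphology, EOG/EMG contamination, non-stationarity within a stage
segment, realistic volume-conduction lead fields, or inter-channel noise
correlation. Passing tests therefore demonstrate that the pipeline
recovers the coupling structure it is designed to measure — not that real
sleep EEG behaves like the surrogate.

## Statistical choices

- Friedman omnibus per metric × band on the 14 × 4 subject-stage table,
  average-rank tie handling (scipy); constant tables return χ² = 0, p = 1.
- Nemenyi post-hoc from the studentized-range distribution
  (`q = |R_a − R_b| / √(k(k+1)/6n)`, `p = P(Q_{k,∞} > q√2)`), computed from
  the distribution function rather than a critical-value table, and only
  when the omnibus test passes the Bonferroni-adjusted threshold.
- Bonferroni denominator = number of (metric, band) tables analysed (24 in
  the full analysis).
- Metric comparison: one-way ANOVA over the split × metric accuracy table
  plus Tukey HSD.

## Classifier choices

- Learner: `sklearn.ensemble.GradientBoostingClassifier`, treated as a
  black box with a fixed seed; importances are the impurity-based ones,
  renormalised to sum to 1.
- Full grid: learning rate {0.005, 0.01, 0.05, 0.1, 0.15} × estimators
  {250, 500, 750, 1000, 1250, 1500} × depth {3–7} = 150 combinations.
  The reduced grid (default for routine runs) is 3 cheap shallow
  configurations {(0.1, 100, 3), (0.05, 100, 3), (0.1, 200, 3)}; the full
  grid is opt-in because of its compute cost.
- Inner CV folds are subject-grouped (`GroupKFold`), consistent with the
  subject-wise outer splits; no subject ever spans train and validation.
- Grid ties break toward the cheapest adequate model: smallest
  n_estimators, then depth, then learning rate.
- The 30 outer test sets are drawn uniformly **without** replacement from
  the C(14,3) = 364 possible 3-subject test sets.
- No class re-weighting: stage segments have near-equal durations, so the
  4-class chance level is 0.25.

## Calibration and validation experiments

`phasesleep.experiments` packages the standing experiments, at sizes chosen
to keep each run in the minutes range:

- **Type-I calibration**: 200 stage-effect-free cohorts (pure 1/f noise,
  14 subjects, 3 channels, 100 s at 80 Hz) through the full feature
  pipeline; the share of significant Bonferroni-gated omnibus tests must
  stay ≤ 0.05.
- **High-contrast classification**: default stage structure with
  `source_gain` 4 and 5% jitter, 8 subjects × 8 channels × 100 s at
  100 Hz, 5 subject-wise splits with the reduced grid — the regime where
  near-perfect stage recovery is expected (observed mean accuracy ≈ 0.99).
- **Chance level**: labels permuted across epochs, 20 permutations with
  fixed shallow hyperparameters — mean held-out accuracy 0.25 ± 0.05.
- **Alpha-contrast cohort**: only alpha coupling varies across stages
  (0.85/0.60/0.35/0.10), all other bands stage-constant — the alpha band
  must dominate aggregated feature importances.
- **Welch cross-check**: time-domain COH on a stationary narrowband
  common-source pair agrees with band-averaged Welch coherence
  (square-rooted magnitude-squared coherence) within 0.05.

## Known limitations

- The asymptotic χ² and studentized-range approximations are coarse for
  very small cohorts (n < ~8); the type-I experiment checks only that they
  are not anti-conservative at the Bonferroni threshold.
- Epoch-level feature rows from one subject are statistically dependent;
  only the subject-wise split structure (not the classifier itself)
  accounts for this.
- The EDF reader (via MNE, optional extra) imports data as-is; no artifact
  rejection or resampling is performed. EDF export is not provided; the
  internal exchange format is `.npy` + JSON sidecar.
- The 10-10 montage subset and its schematic 2-D coordinates are a declared
  package convention; real recordings may use any montage, but the
  generator's lead fields assume this one.
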