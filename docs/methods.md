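# Methods

## The task and the model

The pipeline simulates and analyzes a two-alternative phoneme
categorization experiment: on each trial a listener hears one of four
VCCV non-words (/alda/, /alga/ and their uvular-context twins) embedded
in Gaussian white noise and reports whether the second syllable was
/da/ or /ga/.  The analysis goal is the *auditory classification image*
(ACI): a time–frequency map of how noise energy at each point biases
the response, estimated per listener by reverse correlation.

The decision model is the linear observer: with `S_i` the cochleogram
of the trial-`i` stimulus (a 43 × 54 time–frequency matrix treated as a
pixel vector), the probability of answering 'ga' is

    P(r_i = 1) = logit⁻¹( ⟨S_i, β⟩ + c )

where β is the listener's spectro-temporal template (the ACI) and `c`
a response bias.  β and c are estimated by maximum a posteriori
penalized likelihood:

    min −Σ_i [ r_i log p_i + (1−r_i) log(1−p_i) ] + (λ/2) βᵀKβ

with K a smoothness penalty (below) and the bias unpenalized.

## Stimuli

Targets are produced by a parametric source–filter synthesizer: a
120 Hz pulse train with spectral tilt drives three time-varying
second-order resonators (F1–F3).  The /da/–/ga/ contrast lives in the
second-syllable formant-transition onsets — F2/F3 start at 1400/2550 Hz
for /da/ (distant onsets) and 1900/2100 Hz for /ga/ (convergent,
velar-locus onsets) — and both transition into the same /a/ steady
state (700/1200/2500 Hz) over 80 ms.  All four targets share a 680 ms
duration and a second-syllable energy onset at exactly 328 ms,
preceded by a 50 ms stop-closure silence; the closure is true silence,
so the onset is measurable from the waveform to the sample.  Waveforms
are RMS-normalized.

A stimulus at SNR s dB is `γ(t + λ_s n)` with `λ_s = 10^(−s/20)` on
RMS-normalized target and noise, and γ restoring unit RMS.  The
post-hoc SNR `20 log10(RMS(γt)/RMS(γλ_s n))` equals the request
identically.  An optional noise-only raised-cosine fade-in (50 ms
default) can be prepended for listener comfort; it is flagged and
excluded from analysis.  Noise maskers are i.i.d. Gaussian,
regenerated on demand from (seed, index) pairs rather than stored.

## Staircase

The 3-down-1-up transformed up-down rule: SNR up one step after every
error, down one step after three consecutive correct responses since
the last change.  Steps start at 2 dB each session, shrink by 10% at
every SNR change, and floor at 0.2 dB; session 1 starts at −11 dB and
later sessions resume the previous final SNR.  The fixed point is the
SNR where P(correct) = 0.5^(1/3) ≈ 79.4%.  Safety bounds of
[−40, +10] dB contain degenerate observers; a guessing observer is
driven to the ceiling, as expected of a 1-up-dominated rule at 50%
correct.  Full-length runs (20 × 500 trials) of a logistic
psychometric observer (guess rate 0.5, threshold −13 dB, slope
1 dB⁻¹) converge to 79.2–79.4% correct after a 500-trial burn-in, and
correct/error balancing of such a run retains ≈ 4,140 of 10,000
trials.

## Cochleogram front-end

A constant-Q bank of 54 second-order resonant bandpass filters
(`iirpeak`) on geometrically spaced centers from 96 to 7760 Hz,
Q = 8 (−3 dB bandwidth f/8), followed by half-wave rectification, a
2nd-order 64 Hz Butterworth envelope low-pass, power-law compression
with exponent 0.3, and averaging into 15.6 ms frames (partial trailing
frames dropped: 680 ms → 43 frames).  This is a functional cochlea
approximation; the estimation machinery depends only on the binning
grid, and the front-end sits behind a single interface so it can be
swapped.  The original analysis pipeline's cochlea model has an
"overlapping = 40%" setting whose meaning is not reconstructible from
the available description; it is recorded in the config but not
interpreted.  Scaling a waveform scales all (compressed) cochleogram
values monotonically, so pixel ordering is level-invariant.

## Estimation

* **Balancing.**  Because the staircase pins accuracy near 79%, raw
  trial sets are ~4:1 correct:error; estimating on them distorts the
  template.  Randomly chosen correct trials are discarded until counts
  match (order otherwise preserved).
* **Penalty.**  K = LᵀL + 10⁻⁶ I, with L the discrete 2-D Laplacian on
  the time–frequency grid under reflecting (Neumann) boundaries.  The
  Laplacian-squared term is the smoothness prior (data-driven low-pass
  filtering of the ACI); the tiny ridge makes K positive definite so
  the penalty-dominated limit shrinks the whole template, constant
  mode included, without affecting smoothing at working λ.
* **Solver.**  Penalized IRLS (Newton) with step-halving, so the
  penalized objective decreases monotonically.  Convergence when the
  per-trial gradient sup-norm falls below 10⁻⁶; iteration cap 200.
  Newton systems are solved three ways depending on size: densely for
  ≤ 700 pixels; by a Woodbury identity with a cached sparse
  factorization of K when trials number fewer than half the pixels
  (the common full-grid case — an n × n inner solve instead of
  p × p); by conjugate gradients otherwise.  The three paths agree to
  machine precision and the λ=0 fit matches an independent logistic
  regression (statsmodels) to better than 10⁻⁴ relative error.
* **Penalty selection.**  One shared λ for all listeners, minimizing
  the mean 10-fold cross-validated deviance across listeners on a
  log-spaced grid (default 15 points over 1–10⁶); folds are stratified
  by response; ties break toward the smoother value; a boundary
  minimum warns.  Held-out probabilities are clipped to
  [10⁻¹², 1−10⁻¹²] inside deviance.
* **Z-scoring.**  Group analyses use per-listener z-scored templates
  ((β − mean)/sd over pixels, sample sd, bias excluded).

## Simulated observers

The synthetic-data generator is the pipeline's ground truth.  Internal
noise is absorbed into the logistic via a gain parameter (higher gain
= less internal noise), so simulated responses come from exactly the
likelihood family the estimator fits.

Two simulation tiers are used, and they emulate different things:

* **Pixel-grid worlds** generate cochleogram-like stimuli directly on
  a reduced grid (smooth class means, the 'ga' mean carrying an extra
  smooth blob, isotropic pixel noise).  The operating point is
  calibrated to the published task statistics: decision-variable
  half-separation 2.17 and noise sd 2.0 give 79.4% correct — the
  staircase's fixed point — and an ideal response predictability of
  ~71% on balanced trials, bracketing the published ~69% auto-
  prediction rate.  These worlds drive the parameter-recovery,
  penalty-selection, and prediction analyses at realistic trial
  counts in seconds.
* **The audio path** runs the full chain — synthesis, mixing at the
  staircase SNR, cochleogram, linear observer.  Template projections
  of noisy mixes carry a common-mode component that varies with SNR;
  a fixed-bias observer would drift off criterion as the staircase
  moves, so pipeline observers have their templates orthogonalized
  against the mean-stimulus patterns over the staircase's working SNR
  range and their bias centered on reference mixes (criterion
  maintenance, the analogue of a listener's level normalization).
  Individual listeners are smooth random distortions of the shared
  ideal contrast template (heterogeneity = perturbation norm relative
  to the unit-norm base).

What the audio simulations do *not* emulate: the synthetic VCCV tokens
are far less discriminable per dB of broadband SNR than recorded
speech, so simulated staircases settle near 0 dB rather than the
−13 to −12 dB of human listeners.  `calibrate_gain` (bisection on
simulated accuracy) can place the observer at any attainable level,
but no linear observer on these tokens reaches 79% correct at −12 dB.
Passing tests therefore validate the procedure — staircase mechanics,
estimator correctness, statistical calibration — not the absolute SNR
operating range of human speech-in-noise perception.

## Prediction analyses

Auto- and cross-prediction use one 10-fold machinery: the training
listener's balanced trials are split into response-stratified tenths;
a model fitted on each nine-tenths is scored (deviance
−2 log-likelihood, and accuracy of the predicted-probability side of
0.5, ties counting as wrong) on the corresponding held-out partition
of the *test* listener's data; the ten values are averaged.  With
train = test this is ordinary cross-validation, so the N × N
train-by-test deviance matrix has CV auto-prediction on its diagonal
and all entries on one scale (equal balanced sizes are assumed when
comparing listeners).  Specificity of listener i is
auto_deviance(i) − mean_{j≠i} deviance(model j on data i): negative
when the own model predicts best.  Sensitivity d′ = Φ⁻¹(hit) − Φ⁻¹(fa)
and criterion −(Φ⁻¹(hit)+Φ⁻¹(fa))/2 are computed from the raw
(unbalanced) runs — balancing forces both rates to ½ — with 0/1 rates
pulled in by the 1/(2N) rule.

In simulation, a heterogeneous six-listener population gives mean
auto-prediction accuracy 0.700 against cross-prediction 0.635, all
specificities negative (−14 to −39), and d′ of 1.6–1.7 — the same
pattern and magnitudes as the published group values.

## Group statistics

* **Within-group maps:** pixelwise one-sample t against zero on the
  z-scored templates, Benjamini–Hochberg FDR mask (default q = 0.01);
  undefined-t pixels are excluded with a warning.  Null simulations
  (19 noise maps, 200 replicates) keep the significant fraction at or
  below q.
* **Between groups:** cluster-based permutation test.  Pixels with
  two-sample |t| above the two-sided α-threshold quantile (default
  0.05) form 4-connected clusters split by sign; the cluster statistic
  is the mass Σ|t|; the null is the maximum cluster mass over random
  group relabelings (default 1000); cluster p = (b+1)/(m+1) — the
  add-one exact-test convention, which keeps the test at or slightly
  below nominal level (measured type-I error ≈ 5% over 500 null
  replicates on a 12 × 12 grid).  Connectivity is configurable to
  8-neighbor.
* **Weight sets (ROIs):** pooled across all listeners, one-sample t
  per pixel, threshold p < 10⁻¹⁰, 4-connected components of ≥ 7 pixels
  kept; each annotated with size, sign of the mean weight, centroid
  and extent in ms/Hz through the grid metadata (bin centers).  A
  two-sample t-test on mean in-set weight per listener compares the
  groups per set, reported uncorrected with a Bonferroni column for
  transparency.

## Reproducibility and problem sizes

Every stochastic stage takes an explicit seed; a study run is fully
reproducible from (config, master seed), and the run manifest stores
content checksums (computed over array bytes and log text, so they are
independent of file-format timestamps).  HDF5 artifacts are written
with `track_times=False` for byte-identical files.

Simulations in the test-suite and analysis scripts run at reduced
scale as a design choice — 16 kHz audio (the 96–7760 Hz grid fits
under the Nyquist limit), hundreds of trials per listener for
end-to-end runs, reduced pixel grids for large-replicate estimator and
statistics studies — while single-quantity checks (staircase
convergence, balancing counts, timing, grid geometry) run at the full
published sizes (10,000 trials, 48 kHz, 43 × 54 grid).

## Known limitations

* The synthesizer produces stylized, fully voiced tokens; no
  aspiration burst spectrum, coarticulation detail, or natural f0
  declination.  Absolute SNR thresholds are therefore not comparable
  to human data (above).
* The front-end approximates a cochlea functionally; no adaptive gain
  control or suppression, and no attempt at bit-compatibility with
  any particular cochlea model.
* The linear observer has no attention lapses, response-time
  structure, or learning; session-resumed staircases therefore show
  none of the slow across-session drift of real listeners.
* Cross-prediction deviance assumes equal balanced table sizes across
  listeners; no per-trial normalization is applied.
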