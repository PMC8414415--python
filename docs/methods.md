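# Methods and design notes

## Scope

`mirp` studies how band-wise relative power (RP) of sensorimotor EEG
relates to motor-imagery (MI) decoding performance, across subjects and
across repeated sessions. Because suitable multi-session human datasets
are rarely shareable, the package is built around a synthetic-data
generator with explicit ground truth: every downstream stage (artifact
removal, decoding, spectral factors, statistics) is validated against
quantities the generator controls.

## Synthetic study generator

### Paradigm

Each run holds 40 cue-based trials — 10 each of left hand, right hand,
both feet, and idle, in randomized order. A trial lasts 9 s: 1 s fixation
cross, 5 s task, 3 s inter-trial rest. Sampling rate is 500 Hz. The cue
defines t = 0; fixation occupies [−1, 0) s and the task [0, 5) s. An 8-s
rest lead-in precedes the first trial so that the full −4…+5 s extraction
window exists for every trial (without it the first trial could never be
analysed).

### Montage

26 electrodes over frontocentral/centroparietal cortex (F3…P4 in the
10-10 naming), laid out on a unit disc by row and lateral index. Seven
disjoint regions group them: SMA = {FCz, Cz, CPz}, left/right PMC, M1 and
S1 as the corresponding three-electrode columns. The exact electrode set
is a documented stand-in — published montage figures rarely enumerate
labels — and is fully configurable.

### Signal model

Per channel, the signal is a 1/f background (exponent 1 by default, SD
`noise_scale` = 10 µV) plus one band-limited source per (band, region)
pair. Sources are amplitude-modulated narrowband noise — white noise
FIR-filtered into theta 4–8, alpha 8–13, beta 13–30 or gamma 30–50 Hz —
rather than sinusoids, because pure tones make CSP degenerate and give
unrealistic spectra. Each source projects to the scalp with gain 1 on its
region's electrodes and a Gaussian fall-off (σ = 0.08 disc units) with
distance to the nearest member, i.e. a smooth region-peaked profile
without full volume-conduction modelling.

Baseline band amplitudes default to theta 4, alpha 9, beta 4.5, gamma
1.5 µV (RMS of the source at its own electrodes) with per-subject
log-normal jitter (σ = 0.15). These are plausibility choices — typical
resting scalp EEG magnitudes — not fitted values.

### Task modulation (ERD and band boosts)

During the 5-s task window of an MI trial, the alpha and beta sources of
the class's motor region (left hand → right M1, right hand → left M1,
feet → SMA) are attenuated by the subject's ERD depth `d ∈ [0, 1]`
(amplitude factor `1 − d`, hence power factor `(1 − d)²`); theta and
gamma sources everywhere receive small boosts (defaults 0.15/0.25) during
MI tasks. Idle trials stay at baseline. Three jitters shape realistic
variability:

* per-session band-amplitude drift (log-SD 0.05),
* per-session multiplicative ERD jitter (log-SD 0.25) — because it is
  multiplicative, higher-ERD (better) subjects vary more across sessions,
  reproducing the positive mean–SD relationship seen in real cohorts,
* per-trial engagement jitter (N(1, 0.4), clipped at 0) scaling both the
  ERD and the boosts — attention fluctuates trial to trial.

### Ground-truth coupling

`make_cohort` draws ERD depth as a monotone map of
`coupling · rank(baseline SMA alpha RP) + (1 − coupling) · u` with
independent uniform `u`. Coupling 1 therefore gives Spearman ρ = 1
between alpha RP and ERD depth by construction, coupling 0 independence;
the default 0.8 is the documented effect size that the correlation
analysis is expected to recover. ERD depth spans [0.15, 0.6] across a
cohort.

### Artifacts

Blinks are stereotyped sub-4 Hz Gaussian bumps (~90 µV) at Poisson times
(default 10/min), added to scalp channels with a frontally-decaying gain
and recorded near-full-scale on a dedicated VEOG channel (0.3× on HEOG),
both with 3 µV sensor noise. EMG bursts (default 3/min, 0.3–1 s) are
30–100 Hz noise at ~20 µV added to the lateral-most electrodes. Ground-
truth artifact time courses are kept on the run for validation.

### What the generator does *not* emulate

No volume conduction or realistic leadfields, no ECG or line noise, no
electrode drift or impedance changes, no 1/f knee, no IAF variation, and
spatially far less source mixing than real EEG. Consequently decoding
accuracies run higher than on human recordings (roughly 55–100% rather
than 40–73% three-class); passing tests demonstrate correctness of the
estimators and recovery of injected structure, not expected effect sizes
on real data. Chance-level behaviour on the zero-information
configuration is, however, directly transferable.

## Preprocessing

* **FIR band-pass**: symmetric odd-length Hamming-window FIR (transition
  2 Hz, > 50 dB stop-band), applied with 'same'-mode convolution so the
  group delay cancels exactly; linear-phase by construction.
* **ICA-EOG**: fixed-point ICA (deflation, logcosh, fixed seed) on scalp
  channels only; each component source is correlated with each EOG
  channel and components whose |r| z-score across components exceeds 3.0
  are zeroed before back-projection. The variant of ICA, the component
  count and the threshold are conventions, chosen to mirror common
  EEG-toolbox behaviour.
* **EEMD–CCA** (per channel): ensemble empirical mode decomposition with
  complementary noise pairs — each white-noise realisation is added with
  both signs, so the ensemble-mean noise cancels and ΣIMF + residual
  reconstructs the input to ≪1% relative RMS (plain EEMD at 100 ensembles
  and 0.2·SD noise would leave ~2% residual noise). Sifting stops when
  extrema and zero-crossing counts differ by ≤1 for 3 consecutive sifts
  (max 10 IMFs, 50 sifts). CCA between the IMF matrix and its one-sample
  delay orders sources by lag-1 autocorrelation; sources below the 0.9
  threshold (broadband, EMG-like) are removed. The threshold and ensemble
  count (100) are configurable defaults from the EEMD-CCA literature, not
  fitted values.

## Decoding

Runs are band-passed to 8–30 Hz; the task window [0.5, 4.5) s (discarding
0.5 s at task start and end) is cut into four 1-s sub-epochs per trial.
One-vs-rest CSP is fitted per class (4 filters each: 2 top + 2 bottom
eigenvectors; per-epoch covariances are trace-normalized, averaged, and
ridge-stabilised with ε = 1e-8 of the mean diagonal). Features are log
variance shares; an RBF-SVM with C = 0.8 and γ = 1/(n_features · feature
variance) classifies them after per-feature standardisation. Stratified
10-fold CV is used, and CSP + scaler + SVM are re-fitted inside every
training fold — fitting CSP on all data leaks test information and
inflates accuracy; the optimistic variant remains available via
`csp_within_folds=False` for comparison. Sub-epochs of one trial may
fall into different folds; this mirrors epoch-level CV practice.

Zero-denominator precision/recall are defined as 0, so macro scores are
conservative.

## Spectral factors

Welch PSD uses non-overlapping 500-ms Hamming windows (frequency step
2 Hz; a 4-s task segment gives 8 averaged blocks). Band power is the
trapezoidal area under the density with linear interpolation at off-grid
edges (13 Hz on a 2-Hz grid), which keeps band powers exactly additive,
so four-band RP sums to 1 within 1e-9 for any input. RP is computed per
trial, then averaged trial → run → session (ratio-then-average keeps
every trial's RP in [0, 1]; the average-then-ratio alternative is not
provided a separate code path because the tables are computed per trial
throughout). Trial stages: pre-task [−3, −1) s, cross [−1, 0) s, task
[0.5, 4.5) s. A pre-task window extending to +1 s would overlap both the
cross stage and the cue; the non-overlapping reading is the default and
any other window can be passed as a `StageWindow`. The task stage is
split by task; the three MI tasks are additionally averaged into
`task_mi_mean`, the basis of ΔRP = RP(task, MI mean) − RP(pre-task).

## Statistics

* Group split: subjects sorted by mean three-class accuracy; top 8 → HP,
  bottom 8 → LP, middle excluded; boundary ties break by ascending id.
* t-maps: Welch's unequal-variance two-sample test per electrode on
  session-averaged per-subject values (a pooled-variance flag exists),
  BH-FDR over the 26-electrode family within each (band, quantity).
* Across subjects: Spearman on subject means (one point per subject).
  Across sessions: repeated-measures correlation implemented directly
  from the ANCOVA normal equations (subject dummies + common slope),
  `df = n_obs − n_subjects − 1`, two-sided p via the t equivalence; the
  implementation is cross-checked against pingouin's `rm_corr` in the
  test suite and, unlike it, accepts the minimal 2-subject case.
* Correlation grid: all 11 task combinations × {theta, alpha, gamma} ×
  both aspects (66 cells); BH-FDR applied separately within each aspect
  family of 33 tests. FDR family boundaries are a design choice —
  per-aspect families match how such grids are usually reported.
* Region factors default to SMA-averaged values; any montage region can
  be requested.

## Numerical choices and degenerate inputs

* CSP eigenvalues are clipped to [0, 1]; generalized eigenvectors are
  returned with unit composite-covariance norm (scipy's B-orthonormal
  convention).
* Covariance ridge 1e-8 × mean diagonal; rank-deficient runs should
  reduce `n_components` for ICA (a clear error is raised otherwise).
* Constant signals: EEMD returns zero IMFs and the signal as residual;
  Spearman and rmcorr raise on zero-variance inputs rather than return
  NaN; flat EOG channels are rejected.
* Epoch windows that extend past a recording are dropped with a logged
  warning, never silently truncated.
* All stochastic steps (generation, ICA, EEMD, fold shuffling) take
  explicit seeds; a run is bit-reproducible from its manifest.

## Problem sizes used in the checked examples

The packaged checks run at deliberately small scale, chosen as the
smallest sizes at which each property is identifiable: chance-level
decoding uses 2 subjects × 2 sessions × 6 runs (2 880 pooled three-class
epochs; the binomial 99% CI around chance is then ±2.3 points);
cohort-level coupling recovery uses 200 replicate cohorts of n = 20; the
end-to-end recovery check uses 20 subjects × 1 session × 2 runs. The
full default study (20 × 7 × 6) runs through the same code paths
unchanged.

## On-disk format

Runs are stored as raw little-endian float32 (channel-major) with a JSON
sidecar (channels, sampling rate, units) and a tab-separated `events.tsv`
(`onset`, `duration`, `trial_type`) in a BIDS-EEG-inspired
`sub-XX/ses-YY/run-ZZ` layout. An optional int16 mode emulates the
16-bit sample quantization of clinical EDF files; native EDF was not
adopted because no EDF writer is part of the supported dependency set and
the float-binary sidecar format round-trips exactly.

## Known limitations

* The generator's spatial model is deliberately separable; absolute
  decoding accuracies are optimistic (see above).
* EEMD is O(ensembles × sifts × n log n) per channel and is therefore a
  per-channel opt-in (`eemd_cca` flag) rather than a default stage.
* No multitaper/wavelet spectra, no IAF-individualized bands, no
  Riemannian or filter-bank decoders — all out of scope by design.
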