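# Methods

## The coupling statistic

The analysis quantifies the temporal coupling between global brain
activity and CSF inflow. The global signal g(t) is the grey-matter
average of voxel-wise z-scored BOLD time series, re-z-scored for
comparability; the CSF signal c(t) is the mean over a bottom-slice CSF
region, expressed as a fraction of its temporal mean so the inflow
polarity (signal increases when unsaturated fluid enters the slice
stack) is preserved. The cross-correlation function is

    C(τ) = corr( g(t + τ), c(t) ),   τ = k · TR,  |τ| ≤ 20 s,

with the Pearson correlation computed on the overlapping segment of each
shift (no zero padding — padding would shrink r at large lags). The lag
sign convention is fixed by the inflow mechanism: when c(t) tracks
−dg/dt for a narrowband g of period T, the minimum of C falls at
τ = +T/4. Coupling strength is C(+4 s); more negative values mean
stronger coupling. The companion statistic correlates −dg/dt with c(t)
and peaks at lag 0 under the same mechanism.

Two details are deliberate:

* **+4 s must be exactly on the lag grid.** At TR = 2 s the +4 s lag is
  two samples; the implementation refuses to interpolate between lags.
* **Derivative alignment.** The derivative cross-correlation uses a
  centred-difference derivative, which is timestamped exactly on the
  sample grid. A forward difference estimates the derivative half a
  sample late; for a narrowband signal that places the theoretical peak
  midway between lag 0 and −TR, and the measured argmax then flips
  between the two by noise. The forward-difference primitive is still
  available (`negative_derivative`, `derivative_coupling(...,
  method="forward")`).

## Preprocessing

Two divergent paths mirror standard practice for this analysis:

* **gBOLD path**: slice-timing correction → nuisance regression
  (24 motion regressors: the six realignment parameters, their
  one-volume lags, and both squared, with the lagged block zero-padded
  at the first time point; plus white-matter and CSF mean signals) →
  linear detrend → band-pass 0.01–0.1 Hz.
* **CSF path**: slice-timing correction → detrend → band-pass only.
  No nuisance regression ever touches this path — regressing out CSF
  would remove the very signal under study. Each voxel's temporal mean
  is restored after filtering so the fraction-of-mean normalization
  stays defined (the usual fMRI-toolbox convention; the standalone
  `detrend` op itself is mean-removing).

Filtering is a 4th-order Butterworth applied forward–backward
(`sosfiltfilt`), i.e. zero-phase: an in-band sinusoid emerges with its
cross-correlation peak at lag 0. This is load-bearing — any
filter-induced lag would masquerade as coupling lag. Filtered series
keep their full length (no time-point trimming; 185 volumes are few).

Nuisance regression is ordinary least squares per voxel; collinear
regressor columns are dropped with a logged warning and the residual is
orthogonal to every retained column. The WM and CSF nuisance signals
are mask means taken after slice timing, before regression.

Synthetic volumes are generated with simultaneous slice sampling, so
the composed pipelines run the slice-timing stage as an identity
(`slice_order=None`). Applying an interleaved correction to
already-aligned data would inject artificial sub-TR lags into the
coupling geometry. The operation itself supports arbitrary slice
orders via cubic-spline temporal resampling and is tested against a
closed-form phase-shift oracle.

## The synthetic cohort generator

No raw MRI is distributable for this design, so the generator produces
phantoms carrying exactly the statistical structure the analysis
assumes. What it emulates:

* **Acquisition**: TR = 2 s, 185 volumes; 64×64×36 grids are available,
  tests default to 24×24×12 (same structure, ~20× cheaper).
* **Global signal** u(t): synthesized in the frequency domain as a
  Gaussian amplitude bump (width 0.02 Hz) centred on f0 = 0.0625 Hz,
  restricted to 0.01–0.1 Hz, with uniform random phases. f0 is chosen so
  the quarter period is exactly 4 s = 2 TRs, making the +4 s lag the
  exact theoretical minimum. Width 0 degenerates to a pure sinusoid.
* **CSF signal**: c(t) = B·(1 + a·(κ·z(−du/dt) + σ_csf·ε)) with baseline
  B = 100, modulation depth a = 0.05. κ is the condition-level coupling
  gain (defaults: controls 1.0, patients pre-treatment 0.45,
  post-treatment 0.85 — ordered to reproduce the reduced-then-recovered
  coupling pattern). σ_csf = 2.5 puts the control cohort-mean coupling
  near the published whole-cohort magnitude (≈ −0.26 to −0.35) while
  keeping the κ → coupling ordering identifiable at 10 subjects per κ
  level. Negative κ is rejected: the polarity convention belongs to the
  model.
* **Phantom geometry**: ellipsoidal brain, inner WM core, GM shell split
  into four quadrant parcels standing in for the language, salience,
  dorsal-attention and default-mode networks, a ~20-voxel CSF blob on
  the lowest slice (the CSF region size is unreported in comparable
  studies; this is a free choice), and for patients a spherical
  left-hemisphere lesion (radius uniform in 4–10 mm) with attenuated,
  noisier signal (gain ×0.4, noise ×2 — the simplest mechanism that
  perturbs coupling).
* **Network gains** scale u(t) per parcel (1.0/0.9/0.8/0.7). After
  z-scoring, a gain is invisible in the signal amplitude but raises the
  parcel's SNR against voxel noise (σ_bold = 1.0 relative to the signal
  term), so higher-gain networks show stronger measured coupling.
* **Motion**: smoothed random-walk realignment traces scaled to 0.2 mm
  RMS (rotations 1/50 of that, in radians), plus a motion-locked
  artefact added to all brain voxels with the same amplitude — present
  so the 24-regressor model has something real to remove.
* **Behaviour**: WAB raw subtest scores. Baselines are truncated normals
  matching the published treated-cohort summary; the standardized change
  is d + r·z + √(1−r²)·ε where d is the per-subtest effect size
  (defaults derived from the published paired t statistics at n = 14,
  e.g. 1.35 for object naming), z the standardized coupling change of
  the linked network, and r the target association (−0.543 language
  network/object naming, −0.582 salience/responsive naming, −0.682
  dorsal-attention/sequential order). Negative r encodes "greater gains
  go with more negative coupling changes". Change SDs are sized so that
  truncation at the subtest maxima is rare (realized d stays within
  ±0.15 of the target at n = 200).
* **Tabular cohort** (`simulate_coupling_table`): draws coupling values
  directly from the condition-level model — condition means
  (−0.263/−0.191/−0.245), subject random intercept SD 0.06, residual SD
  0.057 (so the pre/post effect is d ≈ 0.67), and an age slope
  calibrated to r = 0.374 with age. It bypasses image synthesis and is
  the generator behind the statistical calibration tests.

All randomness flows from a single seed; per-subject substreams use
explicit spawn keys, so regeneration is bit-identical and adding
subjects never perturbs existing ones. Treated patients share one label
volume across their two sessions.

**What the phantoms do not emulate**: scanner physics (k-space, slice
excitation, drift), physiological recording (cardiac/respiratory
cycles), arousal-state fluctuations, spatial autocorrelation of noise,
registration error, or any real anatomy. Passing tests therefore show
that the *pipeline* recovers what the generative model encodes — not
that the physiological coupling interpretation holds in real data.

## Statistics

* **Baseline group comparison**: OLS of coupling on a patient indicator
  plus age and sex (0/1 coding, male = 1, patient = 1 — coefficient
  signs are relative to this coding).
* **Longitudinal model**: REML linear mixed model, condition fixed
  effect (control reference), subject random intercept; pairwise
  contrasts (post vs pre, post vs control, pre vs control) with Wald
  95% CIs and Holm-adjusted P values. Non-convergence falls back to
  OLS (zero random-intercept variance) with a logged warning and a
  flag in the results object.
* **Association models**: OLS of a language-score change on a network
  coupling change, adjusting for age, baseline score and lesion volume;
  the reported partial r is t/√(t²+df). FDR (Benjamini–Hochberg) is
  applied across the 4-network × 3-measure family; Holm across the
  three mixed-model contrasts — matching how each adjustment is used.
* **Partial correlation**: residual-on-residual Pearson r with
  t-based P at df = n − k − 2. Control lesion volume is set to 0 in the
  all-participants age analysis (how to handle controls there is
  unspecified in comparable work; 0 is the natural encoding of "no
  lesion").
* **Power**: exact noncentral-t power for paired tests (noncentrality
  d√n, df n − 1), smallest n meeting the target. Both tail conventions
  are exposed because published sample-size figures for such designs are
  often one-tailed; d = 1.35 at 80%/α = 0.05 gives n = 6 one-tailed,
  n = 7 two-tailed.
* Normality (Shapiro–Wilk) is reported as a diagnostic, never used to
  switch tests. P values are two-tailed throughout. Multiplicity
  adjustments delegate to `statsmodels.stats.multitest` and are verified
  in tests against exhaustive step-down/step-up oracles.

## WAB scoring

Spontaneous speech = speech fluency + information content (0–20);
comprehension = (yes/no + auditory word recognition + sequential
order)/20; repetition = raw/10; naming = (object naming + word fluency +
sentence completion + responsive naming)/10;
AQ = 2 × (spontaneous + comprehension + repetition + naming), 0–100.
All weights and denominators are configurable because translated WAB
adaptations scale some domains differently — and indeed the published
comprehension and naming domain means do not exactly equal the standard
weighted sums of the printed subtest means, so only the repetition,
spontaneous and AQ arithmetic (which verify exactly) are asserted
against the published table. Scores are carried at full precision;
printed-rounding tolerances (±0.02–0.05) appear only in tests.

## Problem sizes and numerical choices

Tests and the acceptance script run the imaging pipeline at the
24×24×12 grid with 185 volumes: 20 subjects for the lag-geometry check,
5 κ levels × 10 subjects for the recovery sweep, 100 tabular replicates
for mixed-model CI coverage, 500 replicates for null calibration, and
50 000 Monte-Carlo replicates for the power cross-check — sizes at
which each property is comfortably identifiable. Collinearity is
handled by pivoted-QR column dropping (tolerance 1e-10 relative);
zero-variance voxels are excluded from extraction with a logged count;
cross-correlation lags with fewer than 3 overlapping samples are
omitted with a warning, and zero-variance overlaps yield NaN rather
than a fabricated r.

## Limitations

* The generative CSF model is mechanistic but minimal: one shared inflow
  signal per subject, white noise, no partial-volume or flow-velocity
  modelling.
* Network parcels are geometric quadrants, not anatomy; atlas warping
  and native-space registration are out of scope (phantoms are born in
  a common space).
* The mixed model's contrast CIs are Wald intervals conditional on the
  estimated variance components; coverage is verified by simulation at
  the default cohort size, not guaranteed at much smaller n.
* Real-data effect sizes (group β, network means) are anchors for
  generator defaults, not reproduction targets — the raw clinical data
  behind them are not public.
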