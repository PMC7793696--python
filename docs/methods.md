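# Methods

This note documents the generative model, the estimators, the closed-loop
protocol simulation and the statistical procedures implemented in
`smrcoh`, together with the numerical choices made where the design was
genuinely open.

## Generative model of the two-channel recording

A simulated run is the sum of independent components per channel
(Cz, CPz; amplitudes in µV):

1. **Background**: Gaussian 1/f^α noise (frequency-domain shaping,
   exactly demeaned and rescaled to the target SD). Default α = 1, the
   typical spectral exponent of resting EEG, SD 6 µV.
2. **Coupled SMR pair**: for coupling parameter `c ∈ [0, 1]`,

       x₁ = √c·s(t)     + √(1−c)·n₁(t)
       x₂ = √c·s(t−τ)   + √(1−c)·n₂(t)

   with `s, n₁, n₂` independent unit-RMS Gaussian signals brick-wall
   filtered to 12–15 Hz. The in-band spectral correlation coefficient is
   then `c`, so the magnitude-squared coherence has the closed form
   **MSC = c²** and the imaginary coherency is `c·sin(2πfτ)`. The default
   lag τ = 18 ms is a quarter period of the 13.5 Hz band centre, which
   maximizes |ImCoh|; τ = 0 produces a pure volume-conduction surrogate
   (real coherency, ImCoh → 0). The weight convention was chosen over the
   alternative (weight `c` on the shared source, which would give
   MSC = c⁴) precisely because it yields this closed-form target.
3. **Theta and beta components**: independent band-limited noise per
   channel (4–7 Hz at 3.1 µV RMS, 21–35 Hz at 1.4 µV RMS). Component
   amplitudes were calibrated once so that Cz band powers land near the
   scale typical of this paradigm (SMR ≈ 3 µV², theta ≈ 10 µV²,
   beta ≈ 3.5 µV², each including the 1/f background's in-band share).
4. **Artifacts**: blinks are 400 ms raised-cosine transients (default
   300 µV on EOG, attenuated 0.4/0.2 on Cz/CPz, reflecting the frontal
   dominance of ocular potentials; 10 % are negative-going), muscle events
   are 0.3–0.5 s envelopes of 30–100 Hz noise (40 µV RMS) on the EEG
   channels. Onsets are Poisson (defaults 4 blinks/min, 1 burst/min; these
   rates are the calibration knob for the pooled rejection rate, which
   lands near 9 % under the default criteria). The ground-truth mask marks
   the FWHM core of each event — the span where the artifact dominates the
   EEG — not the near-zero cosine tails, so mask-based recall statements
   are meaningful.
5. **Learning**: the coupling used in session *s*, run *r* is
   `clip(c₀ + β_session·(s−1) + β_run·(r−1) + ε, 0, 0.95)` with
   ε ~ N(0, noise_sd²) drawn once per run. Ground truth is recorded in the
   run's metadata and EDF sidecar.

What the generator deliberately does **not** emulate: head-model mixing
beyond the three named channels, nonstationarity other than linear trends
and artifacts, cognitive state, or the spectral fine structure of real
sensorimotor rhythm (it is Gaussian band noise, not a rhythmic bursting
process). Passing tests therefore demonstrate estimator and pipeline
correctness under a known linear-Gaussian world, not performance on real
EEG.

## Preprocessing

Runs are cut into non-overlapping 1-s epochs (trailing partial second
discarded). An epoch is rejected when, on any EEG channel, a consecutive
sample pair differs by more than 50 µV, any sample exceeds ±120 µV, or any
sliding 100 ms window (stride 1 sample) has peak-to-peak range below
0.5 µV; "activity" is interpreted as peak-to-peak range, the standard
flatline criterion, since SD within the window would be an equally
defensible reading. Ocular rejection — manual in practice — is replaced by
an automatic EOG amplitude threshold (default 100 µV), documented as a
proxy and configurable. Rejection is epoch-level and all-channel because
the coherence estimator needs paired epochs.

## Spectral estimation

Per epoch the channels are demeaned, multiplied by a split-cosine-bell
(Tukey) window with 10 % total taper — "Hanning 10 %" in the convention of
legacy EEG packages; the full Hann window is `taper_fraction = 1` — and
FFT'd at 1 Hz resolution. Spectra are window-power normalized so a pure
amplitude-A sinusoid carries A²/2 in its bin and white noise satisfies
Parseval within 1 %. Coherency uses the **average-then-normalize**
convention, `C(f) = ⟨XY*⟩ / √(⟨|X|²⟩⟨|Y|²⟩)`; a normalize-then-average
variant exists for sensitivity analysis. A single epoch is refused
(its MSC is identically 1). Band averages take bins whose centre lies in
[f_lo, f_hi] inclusive — at 1 Hz resolution the SMR band averages the 12,
13, 14 and 15 Hz bins. The imaginary part is reported signed and averaged
after per-bin computation. Under independence E[MSC] ≈ 1/n_epochs; the
180 epochs of a full 3-min run put this bias floor near 0.006.

Band power is computed both as the sum of the epoch-averaged auto-spectrum
over band bins and by complex demodulation: multiply by
`exp(−i2πf_c t)` at the band centre, low-pass at half the bandwidth with a
zero-phase 4th-order Butterworth filter (standard and numerically stable at
these bandwidths), and scale the squared envelope so a pure sinusoid of
amplitude A yields A²/2. The two routes agree within ~10 % on stationary
narrowband signals; brick-wall band edges account for most of the
difference (the demodulation low-pass is −3 dB at the band edge).

## Closed-loop protocol

Defaults mirror the training design: 10 sessions of one baseline plus six
feedback runs, 3 min each, 256 Hz. The online display updates at 1 Hz; the
coherence bar is band MSC (the measure actually fed back) over a trailing
8-epoch window (all epochs so far while the window fills; the t = 1 update
is undefined), and the control bars are the current epoch's
complex-demodulation theta/beta power on Cz. The online window length and
measure are configurable since the realtime estimator of the commercial
system is not published; no online artifact handling is simulated, only
offline rejection. Baseline thresholds: mean online coherence; mean + 1
sample SD (n−1) of control power. After each feedback run the coherence
threshold is reset to that run's mean (a running mean over all prior runs
is selectable); control thresholds stay fixed within the session. Reward
increments once per entry into the all-green state — "a counter increased"
describes discrete events — with per-second accrual as an option.

## Statistics

Per group and outcome the trend model is
`value ~ session + run + session:run` with session 1..10 and run 1..7
(run 1 = baseline; whether the baseline should be coded 0 or 1 is
ambiguous, so the coding is explicit and configurable) entered as numeric
covariates, plus a random intercept and independent per-subject variance
components for the session and run slopes (the lme4 form
`(1|s) + (0+session|s) + (0+run|s)`). Effects are reported in the
sequential order session, run, session:run. The statsmodels backend
provides no Satterthwaite denominator df, so Wald F tests are reported
with the labeled between-subject fallback df = n_subjects − 1; a
**two-stage** estimator (per-subject OLS, then one-sample t across
subjects, exactly equal to the mixed fixed effects on balanced data) is
attached to every result as a cross-check and used automatically when the
mixed fit is singular (e.g. noise-free data). Optimization tries Powell
first, then L-BFGS and BFGS, accepting the first converged fit; gradient
methods occasionally stall in the variance components and report inflated
standard errors. Monte-Carlo calibration (200 null cohorts of 10 subjects)
puts the session test's type-I error near the nominal 5 %.

Cousineau-Morey within-subject SEs: subtract each subject's mean, add the
grand mean, take per-condition SEs, inflate by √(C/(C−1)). Incomplete
matrices are refused rather than silently deleted listwise. Pre/post
comparisons use paired t tests (df = n−1) with Bonferroni adjustment
`min(1, p·family)`; zero-variance differences are flagged degenerate
rather than returning an arbitrary statistic. Per-strategy learning is
summarized by the OLS slope of coherence on run number per (subject,
session), averaged per reported strategy label, a subject with k labels
contributing to k label means.

## Problem sizes and determinism

Estimator-level checks use the protocol's native geometry (180 1-s epochs
per run). Cohort-level experiments in the tests and the acceptance script
use 30-s runs and 10-subject groups, which keeps a full
20-subject × 10-session × 7-run experiment near half a minute while
leaving every qualitative contrast (slope signs, significance pattern,
calibration) intact; run length is a config field, so the full 180-s
geometry is one argument away. All randomness flows through
`numpy.random.Generator` seeded from explicit integers; identical seeds
give bit-identical recordings, datasets and fit results.

## Known limitations

- The imaginary-coherency null under volume conduction holds in
  expectation; single 180-epoch estimates scatter with SD ≈ 0.02–0.03.
- EDF quantization (16-bit over each channel's own range) introduces
  ~0.003 µV rounding on typical runs; bit-exact round trips are only
  guaranteed for the CSV/JSON artifacts.
- The fallback denominator df is conservative relative to Satterthwaite
  for effects estimated with many within-subject replicates.
- Coupling is amplitude mixing of a single shared narrowband source;
  phase-coupling regimes (e.g. coupled oscillators with distributed lags)
  are out of scope.
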