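# Methods

This note records the models, conventions and numerical choices behind
`cardiomap`, in the spirit of a methods supplement: what is simulated, how
each quantity is defined, which defaults matter, and what the synthetic
benchmarks do and do not demonstrate about real recordings.

## Synthetic recordings

### Action-potential waveform

Each beat is the product of a logistic upstroke and a repolarization
envelope, evaluated from the stimulus time:

* upstroke `S(t) = logistic((t − t_up)/τ_up)` with `t_up = 5·τ_up`, so the
  waveform starts essentially at rest; `τ_up = 4 ms` by default, giving a
  10–90 % rise of ~18 ms — representative of monolayer optical upstrokes,
  which are slower than single-cell electrical upstrokes because the ROI
  averages many cells;
* envelope `R(u) = (1 − p)·e^(−u/τ_notch) + p·logistic((D − u)/τ_rep)` for
  `u = t − t_up ≥ 0`: a fraction `1 − p` of the amplitude decays early
  (time constant `τ_notch`), while the plateau fraction `p` holds for
  duration `D` and then falls sigmoidally, leaving an exponential tail with
  time constant `τ_rep`.

A large `p` produces the prolonged ventricular plateau; a small `p` with a
fast tail produces the short triangular atrial shape. This family was
chosen over a literal "hold, then single exponential" because optical APD
level sets are close to equally spaced in time (repolarization is nearly
linear between 20 % and 80 %), which a convex pure-exponential envelope
cannot reproduce; the sigmoidal fall can, while keeping an exponential tail
for the restitution dynamics.

Subtype presets were calibrated once against the dense-grid oracle so the
true APD20/50/80 equal 84/131/179 ms (atrial) and 127/191/251 ms
(ventricular) — the optical phenotype targets — and then frozen
(`ATRIAL`, `VENTRICULAR` in `cardiomap.synth`).

### Ca²⁺ transient

A linear rise to the peak followed by an exact mono-exponential decay with
`cat_decay_tau`, starting `cat_onset_delay` (15 ms) after voltage
activation. The rise duration is `cat_ttp/0.9`, so the 10 %-to-peak time
equals `cat_ttp` by construction. The corner peak and exact exponential
give closed forms for every recovery crossing (`CaTD50 = TTP + τ·ln 2`
from onset) and make the fitted τ an exact oracle.

Preset time constants: atrial TTP 116 ms, τ 350 ms; ventricular TTP
246 ms, τ 430 ms. The ventricular τ is deliberately below the published
fitted value of 671 ms: with a literal mono-exponential decay, TTP 246 ms
plus τ 671 ms puts the 80 % recovery at ~1.3 s, which cannot complete
inside a 1 Hz pacing cycle — real decays are faster than their fitted
tails, a luxury a single-exponential generator does not have. The 430 ms
value preserves the atrial < ventricular ordering on every Ca²⁺ metric and
keeps 80 % recovery inside the cycle; the 671 ms constant is still
exercised directly in the decay-fit validation.

Even so, at 1 Hz the transients do not fully return to baseline between
beats (true of the real signals too). Recovery benchmarks therefore pace
Ca²⁺ recordings at 0.4 Hz (atrial) / 0.25 Hz (ventricular), and the drug
screens pace at 0.75 Hz so the slowest transient keeps ~30 % headroom for
drug-induced prolongation. Measured CaTD under fast pacing reads slightly
short of truth because the diastolic level is elevated; this bias is
common to all doses of a screen and largely cancels in percent changes.

### Restitution dynamics

Rate adaptation follows a prescribed map `APD80(DI) = a − b·e^(−DI/c)`
(dynamic convention, `DI_n = CL_n − APD80_{n−1}`): each beat's
duration-controlling parameters are rescaled by a factor solved (Brent's
method on the dense-grid measurement) so its true APD80 equals the map
value, floored at 30 ms. Per-subtype maps were calibrated once through the
full ramp pipeline so the measured maximum slopes land near the optical
phenotype targets (~0.91 atrial at a=180, b=720, c=120; ~1.26 ventricular
at a=252, b=520, c=120). The ventricular map has slope > 1 at the fastest
steps, which produces mild alternans — realistic, and the alternating
points still lie on the map, so the fit is unaffected.

Stimuli that arrive before 99 % repolarization of the previous beat are
flagged `overlap` in the manifest (never an error); overlapping waveforms
combine by pointwise maximum, emulating an elevated take-off level.

### Drugs, noise, rendering

Drug action multiplies duration-controlling parameters (never the rendered
trace) by `1 + E_max·dⁿ/(dⁿ + EC50ⁿ)`, so ground truth stays consistent
after dosing; dose 0 is the exact identity. Screen compounds are defined
per subtype so a drug can be atrial-selective.

Acquisition noise is white Gaussian (default sd 2 % of amplitude) plus a
linear baseline drift (default 0.5 % of amplitude per second, i.e. ≤ 10 %
over a 10 s well — enough to make detrending necessary, not enough to be
ambiguous). Rendering writes `offset + gain·signal` per pixel to
interleaved or stacked 16-bit stacks; the voltage channel is negated about
its mean by default, as voltage-sensitive dyes report depolarization as a
fluorescence decrease. With zero noise, unit gain and positive polarity the
ROI mean reproduces the input trace to machine precision.

### Cohort variability

Wells differ by a lognormal scale on all duration parameters (CV 10 %,
matching the ~±9 % SEM over n = 6 wells of the reference phenotypes), and
each recording adds an independent lognormal scale (CV 4 %) for
session-to-session spread. The same two-level model, sampled without
rendering traces, provides the nulls for the 1000-replicate error-rate
calibrations — the statistical null lives at the well level, and this
keeps large replicate counts cheap.

## Signal conditioning

Order: polarity (flip if the skewness of the first difference is negative —
the fast upstroke puts the extreme derivative outliers on the depolarizing
side), then detrending, then robust rescale to [0, 1] by the 1st/99th
percentiles. Orientation must precede detrending because the rolling
percentile tracks the diastolic side of the signal.

Default detrend: rolling 20th-percentile baseline over a window of about
two cycle lengths, subtracted. A global polynomial (order 2) is available
and suits signals with a high duty cycle (slow Ca²⁺ transients), where a
percentile window may not see enough diastole. Conditioned metrics are
invariant to positive affine transforms of the raw counts.

Smoothing is Savitzky–Golay with a deliberately conservative default
(30 ms quadratic window): at 100 frames/s that spans 3 samples — an exact
pass-through — while at ≥ 250 frames/s it genuinely filters. Wider windows
visibly distort the 2–3-sample optical upstroke (several ms of APD shift),
so they are opt-in.

## Beat metrics

* **Activation** (APD reference): the maximum-derivative time, refined to
  sub-sample precision by fitting `A·logistic((t − t₀)/τ)` to the upstroke
  foot (samples below ~45 % of amplitude, widened to 70–90 % under coarse
  sampling; τ floored at a quarter sample to exclude a degenerate step
  solution; spline/steepest-interval fallbacks for step-like upstrokes).
  The upstroke-midpoint convention is available as a config option.
* **Ca²⁺ onset** (CaTD/TTP reference): 10 % upstroke crossing.
* Amplitude is per beat: baseline = median of the pre-stimulus diastolic
  window, peak = window maximum; for Ca²⁺ beats the corner peak is refined
  as the intersection of lines fit to the flanking samples (τ amplifies any
  amplitude error into the recovery crossings). Level crossings use linear
  interpolation; max-derivative ties break to the earliest time.
* **τ fit**: `A·e^(−t/τ) + C` over the 90→10 % decay segment (or to the
  window end when recovery is incomplete; ≥ 10 samples), initialized from a
  log-linear regression, τ bounded in (1 ms, 10 × segment length);
  non-convergence yields a flagged NaN, never the initializer.
* Undefined metrics propagate as flagged NaN. Truncated final beats are
  excluded from metric tables.

Noiseless recovery against the dense-grid manifest is ≤ 1 ms for every
duration metric at 100 frames/s and ≤ 0.01 ms at 1000 frames/s; the
residual at 100 frames/s is interpolation error and varies with the
stimulus phase relative to the sample grid (up to ~±1.5 ms when the cycle
length is not a multiple of the sampling interval).

## Restitution analysis

Points enter the curve after discarding the first 2 beats of each rate
step (non-steady-state; the ramp protocol default is 60→200 bpm in 10 bpm
steps of 8 beats). DI uses the preceding beat's APD80. The monoexponential
fit reports `max_slope = (b/c)·e^(−DI_min/c)` at the smallest retained DI;
if the fit RMSE exceeds 10 ms the slope falls back to the steepest 5-point
local linear regression, and if that fails too the curve is returned with
the slope undefined plus diagnostics.

## Dose-response statistics

Percent change is signed (`100·(post − pre)/pre`), computed per well
against that well's own dose-0 baseline, then summarized as mean ± SEM
across wells — the well, not the beat, is the unit of replication, and the
well→replicate mapping is explicit input. Between-group comparisons use
Welch's t test by default (pooled-variance Student available). Sequential
dosing is treated as independent per-dose contrasts versus baseline, not
as a repeated-measures model — a documented simplification.

Dunnett's many-to-one adjustment is computed exactly from the
product-correlation structure of the k statistics
(`ρ_ij = λ_i λ_j`, `λ_i = √(n_i/(n_i + n_0))`): the k-variate t tail
reduces to a double integral over one latent normal and the pooled-χ
factor, evaluated by Gauss–Hermite × Gauss–Legendre quadrature (accuracy
~1e-6, deterministic, balanced and unbalanced designs alike; critical
values by Brent root-finding to 1e-8).

Percent-change responses need one extra care: the dose-0 "control group"
is identically zero by construction. The contrasts then become one-sample
tests of each dose mean against that constant, with the pooled variance
taken from the dose groups alone. Two consequences of the shared baseline
measurement inside every percent change: (i) the k dose means remain
equicorrelated at ½, exactly the structure the Dunnett integral assumes;
(ii) the dose groups' sums of squares are positively correlated, so the
pooled variance carries fewer effective degrees of freedom than k(n−1) —
moment matching gives ν = 4k(n−1)/(k+3) (for k = 4, n = 6: ν ≈ 11.4
instead of 20). Without the correction the familywise error ran ~0.063 at
α = 0.05 over 5000 simulated nulls; with it, 0.048.

Stars follow the convention * p < .05, ** p < .01, *** p < .001.

## What the synthetic benchmarks do and do not show

They verify the full measurement chain — rendering, channel splitting,
conditioning, beat segmentation, every metric, restitution fitting and the
statistics — against ground truth that is independent of the sampling
grid, and they verify the statistical calibration under the package's own
variability model. They do not capture: spatial heterogeneity or
conduction (each frame is spatially uniform plus noise), motion artifact
(abolished pharmacologically in the target preparations), multi-phase
Ca²⁺ decay (the single-exponential generator is why the ventricular preset
caps τ at 430 ms), dye photophysics beyond linear bleaching, or arrhythmic
dynamics beyond the mild alternans the restitution map induces. Passing
tests therefore demonstrate correctness of the analysis, not realism of
every feature of real recordings.

## Problem sizes

Defaults were chosen to keep a full study light: 6 wells per subtype,
8-beat recordings at 100 frames/s, 4 ramp wells per subtype, three 4-dose
screens, and 1000-replicate null calibrations — the whole analysis and the
acceptance recomputation each run in about a minute on one core.
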