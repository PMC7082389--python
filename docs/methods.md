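# Methods

This note documents the models and procedures implemented in `icpulse`,
their assumptions, the parameters that matter, the numerical choices, and
what the synthetic-data tests do and do not establish about real recordings.

## Signal model and window summaries

All computation starts from uniformly sampled ABP and ICP waveforms at
≥ 50 Hz, in mm Hg throughout (no unit conversion happens anywhere in the
pipeline). The recording is tiled into consecutive, non-overlapping 10-s
windows from its start; an incomplete trailing window is dropped. The 10-s
cadence makes the arithmetic of the derived indices exact: 30 windows span
5 minutes, 6 windows span one minute.

Per window the pipeline computes:

- the arithmetic mean of each channel over its finite samples;
- the heart rate, as the frequency of the largest spectral magnitude of the
  mean-removed ABP within 40–180 cycles/min. A 10-s window has a raw
  resolution of 6 cycles/min, which would quantize the heart rate and
  distort amplitude extraction, so the peak is refined off-grid: a
  three-point quadratic interpolation on log spectral magnitude, followed by
  two rounds of parabolic refinement on directly evaluated projection
  magnitudes. On noise-free sinusoids the refined estimate is accurate to
  about 0.1 cycles/min anywhere in the band;
- the fundamental cardiac amplitudes aABP and AMP, as
  `2/N * |Σ (x − x̄) e^{−2πi f₀ t}|` at the refined fundamental — the value
  that returns exactly `a` for a pure sinusoid `a·sin(2πf₀t)`. The
  fundamental is anchored on ABP (the more robust channel) and re-picked on
  the ICP spectrum within ±1 bin before refinement, so both amplitudes
  describe the same cardiac component. Only the window mean is removed
  before the projection (no linear detrend).

Mean removal plus projection, rather than a peak read off the raw FFT bin,
keeps amplitude error below ~2% even when the heart rate falls between bins.

**Artifact screen.** Clinical monitoring series contain disconnections and
calibration artifacts; the screen here is deliberately simple and
configurable (`ValidityRule`): a window is invalid when mean ABP lies
outside [20, 250] mm Hg, mean ICP outside [−10, 150] mm Hg, more than 10% of
samples are missing, the ABP segment has zero variance, or no cardiac peak
is found. Invalid windows propagate as missing values; nothing is imputed.
If the channels arrive at different rates the slower one is linearly
interpolated onto the faster grid over their common span, without bridging
gaps.

## Derived indices

- **PRx** — moving Pearson correlation of 30 consecutive 10-s means of ABP
  and ICP, stepped every 6 windows (one minute). A window position yields a
  value only when ≥ 80% of its 30 pairs are valid; zero variance in either
  input yields a missing value, not an exception. The value is attributed to
  the *end* of its 5-min span (the index describes the preceding five
  minutes), so the first PRx appears at minute 4.
- **RAP** — the same moving correlation applied to (mean ICP, AMP), same
  window and cadence.
- **CPP** = mean ABP − mean ICP (the conventional definition; consistent
  with the summary statistics this package reproduces). The arterial
  transducer reference (right atrium vs foramen of Monro) is a provenance
  property of the data; no correction is applied.
- **AMP/aABP** — per-window ratio; reported missing when aABP < 1 mm Hg,
  since a near-zero denominator carries no physiological information.
  Minute values are means of the per-window ratios (mean-of-ratios, not
  ratio-of-means).

Minute rows aggregate the valid windows inside each minute; the CPP identity
`cpp = mean_abp − mean_icp` holds row-by-row.

## Episode definition

A refractory-intracranial-hypertension episode is the first contiguous run
of ≥ 60 valid minutes with mean ICP strictly above 40 mm Hg, preceded
(anywhere earlier in the record) by at least one valid minute below
25 mm Hg, in a series spanning at least 12 h. Two conventions the published
definition leaves open are fixed as follows, both configurable: "initial ICP
below 25" defaults to *any earlier valid minute* (alternative:
first-hour median below 25), and a missing minute breaks run contiguity —
sustained elevation cannot be asserted across a gap. A minute at exactly
40 mm Hg does not count toward the run.

## AMP–ICP phenotyping

The minute-by-minute relationship between mean ICP and AMP is fitted per
patient with a penalized cubic regression B-spline of basis dimension 5 —
enough flexibility for three monotonicity segments (flat at low ICP, a steep
rise, a possible terminal decline) but not enough to chase noise. The
smoothing weight is chosen by generalized cross-validation over a
logarithmic grid (GCV = n·RSS/(n − edf)², edf = tr[X(XᵀX+αS)⁻¹Xᵀ]), and the
coefficients come from the penalized least-squares normal equations (the
Gaussian-identity GAM estimator). The fit requires ≥ 60 valid minutes
spanning ≥ 20 mm Hg of ICP; otherwise the patient is labelled
`indeterminate` rather than forced into a pattern.

The fitted derivative on a 1 mm Hg grid is segmented with a dead band
ε = 0.01 (mm Hg AMP per mm Hg ICP):

1. derivative ≥ +ε everywhere → `monotonic_increase`;
2. ≤ −ε everywhere → `monotonic_decrease`;
3. a positive segment followed by a terminal negative segment covering
   ≥ 10% of the ICP range → `upper_breakpoint`, breakpoint at the
   derivative's zero-crossing;
4. a net-rising curve whose terminal low-slope (|d| < ε) run covers ≥ 20%
   of the range → `rightward_deflection`;
5. otherwise the closest case by segment areas, decided by the mean
   derivative over the upper quarter of the ICP range (≤ −ε →
   `upper_breakpoint`; within ±ε → `rightward_deflection`; else
   `monotonic_increase` / `monotonic_decrease` by dominant derivative area).

Rule 5 exists because a basis-dimension-5 spline smears sharp plateau or
collapse onsets over ~10 mm Hg, so exact run boundaries are unreliable on
borderline curves; the tail-mean criterion is the stable summary of how the
curve ends. All thresholds are arguments. Label disagreements on genuinely
borderline curves are expected and documented behaviour, not a defect.

## Aggregate relationship curves

For curves of any index against ICP or CPP, each patient's minutes are first
averaged within 10 mm Hg half-open bins anchored at 0 ([0,10), [10,20), …),
keeping bins with ≥ 5 minutes of support; pooling bin means rather than raw
minutes stops long recordings from dominating the smooth. The pooled points
are LOWESS-smoothed (local linear, tricube weights). The span default is
0.5: the input is bin means, so a physiological ICP range yields only ~8–15
distinct abscissae, and a 0.75 span would average over three quarters of the
range — flattening precisely the local features (such as an interior
AMP–ICP maximum) the curve exists to reveal. The 95% pointwise band is a
patient-level bootstrap (resample patients with replacement, refit,
percentile band; 500 seeded replicates by default), so between-patient
heterogeneity, not minute noise, drives its width.

## Group statistics and case–control comparison

Minutes are assigned to three ICP severity levels — base [0, 25), elevated
[25, 50), severe [50, 150] mm Hg, lower-closed — with minutes outside
[0, 150] excluded and flagged. Each variable is averaged within patient per
level, a patient contributing only where it has ≥ 30 valid minutes (so a
cell is never driven by seconds of data), and cells report the
across-patient mean (sd, n) of those per-patient means: each patient counts
once per cell regardless of recording length, matching per-patient-n summary
tables. Adjacent levels are compared with Welch's (unequal-variance) t test
— the safer reading of "Student's t", converging to the classical test under
equal variances — with no multiplicity correction (the analysis is
descriptive). When both groups have zero variance the t statistic is
undefined and p is reported as 1.

Cases are matched 1:1 to controls without replacement: exact on sex, then
minimal Mahalanobis distance on (age, GCS) with the covariance estimated
from all candidates, greedy in a seeded random case order, ties broken by
control id. Unmatched cases are reported, never silently dropped. No
propensity model and no caliper: the simplest reproducible choice. The
case–control contrast applies the Wilcoxon rank-sum test (exact null
distribution when both groups have ≤ 25 values without ties, otherwise
normal approximation with continuity correction) to first-5-h means of PRx
and of mean ICP; identical samples report p = 1.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes, not
waveform morphology:

- **ABP** = MAP baseline + band-limited Gaussian slow waves
  (0.005–0.05 Hz, the conventional vasogenic band; RMS 3 mm Hg) + a cardiac
  fundamental (default 19 mm Hg, with a 0.3-ratio second harmonic) at the
  configured heart rate + white noise (default SD 1 mm Hg).
- **ICP** mean level follows a piecewise-linear trajectory. Its slow-wave
  component is a signed mixture `c·s_shared + √(1−c²)·s_indep` of the ABP
  slow wave and an independent one (ICP slow RMS 1.5 mm Hg), so the
  correlation of 10-s means — the quantity PRx estimates — targets the
  coupling `c` directly; `c` may itself be a trajectory. Empirically the
  recovered window correlation tracks `c` within 0.2 across
  c ∈ {−0.8 … +0.8}.
- **ICP pulse amplitude** follows an exponential pressure–volume law
  `A(p) = a₀·exp(k(p − p_ref))` with a₀ = 1.8 mm Hg, k = 0.025 /mm Hg,
  p_ref = 17.5 mm Hg — chosen so that baseline AMP ≈ 1.8 mm Hg at ICP
  ≈ 17.5 and AMP ≈ 5.3 at ICP ≈ 61, the scale of published severe-TBI
  summaries. Two optional high-ICP regimes produce the phenotypes:
  a *plateau* (growth stops once CPP < `amp_plateau_cpp`; rightward
  deflection) and a *collapse* (linear decline at 0.15 mm Hg per mm Hg once
  CPP < `collapse_threshold`; upper breakpoint, the generating breakpoint
  being ICP = MAP − threshold). CPP in the amplitude law uses the MAP
  baseline, not instantaneous ABP. With k > 0 and no collapse the law is
  monotone non-decreasing in mean ICP; the rare monotonic-decrease phenotype
  uses k < 0.
- **PbtO2** is flat at 27 mm Hg for CPP ≥ 70 and falls 0.5 mm Hg per mm Hg
  of CPP below 70, floored at 0, with additive noise — the plateau-then-
  decline shape of oxygenation against perfusion pressure. It is generated
  at minute resolution and held constant within each minute.
- **Cohorts** realize a phenotype mix by largest-remainder apportionment
  (the default mix 6/13/12/2 out of 33 reproduces the reference cohort's
  pattern counts exactly at n = 33). Default per-patient trajectories rise
  from 10 mm Hg to a phenotype-dependent peak over 60% of the record and
  hold; by default the reactivity coupling is linked to the ICP trajectory
  (+0.05 below 25 mm Hg ramping to +0.65 above 50), the cohort-level
  deterioration of reactivity with intracranial hypertension. Metadata is
  cosmetic realism: age ~ N(30.3, 12.5²) truncated to [16, 80], 78.8% male,
  GCS ≤ 8 with probability 0.848. Everything is deterministic given the
  seed, via independent named substreams.

**What the generator does not model** — and therefore what passing tests do
not establish about real data: ICP pulse sub-peaks (P1/P2/P3) and waveform
morphology, respiratory modulation, treatment effects (cooling, vasopressors,
decompression), the Cushing arterial response, non-stationary artifacts, or
any mortality/outcome structure. Recovery results bound performance under
the model's assumptions; clinical artifact burden is far richer than the
validity screen simulated here.

## Problem sizes

Synthetic recordings in the tests and the acceptance script are 2–5 h per
patient (120–300 minutes, comfortably above every fit precondition of the
methods) with cohorts of 8–40 patients, rather than multi-day monitoring;
episode-detection checks use ≥ 12 h minute-resolution series directly. The
coupling-recovery experiment uses 20 patients with couplings spaced across
[−0.6, 0.8] on flat ICP; phenotype recovery uses 40 patients at the default
mix and noise; test calibration uses 5000 null replicates at n = 12 per
group; case–control power resamples 24-vs-24 draws from simulated pools of
30 patients per arm.

## Known limitations

- The phenotype taxonomy's rightward-deflection class has no quantitative
  published definition; the plateau rule here is one reasonable
  operationalization and borderline curves can legitimately be labelled
  differently.
- The greedy matcher is order-dependent in principle; with well-separated
  covariates it coincides with the optimal assignment (verified against an
  exhaustive oracle), but on dense pools a global assignment would differ.
- PRx inherits the usual estimator noise of a 30-sample correlation; single
  minute values are nearly meaningless and only window/recording aggregates
  are interpreted.
- The elastance and collapse parameters are calibrated to summary scales,
  not fitted to any waveform data; absolute AMP values in simulations
  should not be read as patient-level predictions.
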