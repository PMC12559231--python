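# Methods

`visres` models the resolution limit of human vision — the finest display
resolution, in pixels per visual degree (ppd), at which a high-contrast
pattern is still detectable — and everything needed to measure it in a
simulated psychophysical experiment and to exploit it in an
eccentricity-dependent image filter.  This note documents the models, the
numerical choices, and what the synthetic data do and do not establish.

## The sensitivity model

Contrast sensitivity for an opponent colour channel c ∈ {Ach, RG, YV}
(achromatic L+M, red–green L−M, yellow–violet S−(L+M)) is log-linear in
spatial frequency, with the slope steepening linearly in retinal
eccentricity:

    log10 S_c(e, ρ) = log10 S0_c + kρ_c (1 + ke_c e) ρ,

with ρ in cycles per degree (cpd), e in degrees, kρ < 0 and ke > 0.  A
stimulus of fixed contrast m is at threshold when S = 1/m, giving the
resolution limit

    ρ_c(e) = A_c / (1 + ke_c e),    A_c = log10(S/S0)/kρ  [cpd],

and a threshold of 2ρ(e) in ppd (a display can show at most one cycle per
two pixels).

**Identifiability.**  With one fixed contrast per channel, S0 and kρ enter
thresholds only through A, the foveal cutoff frequency.  The fit is
therefore parameterised as (A, ke); S0 is a reporting convention (default
200) from which a kρ can be quoted.  The logarithm base cancels in A, so
thresholds are base-invariant (tested).

**Fitting.**  Ordinary least squares on ρ in linear cpd space,
Levenberg–Marquardt with a multi-start over ke ∈ {0.05…0.5}; both
per-observer and per-eccentricity-median fits are available
(`aggregate="median"`), since either could underlie a published aggregate
fit.  Noiseless data are recovered exactly; under 10% lognormal threshold
noise with 18 observers × 3 eccentricities, (A, ke) are recovered within
5% RMSE (tested over 100 replicates).

**Default calibration.**  Foveal cutoffs A = 47 / 44.5 / 26.5 cpd (94, 89
and 53 ppd median foveal limits for Ach/RG/YV) and fold-declines at 10° of
2.3× / 4.9× / 4.8×, i.e. ke = 0.13 / 0.39 / 0.38 via ke = (decline − 1)/e.

## Population model

Observer variability per channel is a Gaussian over thresholds at each
measured eccentricity knot (mean = sample mean, SD = sample SD with n−1),
with (μ, σ) interpolated linearly in eccentricity between knots and
continued linearly, floored at zero, beyond them; extrapolated queries are
flagged.  Percentiles are μ(e) + z_p σ(e); higher percentile = more acute
observer.  The display calculator inverts exact single-pixel arctangent
geometry to convert a percentile threshold into the minimum line count (or
ppi) per viewing distance, or the minimum viewing distance per resolution.

## Simulated psychophysics

**Task geometry.**  Two-interval forced choice (2IFC): guess rate γ = 0.5.
The stimulus variable is resolution in ppd, and higher is *harder* — the
opposite of a contrast staircase — so the psychometric function falls from
a lapse-limited ceiling to the guessing floor as the level rises:

    p(correct | x) = γ + (1 − γ − λ)(1 − exp(−ln2 · 10^{β(T − x)})),

in x = log10(level).  The ln2 factor puts the threshold parameter T
exactly at the performance criterion midway between floor and ceiling,
which is also where fitted thresholds are reported (configurable through
`threshold_at_criterion`).

**Slope.**  Default β = 10 in log10-ppd units, for both the generating
observers and the QUEST likelihood.  Resolution-limit detection is steep:
once a grating exceeds the resolvable cutoff its visibility collapses
within a fraction of an octave.  (The β ≈ 3.5 convention familiar from
contrast staircases describes the contrast dimension and would imply
implausibly gradual transitions in ppd.)  Default lapse λ = 0.01.

**QUEST.**  Discrete posterior over log10 threshold on [0.3, 2.3] at 0.01
steps (2–200 ppd), Gaussian prior centred at log10 60 (the classical
20/20 value) with SD 0.6.  Each trial is placed at the posterior mean
(posterior-quantile placement available).  Updates are plain Bayes with
the 2IFC Weibull likelihood and are validated against an independent
brute-force grid computation to 1e-10.

**Session structure.**  One staircase per colour channel, interleaved in
seeded random order.  Each selected level is presented three times
consecutively (emulating an apparatus whose viewing distance is costly to
change), each response simulated independently and fed to the staircase
individually by default; an aggregated (majority-vote) triplet mode
exists, since consecutive-repeat scoring is a genuine unknown.  A track
stops when the posterior SD reaches 0.07 log10 units after at least 30
responses, or at 50; counts land in {30, 33, …, 48, 50} because levels
change per triplet and the last triplet truncates at the cap.

**Threshold estimation.**  Maximum-likelihood fit of the same Weibull
family to each track's binary responses: γ fixed at 0.5, λ ∈ [0, 0.05],
β ∈ [0.5, 20], T within the grid span; L-BFGS-B with multi-starts over T
and β.  Degenerate response sets (e.g. all correct) return a
boundary-flagged fit rather than raising.  Outliers are flagged per
(channel, eccentricity) by the modified Z-score 0.6745(x − median)/MAD
with the conventional 3.5 cutoff; when the MAD vanishes on non-constant
data the scale falls back to 1.253 × mean absolute deviation, and
constant data yield no outliers.

## Synthetic observers

Per-observer thresholds are drawn from the per-channel Gaussian population
at each eccentricity, truncated positive, and redrawn (≤100 attempts)
until non-increasing in eccentricity — acuity declines monotonically in
the median, and enforcing it per observer keeps the generator simple; one
seeded substream per observer × channel keeps draws reproducible under
population growth.  Default population SDs: foveal achromatic σ = 13 ppd
(placing the best observers, ~120 ppd, near +2σ), σ = 7.9 ppd at 20°
(placing the 95th percentile at 35 ppd), with the implied coefficients of
variation (0.14, 0.25, 0.36 at 0°, 10°, 20°) applied to all channels —
the chromatic spreads are an assumption, not a measurement.

What the generator emulates: the study design (18 observers, 3 channels ×
{0°, 10°, 20°}, interleaved QUEST with triplet repeats, 162 thresholds
before exclusion), Weibull response stochasticity, and population spread.
What it does not: attention lapses clustered in time (so the synthetic
outlier *count* need not match a human dataset), criterion drift,
learning, optical factors varying with viewing distance, or any
correlation between channels within an observer beyond the shared
monotone structure.  Passing recovery tests therefore establishes that
the estimation pipeline is unbiased at study scale under the stated
response model — not that the model captures every property of human
observers.

Stimulus fixtures: square-wave gratings at the display Nyquist frequency
(period 2 px; configurable even period) under a Gaussian envelope whose
default σ = 0.5° makes the ±2σ extent span 2 visual degrees (the envelope
"size" convention is ambiguous; σ is configurable); channel contrasts
0.96 / 0.23 / 0.89.  Box-filter resolution reduction is block-average +
replicate (idempotent; annihilates the Nyquist grating at n = 2, which is
the point of the paired text-stimulus task); Lanczos (a = 3) resampling
preserves DC to 1e-6 and passband amplitudes to 2%.

## Foveated filtering

The image is decomposed into DKL opponent planes (linear sRGB → LMS via
the sRGB/D65 and Hunt–Pointer–Estevez matrices, shipped as swappable
constants; mechanism rows normalised so the display white maps to
(1, 0, 0) and greys have exactly zero chroma), then each plane into
octave bands with a Laplacian pyramid.  A band coefficient at level l
carries peak frequency (ppd/2)/2^l; it is zeroed where that frequency
exceeds the channel's ρ_c(e) at the pixel's eccentricity
(e = atan(r_px/(ppd·180/π)), flat screen, gaze on the normal; optional
discrete rings reproduce a segment-wise look).  At the study's fixed high
contrasts the threshold test reduces to this frequency cutoff; an
amplitude-aware mode (zero only coefficients below the threshold contrast
1/S(e, f)) is provided since the published wording admits both readings.
Cutoffs can come from fitted channel parameters or from a population
percentile.

**Pyramid choice.**  The default pyramid is biorthogonal-interpolating:
reduce = decimation, expand = separable linear interpolation.  Its band
coefficients are identically zero at even sample positions, which makes
masked reconstruction an exact projection: the filter is idempotent to
machine precision and the identity wherever no mask touches.  A classic
smoothing pyramid (5-tap binomial kernel) is available (`scheme=
"binomial"`) and looks smoother, but no smoothing-kernel pyramid can make
analysis → mask → reconstruct idempotent (re-analysis of the
reconstruction perturbs masked coefficients at the percent level), so it
is not the default.  Both reconstruct exactly.  Chromatic band removal
can push pixels out of the display gamut; they are clipped on output, and
only on such pixels does a second application differ from the first (an
alternating band/gamut projection was tried and does not converge — the
band projection is oblique).

## Problem sizes and tolerances

Recovery tests run 20 independent 18-observer studies (the acceptance
script runs 10) and compare per-condition medians across seeds to the
generating population at 10% (5% for the foveal achromatic median); these
sizes keep the full suite within a few minutes while leaving the
median-of-medians sampling error well under the tolerance.  Pyramid
reconstruction is tested at 1e-6, DKL round trips at 1e-4 (through 8-bit-
scale nonlinear encoding), QUEST against its oracle at 1e-10, and the
model inverse-pair identity at 1e-12.  All randomness flows from explicit
seeds; there is no hidden global RNG state.

## Known limitations

- The sensitivity model is the log-linear form only: no luminance, size
  or temporal terms, no meridian anisotropy, no binocular summation.
- Population percentiles assume Gaussian observer spread; tails beyond
  the ~95th percentile are extrapolation.
- Display geometry is on-axis and flat; off-axis and curved displays are
  out of scope.
- The DKL matrices are display-referred conventions, not individually
  calibrated cone fundamentals; the chromatic population SDs are assumed.
- The foveated filter removes whole octaves, so degradation advances in
  visible steps with eccentricity rather than continuously.
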