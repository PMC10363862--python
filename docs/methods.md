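# Methods

This note documents the models implemented in `headturn`, the choices made
where the design was genuinely open, and what the synthetic data do and do
not establish about real experiments.

## Room simulation

**Image-source model.** Shoebox rooms are simulated with the Allen–Berkley
mirror-image construction: image coordinates per axis are
`(1 − 2p)·x_s + 2nL` (p ∈ {0,1}, n ∈ ℤ) and the number of wall reflections
along an axis is `|n − p| + |n|`. Enumeration is limited by path length
(`c · time_limit`) rather than a reflection-order cap; the defaults are
0.3 s for benefit maps (the late tail contributes little to energy ratios)
and 1.4 s for reverberation-time estimation (the decay must reach −35 dB
with margin). Per octave band, an image's amplitude is
`r^k / d` with `r = sqrt(1 − α)`, k the reflection count and d the path
length. Air absorption is neglected (paths of a few tens of meters dominate
the energy at the 2.1 m source distance used here).

**Surface scattering and the diffuse tail.** A purely specular image-source
field in a *flat* room (the modeled room is 11 × 13 × 3 m) has a strongly
double-sloped decay: grazing horizontal paths meet the floor and ceiling
rarely and dominate the late tail, so the Schroeder T30 exceeds the
diffuse-field (Eyring) prediction by ~70 % at uniform absorption. Scenes
therefore carry a surface scattering coefficient *s* (default 0.3; 0 =
purely specular). Specular amplitudes are depleted by `sqrt(1−s)^k`, and the
diverted energy is returned as a seeded stochastic tail whose variance
profile is the surviving specular arrival-energy train convolved with the
Eyring band decay (a mean-field model of the diffuse field: scattered energy
enters at the rate the specular population loses it, then decays at the
diffuse rate). Ears receive independent tail noise mixed to the sinc-law
diffuse-field interaural coherence at each band center. With this renderer,
band T30 of an Eyring-inverted absorption round-trips to within a few
percent.

**Absorption calibration.** The modeled room is constrained only by its
printed octave-band reverberation times (1.16/1.34/1.15/1.02/0.85 s at
250–4000 Hz; 125 Hz copies 250 Hz). Two inversions are provided:

* `method="eyring"` — closed-form diffuse-field inversion
  `α = 1 − exp(−0.161 V / (S T))`, used with the scattering renderer;
* `method="calibrated"` (default) — bisection on the *simulated* specular
  Schroeder T30 per band (α ≈ 0.22–0.30). This mirrors the original
  auralization chain, a purely specular image-source engine whose printed
  reverberation times were measured on its own impulse responses. The
  distinction matters for benefit maps: a single-slope diffuse field at
  T30 ≈ 1.15 s in a 429 m³ room implies ~3.7× more reverberant than direct
  energy at 2.1 m, which compresses head-orientation effects to ≲1.5 dB,
  whereas the double-sloped specular field matches the same T30 with far
  less total reverberant energy.

**Head model.** A rigid sphere of radius 8.75 cm with ears at ±100°.
Interaural delays follow Woodworth's construction
(`−(a/c)·cosΘ` on the near side, `(a/c)(Θ − π/2)` beyond). Two shadow
magnitudes are available: the default single pole/zero approximation
(`|H| = sqrt((αω)² + β²)/sqrt(ω² + β²)`, `α = 1 + cosΘ`, `β = 2c/a`), whose
monotone shadow (−10 to −16 dB contralaterally at 4–8 kHz) tracks measured
artificial-head ILDs well, and the exact rigid-sphere diffraction series,
which is physically exact for a sphere but whose antipodal bright spot caps
the shadow near −5 dB — further from a real head with pinna than the
approximation. Fractional delays are rounded to the nearest sample at
44.1 kHz (phase errors far below the bandwidths analyzed).

**T30.** Backward (Schroeder) integration of the band-filtered squared
impulse response; a least-squares line on the −5…−35 dB range of the decay
curve, extrapolated to 60 dB.

## Intelligibility model

Per gammatone band (4th-order all-pole gammatone implemented as a cascade of
four biquads — the expanded 8th-order transfer function is numerically
unstable at low center frequencies — 16 ERB-spaced centers, 100 Hz–8 kHz):
ear energies, interaural phases (2π f_c times the lag of the maximum
normalized interaural cross-correlation within ±1 ms, parabolic sub-sample
refinement) and the interferer's interaural coherence (that maximum). The
band advantage is the better-ear TIR plus the equalization–cancellation
BMLD with internal-noise constants σ_ε = 0.25 and σ_δ = 105 µs; bands are
combined with ANSI S3.5 one-third-octave band-importance weights
interpolated on log-frequency and renormalized (uniform weights available).
For the model path the per-band ear signals are constructed directly at each
band center (shadow, ITD and log-interpolated absorption evaluated at f_c),
which avoids octave-crossover artifacts that broadband rendering followed by
band analysis would introduce.

**Benefit maps and references.** `benefit_map` sweeps yaw over the circle
(1° default) and stores both `benefit_db = TIR(θ) − TIR(0°)` (zero at the
reference orientation by construction) and `unmasking_db = TIR(θ)`, which is
the spatial unmasking relative to the co-located target/interferer
configuration (identical BRIRs ⇒ 0 dB). The co-located reference is the one
on the scale of the published peak values: with a yaw-0 reference a lateral
target would necessarily peak near 0 dB (yaw 0 already provides 90° of
separation), and the frontal target's benefit is undefined ("N.A.") exactly
because it *is* the co-located reference. Per-word benefits along a
trajectory are medians of the map value at the nearest grid yaw over each
word window.

**What a sphere cannot reproduce.** With either shadow model the lateral and
rear unmasking peaks computed here are ≈4.5 dB, about 1–1.5 dB below values
obtained with measured artificial-head HRTFs (5.5/5.9 dB). Pinna and torso
add 5–15 dB of high-frequency ILD beyond any sphere; shoulder reflections
further alter interaural cues. The map *shapes* (optimal regions near the
undershot orientations, mirror symmetry, frontal flatness) are reproduced;
absolute peaks are conservative.

## Trajectories and circular statistics

Raw yaw series are referenced to the interferer direction at trial start,
unwrapped, and smoothed twice with a zero-phase 27 ms Kaiser window
(β = 5, length forced odd; β is not fixed by the original description and is
exposed in config). Circular median minimizes mean circular absolute
deviation over data points and arc midpoints, ties broken toward the
circular mean; circular variance is 1 − R (mean resultant length). The
two-sample Kuiper statistic V = max(F_a − F_b) + max(F_b − F_a) is computed
on the pooled sorted sample and is exactly rotation invariant; p-values come
from label permutations (default 2000, seeded) with a mid-p tie correction,
because V lives on a lattice of multiples of 1/n and full tie counting makes
the test conservative (type-I rate 0.029 instead of 0.05 at n = 50; 0.038
with mid-p).

## Psychometrics

Scores are counts out of 24 per participant × condition × target × word
position. RAU is Studebaker's linearized transform
`(146/π)·[asin√(x/(n+1)) + asin√((x+1)/(n+1))] − 23` (counts are the
canonical input; RAU(12, 24) = 50 exactly). The psychometric model is a
logistic with a per-participant random intercept, fitted by maximizing the
marginal likelihood with 40-node Gauss–Hermite quadrature (Nelder–Mead with
restart plus quasi-Newton polish; per-participant intercepts as posterior
modes). No guessing floor is modeled: the closed-set 1-in-10 rate is left in
the intercept, matching the plain-logistic analysis the package emulates.
"Slope per dB" is the maximum derivative in proportion units, β₁/4. A RAU
error e converts to dB as `e / (100 · slope)`, treating RAU as percent-like
in midrange.

## Repeated-measures ANOVA

Generic k-factor within-subject decomposition on balanced designs: each
effect is tested against its interaction with subjects; Greenhouse–Geisser
epsilon comes from the covariance of the orthonormal-contrast-transformed
per-subject cell means (Kronecker contrasts for interactions), bounded to
[1/df, 1], and scales both degrees of freedom of the corrected p.
η² = SS_effect / SS_total, and the cumulative η² is their sum. The planned
analyses are the full three-factor model (condition × target group × word
position, left/right targets averaged first), the four two-factor contrasts
(Static vs A-only and AV vs A-only for lateral and rear targets), and the
single-factor model-vs-data comparison.

## Synthetic cohort

The generator reproduces the design (6 blocks × 48 trials, condition fixed
per block, each condition in two blocks, all three conditions within the
first three blocks, 12 trials per target location per block) and the
stimulus timing (sentence duration ~ truncated normal, mean 2.19 s on
[1.78, 2.77] s, SD 0.2 s; five word windows as Dirichlet(8) fractions;
target onset 1 s after interferer onset). Trajectories: Static trials jitter
within the ±3° tolerance (Gaussian-filtered sway, sub-deg/s speeds); moving
trials hold until a reaction time (0.25 ± 0.08 s) after target onset, then
follow a minimum-jerk profile whose duration is set so the peak speed equals
150 °/s, toward the target minus a condition-dependent undershoot
(lateral 29°/27.4°, rear 74.1°/49.4°, frontal −11.5°/−0.5° for
A-only/AV; SDs 20°/10° so that AV final orientations are tighter than
A-only, as required of the emulation). Rear targets are approached leftward
or rightward with equal probability.

Word responses are Bernoulli draws from the psychometric truth
(β₁/4 = 0.08/dB, random-intercept SD 0.5, β₀ = −0.2 placing the four
Static-condition predictions across the rising part of the function). The
dynamic-motion deficit δ (default 1.4 dB) is subtracted from a word's
benefit when the word window's RMS angular speed exceeds 5 °/s (a constant
per-trial mode is available). δ is a phenomenological stand-in for
motion-induced losses (e.g. binaural sluggishness); no mechanistic temporal
model is implemented. The pipeline's deficit estimator inverts the fitted
psychometric function on motion-gated cells
(`x_eff = (logit p_obs − β₀ − u_j)/β₁`, deficit = mean(benefit − x_eff)),
which is unbiased away from the midpoint where a RAU-error/slope conversion
is not; the overall mean signed error in RAU is reported alongside as the
classic summary.

**What passing tests show — and don't.** The generator matches the
*statistical structure* the analysis assumes (balance, trajectory phases,
condition-dependent dispersion, psychometric link). It does not emulate
localization search behavior, corrective under/overshoot dynamics,
audio-visual integration beyond the undershoot/dispersion parameters, lapses
or attention, or any acoustic waveforms. Recovery of δ by the pipeline
demonstrates the estimator's correctness under the generator's assumptions,
not that real motion deficits are of this form.

## Problem sizes and determinism

Benefit maps use the 0.3 s image time limit (≈10⁴ images) and take ~20 s per
scene at 1° resolution on one CPU; T30 estimation enumerates ≈10⁶ images at
the 1.4 s limit. Analysis runs are deterministic given (config, seed): all
randomness (cohort, diffuse tails, permutations) flows from explicit seeds,
and purely specular scenes are seed-free.
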