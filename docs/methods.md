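# Methods

## Overview

`orientpool` simulates an ideal observer performing a two-alternative
forced-choice (2AFC) global-orientation discrimination between a *standard*
texture (a single common orientation, re-randomized every trial) and a
*comparison* texture whose line orientations are drawn from a skewed
distribution. Each interval is encoded by a bank of orientation-tuned
Poisson neurons and read out with one decoder; the observer judges which
interval's estimate is more clockwise. Psychometric functions fitted to the
simulated judgements yield the point of subjective equality (PSE), which is
compared with the human results the paradigm was designed around.

All orientations are axial (180°-periodic) degrees in [0°, 180°); signed
offsets live in (−90°, +90°] with **positive = clockwise**. A distribution's
support holds offsets relative to its reference orientation (negative =
counter-clockwise). This convention is defined once in `orientpool._angles`
and used everywhere.

## Stimulus distributions

Two families of discrete offset distributions:

* **Piecewise Gaussian** (experiments 1–2). Each half (clockwise /
  counter-clockwise of the junction at offset 0) is a half-Gaussian with its
  own SD, sampled on its own grid (defaults: 2.5° steps, ±45° truncation; the
  equal-mass family of experiment 2 uses 0.5° steps clockwise, 2.5°
  counter-clockwise, ±90° truncation). Both halves include the junction
  point, are normalized within the half, and are then weighted:
  * *density-matched* (experiment 1): half masses proportional to the half
    SDs, which keeps the probability *density* continuous at the mode. A
    zero-SD half degenerates to a point mass at the junction with zero
    weight, so e.g. SDs 30/0 put all mass on one truncated half-Gaussian
    (discrete mean −18.27°).
  * *equal-mass* (experiments 2–3): each half carries probability 1/2, so
    the junction is the median by construction; mode and median stay at 0
    while the mean moves with the broader half (18/45 at ±90°: mean +9.41°).
* **Skewed uniform** (experiment 3). Uniform halves with different ranges on
  a common 2.5° grid; the junction itself is excluded and each half carries
  mass 1/2. The grid mean is (range_cw − range_ccw)/4 (75/15: −15°), the
  median 0.

Since −90° and +90° are the same line, a ±90°-truncated construction assigns
the seam point to the clockwise half so it appears once.

Summary statistics: the mean is the linear mass-weighted offset (valid
because every support spans < 180°); the median is the smallest support
point whose cumulative mass reaches 0.5, except that an *exact* 0.5 hit
returns the midpoint to the next support point — this makes the equal-mass
uniform's excluded junction its median, as the construction intends; mode
ties break toward 0.

## Textures

A texture is a list of frames of line orientations; rendering (line
luminance profiles, window geometry, monitor) is not modeled. Static
textures: one frame of 500 lines drawn i.i.d., shown 0.052 s. Dynamic
textures: 25 frames at 0.052 s (1.3 s total); by default each frame draws
*one* orientation shared by all lines (the temporal analogue of one draw per
line; a per-line mode is available — the choice matters little because the
decoders see only the pooled spike counts).

## Encoding

180 neurons at 1° spacing; Gaussian tuning of the *wrapped* axial distance
with half-width-at-half-height h = 22.5°; peak rate R_max = 60 spikes/s.
Stimulus orientations are binned to the nearest 1° grid point (the 0.5°
sampling of experiment 2 is re-binned; the effect on distribution means is
< 0.5°). Mean counts are R_max · t · (tuning ⊛ proportions), floored at
rate_floor · t (rate_floor = 0.01 spikes/s, configurable) so downstream log
likelihoods stay finite; spike counts are independent Poisson draws.
Dynamic stimuli are encoded frame by frame with t = 0.052 s and the counts
summed, which by Poisson additivity equals a single draw from the summed
means. Contrast enters only through an optional multiplicative gain
g(contrast) ∈ (0, 1] on R_max (default g ≡ 1): no contrast-response
mechanism is assumed, the hook simply scales the expected spike count.

## Decoders

* **Maximum likelihood.** log L(candidate) = Σᵢ nᵢ log Rᵢ(candidate) over
  the 180 grid candidates. On an evenly spaced wrapped bank the omitted
  −Σᵢ Rᵢ(candidate) and factorial terms are *exactly* candidate-independent
  (verified against the full Poisson log-pmf in the tests), so the weighted
  sum is the exact ML rule, not an approximation. Two candidate families
  are provided:
  * *point candidates* — each candidate is a single orientation. Because
    log of a Gaussian tuning curve is a (wrapped, floored) quadratic, this
    estimator minimizes a quadratic loss over the response profile and
    therefore lands essentially on the stimulus *mean* — it cannot separate
    from the vector average for these stimuli.
  * *distribution candidates* (used by the simulated observer) — each
    candidate is the interval's own generating distribution placed at a grid
    orientation ("signal known exactly"). This template estimator is
    unbiased for the distribution's placement, so its PSE tracks the
    comparison's mode/median — the behavior that makes ML diagnostic
    against the mean-tracking vector average in these experiments.
* **Winner-takes-all.** Preferred orientation of the maximal count. Its
  estimate distribution is centered like ML's but with several-fold larger
  variance at short durations.
* **Vector average.** Response-weighted average of preferred orientations.
  On axial data a naive weighted mean is seam-broken, and the doubled-angle
  circular resultant systematically shrinks the mean of broad profiles
  (for the 75/15 uniform it reads −10.6° where the profile mean is −14.4°),
  so the estimate is computed as the arithmetic weighted mean of preferred
  orientations unwrapped to (−90°, +90°] about the doubled-angle resultant,
  iterated to a fixed point. This is rotation-equivariant and preserves the
  linear mean of the response profile — and hence of the stimulus, because
  the tuning convolution is symmetric. The raw resultant remains available
  (`method="resultant"`) and serves as initializer and degeneracy detector.

Ties (in a likelihood profile or spike counts) break uniformly at random
with the experiment's seeded generator; flat profiles and all-equal counts
yield a flagged degenerate estimate.

## The simulated 2AFC task

Each trial draws a fresh standard orientation uniformly from 180°, rotates
both intervals' distributions with it, samples and encodes both textures
independently, decodes each with the same decoder, and reports whether the
comparison's estimate is clockwise of the standard's. Degenerate estimates
— and *exact ties* between the two grid-valued estimates, which occur on a
substantial fraction of trials for the discrete ML/WTA decoders — resolve
to a fair coin; without the tie coin those decoders acquire a spurious
half-grid-step PSE bias. The only noise source is Poisson spiking.

**Level placement.** The published level values are not available, so the 9
levels of the method of constant stimuli are placed from a 50-trial pilot at
level 0 that measures the decision variable directly: levels span
(−pilot mean) ± 3 pilot SDs (SD floored at 0.75° so near-deterministic
decoders still get a usable span). Each level then receives 80 trials
(720 total, the "4 runs of 180 trials" scale).

**Fitting.** The two-parameter logistic y = 100/(1 + e^{−(x−μ)/θ}) is
fitted by binomial maximum likelihood (own IRLS, cross-checked against a
statsmodels binomial GLM in the tests); a least-squares fit on the
percentages is retained for strict replication of the printed functional
form. Sign convention: the curve increases toward clockwise judgements.
Fits are flagged non-converged when the slope is non-positive, effectively
flat over the sampled range (logit swing < 0.1), or step-like (complete
separation). 95% CIs on μ use 5000 nonparametric per-level binomial
resamples (vectorized IRLS); if more than 5% of resamples fail the CI is
computed from the remainder and flagged. PSEs are reported signed and as
magnitudes (the printed values are magnitudes of rotation).

## Duration and contrast experiments

The single-interval task judges a static texture against implicit vertical
at 7 log-spaced durations from 0.05 to 3.33 s. The diagnostic distribution
(the printed one's parameters are unavailable) is the 75/15 skewed uniform
with its median placed 2.5° *clockwise* of vertical: the vector-average
prediction (mean, ≈9.4° counter-clockwise of vertical after tuning
convolution) and the template-ML prediction (the placement, 2.5° clockwise)
then straddle vertical, which the runner verifies on noiseless expected
counts before simulating and rejects otherwise. As duration grows, spike
counts rise and the ML observer's clockwise judgements approach 1 while the
vector-average observer's stay near 0 — the two read-outs give opposite
answers about the same pattern, which is what makes the stimulus
diagnostic. The contrast experiment repeats the sweep with R_max scaled by
g(contrast) for contrasts 0.25/0.5/1; with the default identity gain it
reproduces the duration experiment exactly (same seeds by construction).
The observed human transition from vector-average-like to ML-like judgements
over duration is a property of the data, not of this fixed model: the model
reports each decoder's prediction separately and contains no transition
mechanism.

## What the synthetic data does and does not emulate

The generator reproduces the published stimulus *statistics* exactly:
distribution shapes, sampling grids, 500 lines/frame, 25 frames, 0.052 s
frames, condition sweeps. It does not emulate rendering (luminance, line
envelopes, spatial layout, the 12° window), eye/display timing, observer
lapses, adaptation, surround suppression, correlated neural noise, or any
contrast mechanism beyond the gain hook. Passing tests therefore validate
the decoding-level account of the paradigm, not a full image-computable
model of the human data.

## Problem sizes and numerical choices

Simulations use the published scale throughout: 720 trials per psychometric
function, 5000 bootstrap resamples (2000 in some test paths), 300–400
trials per duration point. Reproducibility: a single integer seed feeds
`numpy.random.Generator` streams derived per condition × decoder; same-seed
reruns are bit-identical. Grid binning uses round-half-even at bin edges;
the rate floor (0.01 spikes/s) only matters in the far tuning tails; the VA
fixed-point iteration converges in a handful of steps (tolerance 1e-10,
cap 50).

## Known limitations

* The exact diagnostic distribution of the duration experiments and the
  human transition curves are not reproduced quantitatively (parameters
  unavailable; no transition mechanism in the model).
* The equal-mass ±90° piecewise Gaussian of experiment 2 spans the full
  axis, so *any* read-out shows some circular shrinkage: the simulated VA
  PSE (≈8°) sits slightly below the distribution's linear mean (9.4°).
* The contrast gain is an uncalibrated hook, not a contrast-response model.
* Decoder estimates are grid-quantized at 1°; PSEs are continuous because
  the standard's orientation is continuous.
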