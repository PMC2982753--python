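"""Simulated 2AFC psychophysics and logistic psychometric fitting.

The simulated observer runs the same task as the human observers: on each
trial a *standard* texture (common orientation, randomly rotated) and a
*comparison* texture (lines drawn from a skewed distribution) are each
encoded by the Poisson neuron bank and read out with one decoder; the
observer reports whether the comparison's estimate is clockwise of the
standard's.  There is no internal noise beyond the Poisson spiking.

Responses collected by the method of constant stimuli are fitted with the
two-parameter logistic

    y(x) = 100 / (1 + exp(-(x - mu) / theta)),

where ``x`` is the clockwise rotation applied to the comparison's reference
(mode or median) relative to the standard, ``mu`` is the point of subjective
equality (PSE) and ``theta`` the discrimination-threshold parameter.  The
default fit maximizes the binomial likelihood (IRLS); a least-squares fit on
the percentages is available for strict replication of the printed form.
95% confidence intervals on ``mu`` come from nonparametric per-level
binomial resampling (default 5000 resamples).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.special import expit, logit

from ._angles import signed_offset
from .decoding import (
    candidate_log_rates,
    loglik_profile,
    ml_decode,
    va_decode,
    wta_decode,
)
from .distributions import OrientationDistribution
from .encoding import NeuronBank, encode_stimulus
from .stimuli import (
    COMMON_PER_FRAME,
    DEFAULT_FRAME_DURATION,
    DEFAULT_N_FRAMES,
    DEFAULT_N_LINES,
    sample_dynamic_texture,
    sample_static_texture,
)

__all__ = [
    "PsychometricData",
    "PsychometricFit",
    "StimulusParams",
    "SimulatedObserver",
    "simulate_2afc_trial",
    "run_constant_stimuli",
    "fit_logistic",
    "bootstrap_pse_ci",
    "simulate_vertical_judgement",
]

DECODERS = ("va", "wta", "ml")


# ---------------------------------------------------------------------------
# psychometric data and fits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsychometricData:
    """Per-level 2AFC tallies: ``n_clockwise`` of ``n_trials`` at each level."""

    levels: np.ndarray
    n_trials: np.ndarray
    n_clockwise: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.levels, dtype=float)
        n = np.asarray(self.n_trials, dtype=int)
        k = np.asarray(self.n_clockwise, dtype=int)
        object.__setattr__(self, "levels", x)
        object.__setattr__(self, "n_trials", n)
        object.__setattr__(self, "n_clockwise", k)
        if not (x.shape == n.shape == k.shape) or x.ndim != 1:
            raise ValueError("levels, n_trials, n_clockwise must be aligned 1-D arrays")
        if np.unique(x).size < 2:
            raise ValueError("need at least two distinct levels")
        if np.any(n < 1) or np.any(k < 0) or np.any(k > n):
            raise ValueError("need 0 <= n_clockwise <= n_trials >= 1")

    @property
    def proportions(self) -> np.ndarray:
        return self.n_clockwise / self.n_trials

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "level_deg": self.levels,
                "n_trials": self.n_trials,
                "n_clockwise": self.n_clockwise,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PsychometricData":
        return cls(
            df["level_deg"].to_numpy(),
            df["n_trials"].to_numpy(),
            df["n_clockwise"].to_numpy(),
        )


@dataclass(frozen=True)
class PsychometricFit:
    """Logistic parameters: PSE ``pse`` and threshold ``threshold`` (degrees)."""

    pse: float
    threshold: float
    converged: bool
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    ci_flagged: bool = False
    method: str = "ml"

    def predict(self, x) -> np.ndarray:
        """Percentage of clockwise judgements at level ``x``."""
        return 100.0 * expit((np.asarray(x, dtype=float) - self.pse) / self.threshold)


def _irls_batch(x: np.ndarray, n: np.ndarray, k: np.ndarray, max_iter: int = 60):
    """Binomial-logistic IRLS, vectorized over rows of ``k`` (shape (B, L)).

    Returns intercepts, slopes and an ok-flag per row (finite, converged,
    non-singular).
    """
    k = np.atleast_2d(np.asarray(k, dtype=float))
    B, L = k.shape
    # initialize from weighted least squares on empirical logits
    z = logit((k + 0.5) / (n + 1.0))
    w = np.broadcast_to(n.astype(float), (B, L))
    sw, swx = w.sum(1), (w * x).sum(1)
    swxx = (w * x * x).sum(1)
    det = sw * swxx - swx**2
    b1 = (sw * (w * x * z).sum(1) - swx * (w * z).sum(1)) / det
    b0 = ((w * z).sum(1) - b1 * swx) / sw
    ok = np.isfinite(b0) & np.isfinite(b1)
    active = ok.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[:, None] + b1[:, None] * x
        p = expit(eta)
        W = n * p * (1.0 - p)
        g0 = (k - n * p).sum(1)
        g1 = ((k - n * p) * x).sum(1)
        h00, h01, h11 = W.sum(1), (W * x).sum(1), (W * x * x).sum(1)
        det = h00 * h11 - h01**2
        bad = ~np.isfinite(det) | (np.abs(det) < 1e-300)
        ok &= ~(bad & active)
        active &= ~bad
        with np.errstate(invalid="ignore", divide="ignore"):
            d0 = (h11 * g0 - h01 * g1) / det
            d1 = (h00 * g1 - h01 * g0) / det
        d0 = np.where(active, d0, 0.0)
        d1 = np.where(active, d1, 0.0)
        b0 += d0
        b1 += d1
        still = (np.abs(d0) > 1e-12) | (np.abs(d1) > 1e-12)
        active &= still
    ok &= np.isfinite(b0) & np.isfinite(b1) & ~active  # ~active: converged
    return b0, b1, ok


def fit_logistic(data: PsychometricData, method: str = "ml") -> PsychometricFit:
    """Fit the logistic psychometric function to 2AFC tallies.

    ``method="ml"`` maximizes the binomial likelihood (default, well behaved
    with small per-level counts); ``method="ls"`` minimizes squared error on
    the per-level percentages.  The fit is flagged non-converged when the
    slope is non-positive, the optimizer fails, or the curve is effectively
    flat or step-like over the sampled range (slope indistinguishable from 0
    or from complete separation).
    """
    x, n, k = data.levels, data.n_trials, data.n_clockwise
    span = float(x.max() - x.min())
    if method == "ml":
        b0, b1, ok = _irls_batch(x, n, k[None, :])
        b0, b1, ok = float(b0[0]), float(b1[0]), bool(ok[0])
        pse, thr = -b0 / b1 if b1 != 0 else float("nan"), 1.0 / b1 if b1 != 0 else float("inf")
    elif method == "ls":
        def f(xv, mu, theta):
            return 100.0 * expit((xv - mu) / theta)

        try:
            p0 = (float(np.interp(0.5, data.proportions, x, left=x[0], right=x[-1])), span / 6.0)
            popt, _ = curve_fit(f, x, 100.0 * data.proportions, p0=p0, maxfev=10000)
            pse, thr = float(popt[0]), float(popt[1])
            ok = np.isfinite(pse) and np.isfinite(thr)
        except RuntimeError:
            pse, thr, ok = float("nan"), float("nan"), False
    else:
        raise ValueError(f"unknown fit method {method!r}")
    converged = bool(
        ok
        and np.isfinite(pse)
        and thr > 0
        and span / thr > 0.1       # not flat over the sampled range
        and thr > span / 500.0     # not a step (complete separation)
    )
    return PsychometricFit(pse, thr, converged, method=method)


def bootstrap_pse_ci(
    data: PsychometricData,
    n_boot: int = 5000,
    rng: np.random.Generator | None = None,
    base_fit: PsychometricFit | None = None,
) -> PsychometricFit:
    """Percentile 95% CI on the PSE from per-level binomial resampling.

    Resamples ``n_clockwise`` at each level from its empirical proportion,
    refits every resample, and takes the 2.5/97.5 percentiles of the PSE.
    If more than 5% of the resamples fail to converge the CI is computed
    from the remainder and flagged.
    """
    rng = np.random.default_rng() if rng is None else rng
    fit = fit_logistic(data) if base_fit is None else base_fit
    if not fit.converged:
        raise ValueError("cannot bootstrap a non-converged base fit")
    x, n = data.levels, data.n_trials
    kb = rng.binomial(n[None, :], data.proportions[None, :], size=(n_boot, n.size))
    b0, b1, ok = _irls_batch(x, n, kb)
    span = float(x.max() - x.min())
    ok &= (b1 > 0) & (span * b1 > 0.1) & (b1 < 500.0 / span)
    if not ok.any():
        raise ValueError("no bootstrap resample converged")
    pses = -b0[ok] / b1[ok]
    lo, hi = np.percentile(pses, [2.5, 97.5])
    flagged = (1.0 - ok.mean()) > 0.05
    return replace(fit, ci_low=float(lo), ci_high=float(hi), ci_flagged=bool(flagged))


# ---------------------------------------------------------------------------
# the simulated observer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusParams:
    """How each interval's texture is generated and presented.

    ``mode`` is ``"static"`` (one frame, spatial sampling) or ``"dynamic"``
    (``n_frames`` frames, temporal sampling).  ``gain`` multiplies the bank's
    maximum rate (contrast-attenuation hook; 1 = full contrast).
    """

    mode: str = "static"
    n_lines: int = DEFAULT_N_LINES
    frame_duration: float = DEFAULT_FRAME_DURATION
    n_frames: int = DEFAULT_N_FRAMES
    dynamic_mode: str = COMMON_PER_FRAME
    contrast: float = 1.0
    gain: float = 1.0

    def __post_init__(self):
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")
        if not (0 < self.gain <= 1):
            raise ValueError("gain must be in (0, 1]")

    @property
    def total_duration(self) -> float:
        frames = 1 if self.mode == "static" else self.n_frames
        return frames * self.frame_duration


class SimulatedObserver:
    """Ideal observer: encode each interval, decode it, compare estimates.

    The ML decoder is "signal known exactly": its candidate set is the 180
    grid placements of the interval's own generating distribution (a point
    mass for the common-orientation standard).  Per-distribution candidate
    matrices are cached, so reuse one observer across the trials of a
    condition.
    """

    def __init__(self, bank: NeuronBank, decoder: str = "va", stimulus: StimulusParams | None = None):
        if decoder not in DECODERS:
            raise ValueError(f"unknown decoder {decoder!r}; choose from {DECODERS}")
        self.bank = bank
        self.decoder = decoder
        self.stimulus = StimulusParams() if stimulus is None else stimulus
        self._log_rates_cache: dict = {}

    # -- internals --------------------------------------------------------

    def _sample(self, dist: OrientationDistribution, rng, frame_duration=None):
        p = self.stimulus
        fd = p.frame_duration if frame_duration is None else frame_duration
        if p.mode == "static":
            return sample_static_texture(dist, p.n_lines, rng, fd, p.contrast)
        return sample_dynamic_texture(
            dist, p.n_frames, rng, p.dynamic_mode, p.n_lines, fd, p.contrast
        )

    def _ml_log_rates(self, dist: OrientationDistribution, duration: float) -> np.ndarray:
        key = (dist.support.tobytes(), dist.mass.tobytes(), round(duration, 9), self.stimulus.gain)
        if key not in self._log_rates_cache:
            self._log_rates_cache[key] = candidate_log_rates(
                self.bank, duration, template=dist, gain=self.stimulus.gain
            )
        return self._log_rates_cache[key]

    def estimate_interval(self, dist, rng, frame_duration=None):
        """Sample, encode and decode one interval; returns a DecoderEstimate."""
        tex = self._sample(dist, rng, frame_duration)
        resp = encode_stimulus(self.bank, tex, rng, self.stimulus.gain)
        if self.decoder == "va":
            return va_decode(self.bank, resp.spike_counts)
        if self.decoder == "wta":
            return wta_decode(self.bank, resp.spike_counts, rng)
        profile = loglik_profile(
            self.bank,
            resp.spike_counts,
            resp.duration,
            log_rates=self._ml_log_rates(dist, resp.duration),
        )
        return ml_decode(profile, rng)

    def _decision_variable(self, standard, comparison, rng):
        """Signed clockwise offset of the comparison estimate, or None."""
        delta = rng.uniform(0.0, 180.0)
        est_s = self.estimate_interval(standard.rotated(delta), rng)
        est_c = self.estimate_interval(comparison.rotated(delta), rng)
        if est_s.degenerate or est_c.degenerate:
            return None
        return float(signed_offset(est_c.estimate, est_s.estimate))

    # -- public API -------------------------------------------------------

    def trial(self, standard, comparison, rng) -> bool:
        """One 2AFC trial: True iff the comparison is judged more clockwise.

        The standard's orientation is re-randomized every trial; the
        comparison keeps its reference offset relative to the standard.
        Degenerate estimates, and exact ties between the two intervals'
        (grid-valued) estimates, resolve to a fair coin (forced choice);
        without the tie coin the discrete decoders acquire a spurious
        half-grid-step PSE bias.
        """
        d = self._decision_variable(standard, comparison, rng)
        if d is None or d == 0.0:
            return bool(rng.random() < 0.5)
        return d > 0


def simulate_2afc_trial(
    standard_dist: OrientationDistribution,
    comparison_dist: OrientationDistribution,
    decoder: str,
    bank: NeuronBank,
    stimulus_params: StimulusParams,
    rng: np.random.Generator,
) -> bool:
    """Functional wrapper around :meth:`SimulatedObserver.trial`."""
    return SimulatedObserver(bank, decoder, stimulus_params).trial(
        standard_dist, comparison_dist, rng
    )


def run_constant_stimuli(
    observer: SimulatedObserver,
    standard_dist: OrientationDistribution,
    comparison_dist: OrientationDistribution,
    rng: np.random.Generator,
    trials_per_level: int = 80,
    n_levels: int = 9,
    levels: np.ndarray | None = None,
    pilot_trials: int = 50,
) -> PsychometricData:
    """Method of constant stimuli: tally clockwise judgements per level.

    A level ``x`` rotates the comparison's reference ``x`` degrees clockwise
    relative to the standard.  When ``levels`` is not given, a pilot run at
    level 0 measures the decision variable directly; the levels are then
    ``n_levels`` points spanning the anticipated PSE +/- 3 pilot SDs (the
    defaults give 9 x 80 = 720 trials, the scale of one observer's data for
    one condition).
    """
    if levels is None:
        d = []
        while len(d) < pilot_trials:
            v = observer._decision_variable(standard_dist, comparison_dist, rng)
            if v is not None:
                d.append(v)
        d = np.asarray(d)
        center = -float(d.mean())
        spread = max(float(d.std()), 0.75)  # keep a usable span for near-deterministic decoders
        levels = center + np.linspace(-3.0 * spread, 3.0 * spread, n_levels)
    levels = np.asarray(levels, dtype=float)
    n = np.full(levels.size, trials_per_level, dtype=int)
    k = np.zeros(levels.size, dtype=int)
    for i, x in enumerate(levels):
        rotated = comparison_dist.rotated(x)
        k[i] = sum(observer.trial(standard_dist, rotated, rng) for _ in range(trials_per_level))
    return PsychometricData(levels, n, k)


def simulate_vertical_judgement(
    dist_at_vertical: OrientationDistribution,
    duration: float,
    decoder: str,
    bank: NeuronBank,
    n_trials: int,
    rng: np.random.Generator,
    gain: float = 1.0,
    n_lines: int = DEFAULT_N_LINES,
) -> float:
    """Single-interval task: proportion of trials judged clockwise of vertical.

    A static texture drawn from ``dist_at_vertical`` (whose reference places
    it near 90 deg) is shown for ``duration`` seconds; the decoded estimate
    is compared against implicit vertical.  Degenerate estimates resolve to
    a fair coin.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    params = StimulusParams(mode="static", n_lines=n_lines, frame_duration=duration, gain=gain)
    observer = SimulatedObserver(bank, decoder, params)
    clockwise = 0
    for _ in range(n_trials):
        est = observer.estimate_interval(dist_at_vertical, rng)
        d = None if est.degenerate else float(signed_offset(est.estimate, 90.0))
        if d is None or d == 0.0:  # forced choice on a degenerate or tied estimate
            clockwise += rng.random() < 0.5
        elif d > 0:
            clockwise += 1
    return clockwise / n_trials
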