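"""Read-outs of an orientation estimate from population spike counts.

Three decoders are provided:

* **ML** — maximum likelihood over a grid of candidate stimuli.  The log
  likelihood of candidate ``c`` is the weighted sum ``sum_i n_i log R_i(c)``;
  the terms ``-R_i(c)`` and ``-log n_i!`` of the full Poisson log likelihood
  are dropped because on an evenly spaced, circularly wrapped bank both are
  exactly candidate-independent (``include_rate_term=True`` restores the rate
  term).  Candidates are either the single grid orientations (default) or,
  when a ``template`` distribution is supplied, the grid placements of that
  distribution — the "signal known exactly" decoder an ideal observer uses
  when the generating distribution is known.
* **WTA** — winner-takes-all: preferred orientation of the most active neuron.
* **VA** — vector average: the response-weighted mean of the preferred
  orientations.  On axial data a plain weighted mean is seam-broken and the
  doubled-angle circular resultant under-weights the tails of broad
  profiles, so the estimate is computed as the arithmetic weighted mean of
  preferred orientations unwrapped about the doubled-angle resultant,
  iterated to a fixed point.  This is rotation-equivariant and preserves the
  linear mean of the response profile (hence of the stimulus, since the
  tuning convolution is symmetric).

Ties are broken uniformly at random with the supplied generator; flat or
all-zero inputs yield an estimate flagged as degenerate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._angles import signed_offset, wrap_orientation
from .distributions import OrientationDistribution
from .encoding import NeuronBank, stimulus_proportions

__all__ = [
    "LikelihoodProfile",
    "DecoderEstimate",
    "candidate_log_rates",
    "loglik_profile",
    "ml_decode",
    "wta_decode",
    "va_decode",
]

_TIE_RTOL = 1e-12


@dataclass(frozen=True)
class LikelihoodProfile:
    """Log likelihood of each candidate orientation (arbitrary offset)."""

    candidates: np.ndarray
    loglik: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.candidates, dtype=float)
        ll = np.asarray(self.loglik, dtype=float)
        object.__setattr__(self, "candidates", c)
        object.__setattr__(self, "loglik", ll)
        if c.shape != ll.shape or c.ndim != 1:
            raise ValueError("candidates and loglik must be aligned 1-D arrays")
        if not np.all(np.isfinite(ll)):
            raise ValueError("non-finite log likelihood (is rate_floor > 0?)")

    @property
    def is_flat(self) -> bool:
        span = self.loglik.max() - self.loglik.min()
        return span <= _TIE_RTOL * max(1.0, abs(self.loglik.max()))


@dataclass(frozen=True)
class DecoderEstimate:
    """Orientation estimate in ``[0, 180)`` with its decoder name."""

    estimate: float
    decoder: str
    degenerate: bool = False


def candidate_log_rates(
    bank: NeuronBank,
    duration: float = 1.0,
    template: OrientationDistribution | None = None,
    gain: float = 1.0,
) -> np.ndarray:
    """``log R_i(c)`` matrix, shape ``(n_neurons, n_candidates)``.

    Candidate ``c`` is grid orientation ``bank.grid[c]``: either a single
    line at that orientation (``template=None``) or the ``template``
    distribution placed with its reference there.  Precompute this once when
    decoding many trials of the same stimulus family.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    S = bank.sensitivity_matrix()
    if template is None:
        rates = bank.r_max * gain * duration * S
    else:
        prop = stimulus_proportions(
            OrientationDistribution(template.support, template.mass, 0.0), bank
        )
        profile = bank.r_max * gain * duration * (S @ prop)
        n = bank.n_neurons
        idx = (np.arange(n)[:, None] - np.arange(n)[None, :]) % n
        rates = profile[idx]
    return np.log(np.maximum(rates, bank.rate_floor * duration))


def loglik_profile(
    bank: NeuronBank,
    spike_counts: np.ndarray,
    duration: float = 1.0,
    template: OrientationDistribution | None = None,
    include_rate_term: bool = False,
    log_rates: np.ndarray | None = None,
) -> LikelihoodProfile:
    """Log likelihood of every candidate given the observed spike counts.

    The argmax is invariant to ``duration`` (it shifts every candidate by the
    same constant) and, on an evenly spaced wrapped bank, to
    ``include_rate_term``.  Pass a precomputed ``log_rates`` matrix from
    :func:`candidate_log_rates` to skip rebuilding it per trial.
    """
    n = np.asarray(spike_counts, dtype=float)
    if n.shape != (bank.n_neurons,):
        raise ValueError("spike_counts must have one entry per neuron")
    if log_rates is None:
        log_rates = candidate_log_rates(bank, duration, template)
    ll = n @ log_rates
    if include_rate_term:
        ll = ll - np.exp(log_rates).sum(axis=0)
    return LikelihoodProfile(bank.grid.copy(), ll)


def _argmax_with_ties(values: np.ndarray, rng: np.random.Generator | None) -> int:
    top = values.max()
    ties = np.flatnonzero(values >= top - _TIE_RTOL * max(1.0, abs(top)))
    if ties.size == 1 or rng is None:
        return int(ties[0])
    return int(rng.choice(ties))


def ml_decode(profile: LikelihoodProfile, rng: np.random.Generator | None = None) -> DecoderEstimate:
    """Candidate with maximal log likelihood; ties broken at random."""
    if profile.is_flat:
        return DecoderEstimate(float("nan"), "ml", degenerate=True)
    i = _argmax_with_ties(profile.loglik, rng)
    return DecoderEstimate(float(profile.candidates[i]), "ml")


def wta_decode(
    bank: NeuronBank,
    spike_counts: np.ndarray,
    rng: np.random.Generator | None = None,
) -> DecoderEstimate:
    """Preferred orientation of the most active neuron."""
    n = np.asarray(spike_counts, dtype=float)
    if n.max() <= n.min():
        return DecoderEstimate(float("nan"), "wta", degenerate=True)
    i = _argmax_with_ties(n, rng)
    return DecoderEstimate(float(bank.preferred[i]), "wta")


def _axial_resultant(bank: NeuronBank, weights: np.ndarray):
    ang = np.deg2rad(2.0 * bank.preferred)
    s = float(np.dot(weights, np.sin(ang)))
    c = float(np.dot(weights, np.cos(ang)))
    length = np.hypot(s, c) / max(weights.sum(), np.finfo(float).tiny)
    return (np.degrees(np.arctan2(s, c)) / 2.0) % 180.0, length


def va_decode(
    bank: NeuronBank,
    spike_counts: np.ndarray,
    method: str = "unwrapped-mean",
    max_iter: int = 50,
) -> DecoderEstimate:
    """Response-weighted average of the preferred orientations.

    ``method="unwrapped-mean"`` (default) returns the fixed point of the
    arithmetic weighted mean computed on offsets unwrapped to (-90, +90]
    about the current center, initialized at the doubled-angle resultant;
    ``method="resultant"`` returns the doubled-angle resultant itself.
    Degenerate when all counts are equal (zero resultant for a uniform
    profile).
    """
    w = np.asarray(spike_counts, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0 or w.max() <= w.min():
        return DecoderEstimate(float("nan"), "va", degenerate=True)
    center, length = _axial_resultant(bank, w)
    if length < 1e-9:
        return DecoderEstimate(float("nan"), "va", degenerate=True)
    if method == "resultant":
        return DecoderEstimate(center, "va")
    if method != "unwrapped-mean":
        raise ValueError(f"unknown VA method {method!r}")
    for _ in range(max_iter):
        offsets = signed_offset(bank.preferred, center)
        new = float(wrap_orientation(center + np.dot(w, offsets) / w.sum()))
        if abs(new - center) < 1e-10:
            center = new
            break
        center = new
    return DecoderEstimate(center, "va")
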