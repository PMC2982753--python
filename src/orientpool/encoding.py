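"""Poisson encoding of texture stimuli by a bank of orientation-tuned neurons.

The bank has ``n`` evenly spaced preferred orientations on ``[0, 180)``
(default 180 at 1 deg).  A neuron's sensitivity to orientation ``theta`` is a
Gaussian of the wrapped axial distance ``d`` to its preferred orientation,

    S_i(theta) = exp(-(d / h)^2 ln 2),

so the bandwidth ``h`` is the half-width at half-height (default 22.5 deg).
The mean spike count of neuron ``i`` over an interval of duration ``t`` is

    R_i = R_max * t * sum_theta S_i(theta) * pr(theta),

where ``pr`` is the proportion of stimulus orientations in each 1-deg bin,
and the observed counts are independent Poisson draws with those means.
Mean counts are floored at ``rate_floor * t`` so that log rates downstream
stay finite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._angles import axial_distance, wrap_orientation
from .distributions import OrientationDistribution
from .stimuli import TextureStimulus

__all__ = [
    "NeuronBank",
    "PopulationResponse",
    "tuning_sensitivity",
    "stimulus_proportions",
    "mean_response",
    "sample_spikes",
    "encode_stimulus",
]


def _default_preferred() -> np.ndarray:
    return np.arange(180.0)


@dataclass(frozen=True)
class NeuronBank:
    """Evenly spaced orientation-tuned neurons.

    Parameters
    ----------
    preferred
        Preferred orientations in degrees; must be evenly spaced on [0, 180).
    bandwidth
        Tuning half-width at half-height ``h``, degrees.
    r_max
        Maximum mean firing rate, spikes/s.
    rate_floor
        Small positive rate (spikes/s) that floors every mean response, so
        log likelihoods are finite; 0 disables the floor.
    """

    preferred: np.ndarray = field(default_factory=_default_preferred)
    bandwidth: float = 22.5
    r_max: float = 60.0
    rate_floor: float = 0.01

    def __post_init__(self):
        pref = np.asarray(self.preferred, dtype=float)
        object.__setattr__(self, "preferred", pref)
        if pref.ndim != 1 or pref.size < 2:
            raise ValueError("need at least two preferred orientations")
        steps = np.diff(pref)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("preferred orientations must be evenly spaced and increasing")
        if np.any(pref < 0) or np.any(pref >= 180.0):
            raise ValueError("preferred orientations must lie in [0, 180)")
        if self.bandwidth <= 0 or self.r_max <= 0 or self.rate_floor < 0:
            raise ValueError("bandwidth and r_max must be > 0, rate_floor >= 0")

    @property
    def n_neurons(self) -> int:
        return self.preferred.size

    @property
    def grid(self) -> np.ndarray:
        """Stimulus orientation grid (same as the preferred orientations)."""
        return self.preferred

    def sensitivity_matrix(self) -> np.ndarray:
        """``S[i, j] = S_i(grid[j])``; symmetric for the default 1-deg grid."""
        cached = self.__dict__.get("_sens")
        if cached is None:
            d = axial_distance(self.preferred[:, None], self.grid[None, :])
            cached = np.exp(-((d / self.bandwidth) ** 2) * np.log(2.0))
            object.__setattr__(self, "_sens", cached)
        return cached


@dataclass(frozen=True)
class PopulationResponse:
    """Mean and sampled spike counts of the bank over one stimulus interval."""

    mean_counts: np.ndarray
    spike_counts: np.ndarray
    duration: float

    def __post_init__(self):
        mc = np.asarray(self.mean_counts, dtype=float)
        sc = np.asarray(self.spike_counts)
        object.__setattr__(self, "mean_counts", mc)
        object.__setattr__(self, "spike_counts", sc)
        if mc.shape != sc.shape:
            raise ValueError("mean_counts and spike_counts must be aligned")
        if np.any(mc < 0) or np.any(sc < 0):
            raise ValueError("counts must be non-negative")

    def to_dataframe(self, bank: NeuronBank) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "neuron": np.arange(bank.n_neurons),
                "preferred_deg": bank.preferred,
                "mean_count": self.mean_counts,
                "spike_count": self.spike_counts,
            }
        )


def tuning_sensitivity(bank: NeuronBank, theta: float) -> np.ndarray:
    """Sensitivities ``S_i(theta)`` of every neuron to a single orientation."""
    d = axial_distance(bank.preferred, theta)
    return np.exp(-((d / bank.bandwidth) ** 2) * np.log(2.0))


def stimulus_proportions(
    stimulus: TextureStimulus | OrientationDistribution,
    bank: NeuronBank | None = None,
    frame: int | None = None,
) -> np.ndarray:
    """Proportion of stimulus orientations in each grid bin (sums to 1).

    Texture orientations (pooled over frames, or one ``frame``) are binned to
    the nearest grid orientation; a distribution's masses are re-binned the
    same way.  The default grid is 180 bins at 1 deg.
    """
    n = 180 if bank is None else bank.n_neurons
    spacing = 180.0 / n
    if isinstance(stimulus, OrientationDistribution):
        oris = stimulus.absolute_support
        weights = stimulus.mass
    else:
        oris = stimulus.frames[frame] if frame is not None else stimulus.pooled_orientations()
        if oris.size == 0:
            raise ValueError("empty stimulus frame")
        weights = np.full(oris.size, 1.0 / oris.size)
    idx = np.rint(wrap_orientation(oris) / spacing).astype(int) % n
    prop = np.zeros(n)
    np.add.at(prop, idx, weights)
    return prop


def mean_response(
    bank: NeuronBank,
    proportions: np.ndarray,
    duration: float,
    gain: float = 1.0,
) -> np.ndarray:
    """Expected spike counts ``R_i`` for a stimulus interval of ``duration`` s.

    ``gain`` multiplies ``r_max`` (hook for contrast attenuation; 1 = full
    contrast).  The result is floored at ``rate_floor * duration``.
    """
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not (0 < gain <= 1):
        raise ValueError("gain must be in (0, 1]")
    rates = bank.r_max * gain * duration * (bank.sensitivity_matrix() @ proportions)
    return np.maximum(rates, bank.rate_floor * duration)


def sample_spikes(mean_counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson spike counts with the given means."""
    mean_counts = np.asarray(mean_counts, dtype=float)
    if np.any(mean_counts < 0):
        raise ValueError("mean counts must be >= 0")
    return rng.poisson(mean_counts)


def encode_stimulus(
    bank: NeuronBank,
    stimulus: TextureStimulus,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> PopulationResponse:
    """Encode a texture: per-frame Poisson counts summed over frames.

    Each frame is encoded for ``frame_duration`` seconds and the counts are
    summed across frames, which by Poisson additivity equals a single draw
    with the summed means.
    """
    S = bank.sensitivity_matrix()
    total_mean = np.zeros(bank.n_neurons)
    for f in range(stimulus.n_frames):
        prop = stimulus_proportions(stimulus, bank, frame=f)
        rates = bank.r_max * gain * stimulus.frame_duration * (S @ prop)
        total_mean += np.maximum(rates, bank.rate_floor * stimulus.frame_duration)
    counts = sample_spikes(total_mean, rng)
    return PopulationResponse(total_mean, counts, stimulus.total_duration)
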