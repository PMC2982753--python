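"""Skewed orientation distributions for texture stimuli.

The experiments are parameterized by discrete probability distributions over
orientation *offsets* relative to a reference orientation.  Two families are
provided:

* piecewise ("split") Gaussians whose clockwise and counter-clockwise halves
  have different standard deviations and sampling intervals, and
* skewed uniforms whose halves have different ranges.

Offsets are signed degrees, negative = counter-clockwise, and the reference
is an absolute orientation on the ``[0, 180)`` axis.  Both families can weight
the two halves either in proportion to their standard deviations
("density-matched": the density is continuous at the mode) or with probability
mass 1/2 each ("equal-mass": the junction point is the median by
construction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._angles import wrap_orientation

__all__ = [
    "OrientationDistribution",
    "SkewedGaussianSpec",
    "SkewedUniformSpec",
    "DistributionStats",
    "build_skewed_gaussian",
    "build_skewed_uniform",
    "distribution_stats",
]

_MASS_TOL = 1e-9

DENSITY_MATCHED = "density-matched"
EQUAL_MASS = "equal-mass"


@dataclass(frozen=True)
class OrientationDistribution:
    """Discrete distribution over orientation offsets around a reference.

    Parameters
    ----------
    support
        Strictly increasing offsets in degrees, contained in ``(-90, +90]``.
        Negative offsets are counter-clockwise of the reference.
    mass
        Probabilities aligned with ``support``; non-negative, summing to 1.
    reference
        Absolute orientation of the zero offset, in ``[0, 180)`` degrees.
    """

    support: np.ndarray
    mass: np.ndarray
    reference: float = 0.0

    def __post_init__(self):
        sup = np.asarray(self.support, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        object.__setattr__(self, "support", sup)
        object.__setattr__(self, "mass", m)
        object.__setattr__(self, "reference", float(self.reference) % 180.0)
        if sup.ndim != 1 or sup.shape != m.shape:
            raise ValueError("support and mass must be 1-D and aligned")
        if sup.size == 0:
            raise ValueError("empty support")
        if np.any(np.diff(sup) <= 0):
            raise ValueError("support must be strictly increasing")
        if sup[0] <= -90.0 or sup[-1] > 90.0:
            raise ValueError("support must lie in (-90, +90] degrees")
        if np.any(m < 0):
            raise ValueError("negative probability mass")
        if abs(m.sum() - 1.0) > _MASS_TOL:
            raise ValueError(f"masses sum to {m.sum()!r}, not 1")

    @classmethod
    def point_mass(cls, reference: float) -> "OrientationDistribution":
        """Distribution with all mass at the reference orientation."""
        return cls(np.array([0.0]), np.array([1.0]), reference)

    @property
    def absolute_support(self) -> np.ndarray:
        """Support mapped through the reference onto ``[0, 180)``."""
        return wrap_orientation(self.support + self.reference)

    def rotated(self, delta: float) -> "OrientationDistribution":
        """Same shape, reference rotated by ``delta`` degrees (clockwise > 0)."""
        return OrientationDistribution(self.support, self.mass, self.reference + delta)

    def mirrored(self) -> "OrientationDistribution":
        """Distribution with all offsets negated (CW and CCW halves swapped).

        An offset at exactly +90 maps to itself (same line on the axis).
        """
        sup = -self.support + 0.0
        sup[sup == -90.0] = 90.0
        order = np.argsort(sup)
        return OrientationDistribution(sup[order], self.mass[order], self.reference)

    def sample_offsets(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.choice(self.support, size=size, p=self.mass)

    def to_dict(self) -> dict:
        return {
            "support": self.support.tolist(),
            "mass": self.mass.tolist(),
            "reference": self.reference,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OrientationDistribution":
        return cls(np.asarray(d["support"]), np.asarray(d["mass"]), d.get("reference", 0.0))

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "OrientationDistribution":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class SkewedGaussianSpec:
    """Piecewise Gaussian over offsets: per-half SD, sampling step, truncation.

    ``sigma_ccw``/``sigma_cw`` are the standard deviations of the
    counter-clockwise and clockwise halves (degrees, >= 0; a zero-SD half is a
    point mass at the junction).  Each half is sampled on its own grid
    (``interval_*`` degrees) out to ``truncation_*`` degrees (<= 90).
    ``half_weighting`` is ``"density-matched"`` (half masses proportional to
    the side SDs) or ``"equal-mass"`` (each half carries mass 1/2).
    """

    sigma_ccw: float
    sigma_cw: float
    interval_ccw: float = 2.5
    interval_cw: float = 2.5
    truncation_ccw: float = 45.0
    truncation_cw: float = 45.0
    half_weighting: str = DENSITY_MATCHED

    def __post_init__(self):
        if self.sigma_ccw < 0 or self.sigma_cw < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.sigma_ccw + self.sigma_cw <= 0 and self.half_weighting == EQUAL_MASS:
            raise ValueError("equal-mass weighting is undefined with both halves at sigma = 0")
        if self.sigma_ccw + self.sigma_cw <= 0:
            raise ValueError("at least one half must have sigma > 0")
        if self.interval_ccw <= 0 or self.interval_cw <= 0:
            raise ValueError("sampling intervals must be > 0")
        if not (0 < self.truncation_ccw <= 90 and 0 < self.truncation_cw <= 90):
            raise ValueError("truncations must be in (0, 90] degrees")
        if self.interval_ccw > self.truncation_ccw or self.interval_cw > self.truncation_cw:
            raise ValueError("sampling interval exceeds the half's truncation")
        if self.half_weighting not in (DENSITY_MATCHED, EQUAL_MASS):
            raise ValueError(f"unknown half_weighting {self.half_weighting!r}")


@dataclass(frozen=True)
class SkewedUniformSpec:
    """Skewed uniform over offsets: per-half range, common sampling interval.

    Each half carries total mass 1/2, spread uniformly over its grid points,
    so the junction (offset 0, which is *not* itself a support point) is the
    median by construction.
    """

    range_ccw: float
    range_cw: float
    interval: float = 2.5

    def __post_init__(self):
        if self.range_ccw <= 0 or self.range_cw <= 0:
            raise ValueError("ranges must be > 0")
        if self.range_ccw + self.range_cw > 180.0:
            raise ValueError("total range exceeds 180 degrees")
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.interval > min(self.range_ccw, self.range_cw):
            raise ValueError("interval exceeds the smaller half range")


class DistributionStats(NamedTuple):
    mean: float
    median: float
    mode: float


def _half_gaussian(sigma: float, interval: float, truncation: float):
    """Grid ``0, interval, ..., <= truncation`` and normalized half weights."""
    x = np.arange(0.0, truncation + 1e-9, interval)
    if sigma == 0.0:
        w = np.zeros_like(x)
        w[0] = 1.0
    else:
        w = np.exp(-(x**2) / (2.0 * sigma**2))
    return x, w / w.sum()


def build_skewed_gaussian(spec: SkewedGaussianSpec, reference: float = 0.0) -> OrientationDistribution:
    """Build the piecewise-Gaussian offset distribution of ``spec``.

    Each half is a half-Gaussian (including the junction point 0) normalized
    within the half, then the halves are weighted according to
    ``spec.half_weighting``.  The junction appears once in the support and
    accumulates both halves' contributions.
    """
    x_ccw, w_ccw = _half_gaussian(spec.sigma_ccw, spec.interval_ccw, spec.truncation_ccw)
    x_cw, w_cw = _half_gaussian(spec.sigma_cw, spec.interval_cw, spec.truncation_cw)
    # -90 and +90 are the same line; the seam point belongs to the CW half
    keep = x_ccw < 90.0
    if not keep.all():
        x_ccw, w_ccw = x_ccw[keep], w_ccw[keep] / w_ccw[keep].sum()
    if spec.half_weighting == DENSITY_MATCHED:
        total = spec.sigma_ccw + spec.sigma_cw
        a_ccw, a_cw = spec.sigma_ccw / total, spec.sigma_cw / total
    else:
        a_ccw = a_cw = 0.5
    acc: dict[float, float] = {}
    for x, w in zip(-x_ccw, a_ccw * w_ccw):
        acc[x + 0.0] = acc.get(x + 0.0, 0.0) + w
    for x, w in zip(x_cw, a_cw * w_cw):
        acc[x + 0.0] = acc.get(x + 0.0, 0.0) + w
    support = np.array(sorted(acc))
    mass = np.array([acc[x] for x in support])
    keep = mass > 0  # a sigma = 0 half contributes a point mass at 0 only
    support, mass = support[keep], mass[keep]
    return OrientationDistribution(support, mass / mass.sum(), reference)


def build_skewed_uniform(spec: SkewedUniformSpec, reference: float = 0.0) -> OrientationDistribution:
    """Build the skewed-uniform offset distribution of ``spec``.

    Support is ``-range_ccw, ..., -interval`` and ``+interval, ..., +range_cw``
    (the junction 0 is excluded); each half carries mass 1/2 uniformly.
    """
    ccw = -np.arange(spec.interval, spec.range_ccw + 1e-9, spec.interval)[::-1]
    cw = np.arange(spec.interval, spec.range_cw + 1e-9, spec.interval)
    support = np.concatenate([ccw, cw])
    mass = np.concatenate(
        [np.full(ccw.size, 0.5 / ccw.size), np.full(cw.size, 0.5 / cw.size)]
    )
    return OrientationDistribution(support, mass, reference)


def distribution_stats(dist: OrientationDistribution) -> DistributionStats:
    """Mean, median and mode of the offset distribution, in degrees.

    Linear (non-circular) arithmetic is valid because the support spans less
    than 180 degrees.  The median is the smallest support point where the
    cumulative mass reaches 0.5; if it reaches 0.5 *exactly* there, the median
    is the midpoint between that point and the next (so an equal-mass split
    about an excluded junction point yields the junction).  Mode ties are
    broken toward the support point nearest 0.
    """
    mean = float(np.dot(dist.support, dist.mass))
    cum = np.cumsum(dist.mass)
    i = int(np.searchsorted(cum, 0.5 - _MASS_TOL))
    if abs(cum[i] - 0.5) <= _MASS_TOL and i + 1 < dist.support.size:
        median = float(0.5 * (dist.support[i] + dist.support[i + 1]))
    else:
        median = float(dist.support[i])
    peak = dist.mass.max()
    ties = dist.support[dist.mass >= peak - _MASS_TOL]
    mode = float(ties[np.argmin(np.abs(ties))])
    return DistributionStats(mean, median, mode)
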