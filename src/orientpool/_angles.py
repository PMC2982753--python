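"""Angle arithmetic on the axial (180-degree periodic) orientation space.

Conventions used throughout the package:

* orientations are in degrees on the half-open axis ``[0, 180)``;
* signed offsets live in ``(-90, +90]``;
* positive offsets are *clockwise*, negative offsets counter-clockwise.

A line at 0 deg is the same line as one at 180 deg, so every difference is
wrapped onto the half circle before it is interpreted.
"""

from __future__ import annotations

import numpy as np

PERIOD = 180.0


def wrap_orientation(theta):
    """Map angles (degrees) onto the axial space ``[0, 180)``."""
    return np.asarray(theta, dtype=float) % PERIOD


def signed_offset(a, b):
    """Signed axial difference ``a - b`` wrapped to ``(-90, +90]`` degrees.

    Positive values mean ``a`` is clockwise of ``b``.  Antisymmetric except
    at the +/-90 boundary, where +90 is returned for both orders.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % PERIOD
    return -((-d + 90.0) % PERIOD - 90.0)


def axial_distance(a, b):
    """Unsigned axial distance in ``[0, 90]`` degrees."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % PERIOD
    return np.minimum(d, PERIOD - d)
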