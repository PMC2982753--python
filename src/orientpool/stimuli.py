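"""Texture stimuli: static and dynamic line patterns sampled from a distribution.

A texture is represented purely by the orientations of its lines (one list
per frame); spatial layout and luminance profiles are not modeled.  Static
textures are a single 500-line frame shown for one 0.052 s video frame;
dynamic textures are 25 consecutive frames (1.3 s total), with orientations
sampled over time instead of space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._angles import wrap_orientation
from .distributions import OrientationDistribution

__all__ = ["TextureStimulus", "sample_static_texture", "sample_dynamic_texture"]

DEFAULT_N_LINES = 500
DEFAULT_FRAME_DURATION = 0.052  # seconds per image at 18.75 Hz
DEFAULT_N_FRAMES = 25

COMMON_PER_FRAME = "common-per-frame"
PER_LINE = "per-line"


@dataclass(frozen=True)
class TextureStimulus:
    """One or more frames of per-line orientations.

    ``frames`` has shape ``(n_frames, n_lines)`` (a frame whose lines share a
    single common orientation may be stored with ``n_lines == 1``); absolute
    orientations in ``[0, 180)`` degrees.
    """

    frames: np.ndarray
    frame_duration: float = DEFAULT_FRAME_DURATION
    contrast: float = 1.0

    def __post_init__(self):
        f = np.atleast_2d(np.asarray(self.frames, dtype=float))
        if np.any(f < 0) or np.any(f >= 180.0):
            raise ValueError("orientations must lie in [0, 180) degrees")
        object.__setattr__(self, "frames", f)
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")
        if not (0 < self.contrast <= 1):
            raise ValueError("contrast must be in (0, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_lines(self) -> int:
        return self.frames.shape[1]

    @property
    def total_duration(self) -> float:
        return self.n_frames * self.frame_duration

    def pooled_orientations(self) -> np.ndarray:
        """All line orientations collapsed over frames."""
        return self.frames.ravel()

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format table (frame, line, orientation_deg) for inspection."""
        n_f, n_l = self.frames.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_l),
                "line": np.tile(np.arange(n_l), n_f),
                "orientation_deg": self.frames.ravel(),
            }
        )


def sample_static_texture(
    dist: OrientationDistribution,
    n_lines: int = DEFAULT_N_LINES,
    rng: np.random.Generator | None = None,
    frame_duration: float = DEFAULT_FRAME_DURATION,
    contrast: float = 1.0,
) -> TextureStimulus:
    """Single-frame texture: each line drawn i.i.d. from ``dist``."""
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    offsets = dist.sample_offsets(n_lines, rng)
    return TextureStimulus(
        wrap_orientation(offsets + dist.reference)[None, :], frame_duration, contrast
    )


def sample_dynamic_texture(
    dist: OrientationDistribution,
    n_frames: int = DEFAULT_N_FRAMES,
    rng: np.random.Generator | None = None,
    mode: str = COMMON_PER_FRAME,
    n_lines: int = DEFAULT_N_LINES,
    frame_duration: float = DEFAULT_FRAME_DURATION,
    contrast: float = 1.0,
) -> TextureStimulus:
    """Multi-frame texture with orientations sampled over time.

    In ``common-per-frame`` mode (default) every frame draws one orientation
    shared by all of its lines — the temporal analogue of one draw per line;
    in ``per-line`` mode each line of each frame is drawn independently.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    if mode == COMMON_PER_FRAME:
        offsets = dist.sample_offsets(n_frames, rng)[:, None]
    elif mode == PER_LINE:
        offsets = dist.sample_offsets((n_frames, n_lines), rng)
    else:
        raise ValueError(f"unknown sampling mode {mode!r}")
    return TextureStimulus(
        wrap_orientation(offsets + dist.reference), frame_duration, contrast
    )
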