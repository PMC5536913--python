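"""Core data containers shared across the pipeline.

Coordinate conventions, stated once and used everywhere:

* Egg length is normalised to [0, 1], anterior pole at 0, posterior at 1.
* Dorsal is the top edge of the image (smaller row indices).
* A space-time matrix has AP positions along rows (anterior first) and
  acquisition frames along columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpaceTimeMatrix:
    """Matrix of dorsal anteroposterior intensity profiles over time.

    Each column is the dorsal AP profile of one movie frame; each row
    follows one fractional egg-length position through time.

    Parameters
    ----------
    values : ndarray, shape (n_positions, n_frames)
        Nonnegative intensities in arbitrary units.
    positions : ndarray, shape (n_positions,)
        Strictly increasing fractional egg length on [0, 1],
        anterior to posterior.
    times : ndarray, shape (n_frames,)
        Minutes from the first frame, in acquisition order.
    side : str
        Which side of the embryo the profiles sample; only "dorsal"
        is produced by this package.
    """

    values: np.ndarray
    positions: np.ndarray
    times: np.ndarray
    side: str = "dorsal"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (positions x frames)")
        n_pos, n_frames = self.values.shape
        if n_pos < 16:
            raise ValueError("need at least 16 AP positions")
        if self.positions.shape != (n_pos,):
            raise ValueError("positions length must match number of rows")
        if self.times.shape != (n_frames,):
            raise ValueError("times length must match number of columns")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class EmbryoMovie:
    """Single-channel time-lapse stack of one trapped embryo.

    frames has shape (time, rows, cols); the frame interval is uniform.
    """

    frames: np.ndarray
    frame_interval: float = 30.0  # seconds
    pixel_size: float = 1.0  # arbitrary units

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be 3-D (time x rows x cols)")
        if self.frames.shape[0] < 2:
            raise ValueError("movie needs at least 2 frames")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_minutes(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval / 60.0


@dataclass
class EmbryoGeometry:
    """Elliptical embryo outline in pixel coordinates.

    The AP axis is the major axis; `anterior` and `posterior` are its
    endpoints on the ellipse boundary, as (row, col) pairs.
    """

    center: tuple[float, float]  # (row, col)
    semi_major: float
    semi_minor: float
    angle: float  # radians, major axis vs. image column axis, CCW
    anterior: tuple[float, float] = field(default=None)  # type: ignore[assignment]
    posterior: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.semi_major < self.semi_minor:
            raise ValueError("major axis must be at least the minor axis")
        if self.semi_minor <= 0:
            raise ValueError("axes must be positive")
        if self.anterior is None or self.posterior is None:
            r0, c0 = self.center
            dr = np.sin(self.angle) * self.semi_major
            dc = np.cos(self.angle) * self.semi_major
            # default polarity: anterior at the lower-column end
            self.anterior = (r0 - dr, c0 - dc)
            self.posterior = (r0 + dr, c0 + dc)

    def axis_unit(self) -> np.ndarray:
        """Unit vector (row, col) pointing anterior -> posterior."""
        v = np.subtract(self.posterior, self.anterior)
        return v / np.linalg.norm(v)

    def flipped(self) -> "EmbryoGeometry":
        """Same ellipse with AP polarity reversed."""
        return EmbryoGeometry(
            center=self.center,
            semi_major=self.semi_major,
            semi_minor=self.semi_minor,
            angle=self.angle,
            anterior=self.posterior,
            posterior=self.anterior,
        )
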