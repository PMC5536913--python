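"""Mitotic-dip detection and cross-embryo alignment.

Nuclear divisions empty the nuclei of Cic, so the projected temporal
amplitude dips to near zero at every mitosis.  Embryos are aligned by
shifting each time axis so the dip at the 13th division sits at t = 0,
after which point-wise ensemble statistics and the cycle-14 plateau
amplitude are well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks


class DipDetectionError(RuntimeError):
    """No mitotic dips found; alignment is impossible."""


@dataclass
class DivisionEvents:
    """Detected mitotic dips and the nuclear-cycle labels between them.

    ``cycle_labels[i]`` labels the interval that *follows* ``dip_frames[i]``;
    the last interval is nuclear cycle 14 (movies run to gastrulation, so
    the final detected dip is the 13th division).
    """

    dip_frames: np.ndarray
    cycle_labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dip_frames = np.asarray(self.dip_frames, dtype=int)
        if self.dip_frames.size == 0:
            raise DipDetectionError("no dips")
        if np.any(np.diff(self.dip_frames) <= 0):
            raise ValueError("dip_frames must be strictly increasing")
        if self.cycle_labels is None:
            n = self.dip_frames.size
            self.cycle_labels = np.arange(14 - n + 1, 15)
        self.cycle_labels = np.asarray(self.cycle_labels, dtype=int)
        if self.cycle_labels[-1] != 14:
            raise ValueError("last inter-dip interval must be cycle 14")

    @property
    def thirteenth_division_frame(self) -> int:
        """Frame of the dip at the 13th division (entry into cycle 14)."""
        return int(self.dip_frames[-1])


@dataclass
class GenotypeEnsemble:
    """Per-genotype aligned amplitudes on a common grid, t=0 at the
    13th division; point-wise statistics only where >= 2 embryos overlap."""

    genotype: str
    aligned_times: np.ndarray
    aligned_amplitudes: np.ndarray  # (n_embryos, n_grid), NaN where absent
    pointwise_mean: np.ndarray
    pointwise_sd: np.ndarray
    cycle14_mean_amplitudes: np.ndarray

    @property
    def n_embryos(self) -> int:
        return self.aligned_amplitudes.shape[0]


def detect_division_dips(
    amplitude: np.ndarray,
    times: np.ndarray | None = None,
    min_prominence: float = 0.15,
    smooth_window: int = 3,
) -> DivisionEvents:
    """Locate mitotic dips as prominent local minima of the amplitude.

    The amplitude is lightly smoothed with a ``smooth_window``-frame moving
    average, then minima with prominence at least
    ``min_prominence * max(amplitude)`` are kept.  The final dip is
    labelled the 13th division.
    """
    a = np.asarray(amplitude, dtype=float)
    if a.size < 20:
        raise ValueError("need at least 20 frames")
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(a, pad, mode="edge")
        a_s = np.convolve(padded, kernel, mode="valid")[: a.size]
    else:
        a_s = a
    prominence = min_prominence * a_s.max()
    idx, _ = find_peaks(-a_s, prominence=prominence)
    if idx.size == 0:
        raise DipDetectionError("no mitotic dips detected")
    # refine each dip to the raw-amplitude minimum in a +/-2 frame window
    refined = []
    for i in idx:
        lo, hi = max(0, i - 2), min(a.size, i + 3)
        refined.append(lo + int(np.argmin(a[lo:hi])))
    refined = np.unique(refined)
    return DivisionEvents(dip_frames=refined)


def align_at_13th_division(
    members: list[tuple[np.ndarray, DivisionEvents]],
    times: list[np.ndarray] | None = None,
    grid_step: float = 0.5,
    genotype: str = "",
    cycle14_window_start: float = 20.0,
) -> GenotypeEnsemble:
    """Shift every member so its 13th-division dip sits at t = 0 and
    resample (linear interpolation) onto a shared grid.

    The grid covers the union of the shifted time ranges at ``grid_step``
    minutes (default 0.5 min, the acquisition interval); samples outside a
    member's record are NaN.  Point-wise mean and SD use positions where
    at least two embryos overlap (NaN elsewhere).
    """
    if not members:
        raise ValueError("empty ensemble")
    shifted_t, amps = [], []
    for i, (amp, events) in enumerate(members):
        amp = np.asarray(amp, dtype=float)
        t = (
            np.asarray(times[i], dtype=float)
            if times is not None
            else np.arange(amp.size) * grid_step
        )
        t0 = t[events.thirteenth_division_frame]
        shifted_t.append(t - t0)
        amps.append(amp)
    t_min = min(t.min() for t in shifted_t)
    t_max = max(t.max() for t in shifted_t)
    # snap the grid to multiples of grid_step so t=0 is always on-grid
    grid = np.arange(np.floor(t_min / grid_step), np.round(t_max / grid_step) + 1)
    grid = grid * grid_step
    aligned = np.full((len(members), grid.size), np.nan)
    for i, (t, amp) in enumerate(zip(shifted_t, amps)):
        inside = (grid >= t.min() - 1e-9) & (grid <= t.max() + 1e-9)
        aligned[i, inside] = np.interp(grid[inside], t, amp)
    mean, sd, n_overlap = _pointwise_stats(aligned)
    c14 = []
    for i in range(len(members)):
        try:
            c14.append(_cycle14_mean(aligned[i], grid, cycle14_window_start))
        except ValueError:
            c14.append(np.nan)  # record too short for a plateau window
    c14 = np.asarray(c14)
    return GenotypeEnsemble(
        genotype=genotype,
        aligned_times=grid,
        aligned_amplitudes=aligned,
        pointwise_mean=mean,
        pointwise_sd=sd,
        cycle14_mean_amplitudes=c14,
    )


def _pointwise_stats(
    mat: np.ndarray, min_overlap: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise mean/SD over the non-NaN entries; NaN where fewer than
    ``min_overlap`` members overlap."""
    ok = ~np.isnan(mat)
    n = ok.sum(axis=0)
    filled = np.where(ok, mat, 0.0)
    mean = np.where(n >= 1, filled.sum(axis=0) / np.maximum(n, 1), np.nan)
    dev2 = np.where(ok, (mat - mean) ** 2, 0.0)
    with np.errstate(invalid="ignore"):
        sd = np.sqrt(dev2.sum(axis=0) / np.maximum(n - 1, 1))
    mean = np.where(n >= min_overlap, mean, np.nan)
    sd = np.where(n >= min_overlap, sd, np.nan)
    return mean, sd, n


def _cycle14_mean(amp: np.ndarray, t: np.ndarray, window_start: float) -> float:
    sel = (t >= window_start) & ~np.isnan(amp)
    if sel.sum() < 5:
        raise ValueError("fewer than 5 frames in the cycle-14 window")
    return float(np.mean(amp[sel]))


def cycle14_mean_amplitude(
    amplitude: np.ndarray,
    times: np.ndarray,
    events: DivisionEvents,
    window_start: float = 20.0,
) -> float:
    """Mean amplitude over the cycle-14 plateau window: from
    ``window_start`` minutes after the 13th-division dip to the end of the
    record.  The 20 min default skips the post-mitotic recovery transient
    so the metric reflects the plateau level."""
    amp = np.asarray(amplitude, dtype=float)
    t = np.asarray(times, dtype=float)
    t0 = t[events.thirteenth_division_frame]
    sel = t - t0 >= window_start
    if sel.sum() < 5:
        raise ValueError("fewer than 5 frames in the cycle-14 window")
    return float(np.mean(amp[sel]))
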