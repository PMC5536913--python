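"""Single-nucleus Cic traces and post-mitotic recovery kinetics.

After the 13th division, nuclear Cic re-accumulates with first-order
kinetics; each cycle-14 nucleus is summarised by

    I(t) = plateau * (1 - exp(-t / tau)),   t = 0 at the 13th division,

and the recovery is reported both as tau and as t_half = tau * ln 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from sklearn.base import BaseEstimator

from .alignment import DivisionEvents
from .containers import EmbryoGeometry, EmbryoMovie
from .extraction import _dorsal_frame


@dataclass
class NuclearTrace:
    """Intensity time series of one nucleus during a nuclear cycle."""

    nucleus_id: int
    position: float  # fractional egg length
    times: np.ndarray  # minutes from the 13th division
    intensities: np.ndarray
    cycle: int = 14

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")


@dataclass
class RecoveryEstimate:
    tau: float  # minutes
    plateau: float
    t_half: float  # tau * ln 2
    residual_rms: float
    converged: bool


class RecoveryFitError(RuntimeError):
    """Recovery fit failed (no signal or no convergence)."""


class ExponentialRecovery(BaseEstimator):
    """Saturating-exponential recovery fit, sklearn style.

    ``fit(times, intensities)`` estimates (plateau, tau) by least squares
    for t >= 0; fitted attributes ``tau_``, ``plateau_``, ``t_half_``,
    ``residual_rms_``, ``converged_``.
    """

    def __init__(self, min_frames: int = 10):
        self.min_frames = min_frames

    def fit(self, X, y=None):
        t = np.asarray(X, dtype=float).ravel()
        I = np.asarray(y, dtype=float).ravel()
        sel = t >= 0
        t, I = t[sel], I[sel]
        if t.size < self.min_frames:
            raise ValueError(f"need at least {self.min_frames} frames after t=0")
        peak = I.max()
        if peak <= 0:
            raise RecoveryFitError("trace has no signal above zero")
        # initial tau: time to reach 63% of the late-time level
        late = I[t >= 0.8 * t.max()].mean()
        if late <= 0:
            raise RecoveryFitError("plateau indistinguishable from zero")
        above = np.where(I >= (1 - np.exp(-1)) * late)[0]
        tau0 = float(t[above[0]]) if above.size and t[above[0]] > 0 else max(
            t[1], 1e-2
        )
        model = lambda tt, plateau, tau: plateau * (1.0 - np.exp(-tt / tau))  # noqa: E731
        try:
            popt, _ = curve_fit(
                model, t, I, p0=[late, tau0],
                bounds=([0.0, 1e-4], [np.inf, np.inf]), maxfev=20000,
            )
            converged = True
        except RuntimeError:
            raise RecoveryFitError("recovery fit did not converge")
        plateau, tau = map(float, popt)
        if plateau <= 0:
            raise RecoveryFitError("plateau indistinguishable from zero")
        resid = I - model(t, *popt)
        self.plateau_ = plateau
        self.tau_ = tau
        self.t_half_ = tau * np.log(2.0)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.converged_ = converged
        return self

    def predict(self, X):
        if not hasattr(self, "tau_"):
            raise AttributeError("ExponentialRecovery is not fitted")
        t = np.asarray(X, dtype=float)
        return self.plateau_ * (1.0 - np.exp(-t / self.tau_))

    def estimate_(self) -> RecoveryEstimate:
        return RecoveryEstimate(
            tau=self.tau_,
            plateau=self.plateau_,
            t_half=self.t_half_,
            residual_rms=self.residual_rms_,
            converged=self.converged_,
        )


def estimate_recovery(
    trace: NuclearTrace, events: DivisionEvents | None = None
) -> RecoveryEstimate:
    """First-order recovery estimate for one nuclear trace.

    Trace times are minutes from the 13th division already; when raw
    frame-indexed times are supplied, pass ``events`` so t=0 can be set
    at the 13th-division dip.
    """
    t = trace.times
    if events is not None:
        t = t - t[events.thirteenth_division_frame]
    est = ExponentialRecovery().fit(t, trace.intensities)
    return est.estimate_()


def extract_nuclear_traces(
    movie: EmbryoMovie,
    geometry: EmbryoGeometry,
    events: DivisionEvents,
    min_distance: int = 2,
    smooth_sigma: float = 1.0,
    max_nuclei: int | None = None,
    ap_range: tuple[float, float] = (0.28, 0.72),
) -> list[NuclearTrace]:
    """Detect cycle-14 nuclei in the dorsal band and read out their traces.

    Nuclei are found on a reference frame late in cycle 14 (bright,
    settled spots) as local maxima of a difference-of-Gaussian response
    above the Otsu brightness threshold with a minimum separation, then
    linked by position across frames (cycle-14 cortical nuclei do not
    move in this model).  The per-frame intensity is the mean over a disc
    of radius half the minimum inter-nucleus distance.  Detection is
    restricted to the mid-body ``ap_range``, away from the pole
    boundaries whose steep intensity gradients mimic blob responses.
    """
    t13 = events.thirteenth_division_frame
    n_after = movie.n_frames - t13
    if n_after < 10:
        raise ValueError("need at least 10 frames after the 13th division")
    ref_idx = t13 + int(0.8 * n_after)
    raw = movie.frames[ref_idx]
    ref = ndimage.gaussian_filter(raw, smooth_sigma)
    # difference-of-Gaussian response isolates nucleus-scale blobs from
    # the smooth tissue profile and from pixel noise
    dog = ref - ndimage.gaussian_filter(raw, 3.0 * max(smooth_sigma, 1.0))

    # restrict to the dorsal band region of the ellipse
    h, w = ref.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    r0, c0 = geometry.center
    a, b = geometry.semi_major, geometry.semi_minor
    e1, e2 = _dorsal_frame(geometry)
    u = (rr - r0) * e1[0] + (cc - c0) * e1[1]
    v = (rr - r0) * e2[0] + (cc - c0) * e2[1]
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    band = inside & (v > 0) & (v >= b * np.sqrt(
        np.clip(1.0 - (u / a) ** 2, 0.0, None)) - 0.2 * b)

    masked = np.where(band, dog, 0.0)
    # nuclei must be bright in absolute terms (above the in-ellipse Otsu
    # split) and stand out from the local tissue (DoG response)
    bright = ref > threshold_otsu(ref[inside]) if np.any(inside) else ref > 0
    peaks = peak_local_max(
        masked,
        min_distance=min_distance,
        threshold_abs=0.25 * masked.max(),
        exclude_border=False,
    )
    peaks = np.array([p for p in peaks if bright[p[0], p[1]]], dtype=int).reshape(-1, 2)
    # sub-pixel refinement: DoG-weighted centroid in a 5x5 neighbourhood
    refined = []
    for pr, pc in peaks:
        r_lo, r_hi = max(0, pr - 2), min(h, pr + 3)
        c_lo, c_hi = max(0, pc - 2), min(w, pc + 3)
        patch = np.clip(dog[r_lo:r_hi, c_lo:c_hi], 0.0, None)
        if patch.sum() <= 0:
            refined.append((float(pr), float(pc)))
            continue
        gr, gc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi), indexing="ij")
        refined.append(((patch * gr).sum() / patch.sum(), (patch * gc).sum() / patch.sum()))
    peaks = np.asarray(refined, dtype=float).reshape(-1, 2)
    # keep mid-body nuclei only
    if len(peaks):
        u_pk = (peaks[:, 0] - r0) * e1[0] + (peaks[:, 1] - c0) * e1[1]
        frac_pk = (u_pk + a) / (2.0 * a)
        keep = (frac_pk >= ap_range[0]) & (frac_pk <= ap_range[1])
        peaks = peaks[keep]
    if len(peaks) < 3:
        raise ValueError(f"only {len(peaks)} nuclei detected (need >= 3)")
    if max_nuclei is not None and len(peaks) > max_nuclei:
        order = np.argsort(masked[peaks[:, 0].astype(int), peaks[:, 1].astype(int)])[::-1]
        peaks = peaks[order[:max_nuclei]]
    # AP-sort the nuclei
    u_pk = (peaks[:, 0] - r0) * e1[0] + (peaks[:, 1] - c0) * e1[1]
    order = np.argsort(u_pk)
    peaks, u_pk = peaks[order], u_pk[order]

    if len(peaks) > 1:
        d = np.sqrt(((peaks[None, :, :] - peaks[:, None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        radius = max(1.0, d.min() / 2.0)
    else:
        radius = float(min_distance)

    disc_r, disc_c = np.meshgrid(
        np.arange(-int(radius), int(radius) + 1),
        np.arange(-int(radius), int(radius) + 1),
        indexing="ij",
    )
    disc = disc_r**2 + disc_c**2 <= radius**2
    times = (np.arange(movie.n_frames) - t13) * movie.frame_interval / 60.0

    traces = []
    for k, (pr, pc) in enumerate(peaks):
        rows = np.clip(int(round(pr)) + disc_r[disc], 0, h - 1)
        cols = np.clip(int(round(pc)) + disc_c[disc], 0, w - 1)
        intens = movie.frames[:, rows, cols].mean(axis=1)
        frac = float((u_pk[k] + a) / (2.0 * a))
        traces.append(
            NuclearTrace(
                nucleus_id=k,
                position=frac,
                times=times,
                intensities=np.clip(intens, 0.0, None),
            )
        )
    return traces


def mean_trace(
    traces: list[NuclearTrace], grid_step: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Point-wise mean and SD of a set of traces on a common time grid."""
    if len(traces) < 2:
        raise ValueError("need at least 2 traces")
    t_min = min(tr.times.min() for tr in traces)
    t_max = max(tr.times.max() for tr in traces)
    grid = np.arange(np.floor(t_min / grid_step), np.round(t_max / grid_step) + 1)
    grid = grid * grid_step
    mat = np.full((len(traces), grid.size), np.nan)
    for i, tr in enumerate(traces):
        sel = (grid >= tr.times.min() - 1e-9) & (grid <= tr.times.max() + 1e-9)
        mat[i, sel] = np.interp(grid[sel], tr.times, tr.intensities)
    from .alignment import _pointwise_stats

    mean, sd, n = _pointwise_stats(mat, min_overlap=1)
    sd = np.where(n >= 2, sd, np.nan)
    return grid, mean, sd
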