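"""Synthetic embryo generator.

Produces ground-truth-annotated kymographs, movies and single-nucleus
traces with the statistical structure the analysis pipeline assumes:
a separable product of a double-sigmoid anteroposterior Capicua profile
(low at both poles, uniform plateau through the mid-body) and a temporal
amplitude that collapses to near zero at every syncytial mitosis and
recovers with first-order kinetics through nuclear cycles 10-14.

Every generator is deterministic given its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .containers import EmbryoGeometry, EmbryoMovie, SpaceTimeMatrix

#: Per-cycle interphase plateau, as a fraction of the cycle-14 plateau.
#: Nuclear Cic rises from cycle to cycle as the protein accumulates.
CYCLE_AMPLITUDE_FRACTIONS = (0.40, 0.55, 0.70, 0.85, 1.00)


@dataclass(frozen=True)
class GenotypeParams:
    """Ground-truth parameters of one genetic background.

    plateau_amplitude : mid-body Cic plateau at the end of cycle 14
        (arbitrary intensity units).
    lambda_true : fractional egg length of the half-maximal anterior
        boundary (the quantity the Hill fit recovers).
    hill_coeff_true : boundary sharpness (dimensionless, > 0).
    recovery_tau : post-mitotic nuclear recovery timescale (minutes).
    pole_floor : residual Cic intensity at the poles.
    """

    name: str = "wt"
    plateau_amplitude: float = 100.0
    lambda_true: float = 0.12
    hill_coeff_true: float = 6.0
    recovery_tau: float = 3.0
    pole_floor: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.lambda_true < 0.4:
            raise ValueError("lambda_true must lie in (0, 0.4)")
        if not self.plateau_amplitude > self.pole_floor >= 0.0:
            raise ValueError("require plateau_amplitude > pole_floor >= 0")
        if self.recovery_tau <= 0.0:
            raise ValueError("recovery_tau must be positive")
        if self.hill_coeff_true <= 0.0:
            raise ValueError("hill_coeff_true must be positive")


@dataclass(frozen=True)
class CycleSchedule:
    """Timing of nuclear cycles 10-14 and the mitoses between them."""

    cycle_ids: tuple[int, ...] = (10, 11, 12, 13, 14)
    interphase_durations: tuple[float, ...] = (8.0, 10.0, 12.0, 14.0, 50.0)
    mitosis_duration: float = 3.0
    frame_interval: float = 30.0  # seconds

    def __post_init__(self) -> None:
        if len(self.cycle_ids) != len(self.interphase_durations):
            raise ValueError("one interphase duration per cycle")
        if any(d <= 0 for d in self.interphase_durations):
            raise ValueError("durations must be positive")
        if self.mitosis_duration <= 0 or self.frame_interval <= 0:
            raise ValueError("durations must be positive")
        durs = self.interphase_durations
        if durs[-1] != max(durs):
            raise ValueError("cycle 14 must be the longest interphase")
        if self.total_minutes > 180.0:
            raise ValueError("schedule exceeds a 3 h recording")

    @property
    def n_mitoses(self) -> int:
        return len(self.cycle_ids) - 1

    @property
    def total_minutes(self) -> float:
        return sum(self.interphase_durations) + self.n_mitoses * self.mitosis_duration

    def segments(self) -> list[tuple[str, int, float, float]]:
        """(kind, cycle_id, t_start, t_end) for interphases and mitoses."""
        out = []
        t = 0.0
        for i, (cid, dur) in enumerate(zip(self.cycle_ids, self.interphase_durations)):
            out.append(("interphase", cid, t, t + dur))
            t += dur
            if i < self.n_mitoses:
                out.append(("mitosis", cid, t, t + self.mitosis_duration))
                t += self.mitosis_duration
        return out

    def frame_times(self) -> np.ndarray:
        """Frame times in minutes, one frame every frame_interval seconds."""
        dt = self.frame_interval / 60.0
        return np.arange(0.0, self.total_minutes + 1e-9, dt)


@dataclass(frozen=True)
class NoiseParams:
    """Imaging noise model: multiplicative speckle plus additive detector
    noise, both Gaussian, output clipped at zero."""

    additive_sd: float = 2.0
    multiplicative_cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_cv < 0:
            raise ValueError("noise magnitudes must be nonnegative")


@dataclass
class GroundTruth:
    """Exact factors and annotations behind one synthetic embryo."""

    spatial_profile_true: np.ndarray
    amplitude_true: np.ndarray
    mitosis_frames: np.ndarray
    nucleus_centers: np.ndarray
    tau_true: np.ndarray
    params: GenotypeParams | None = None
    schedule: CycleSchedule | None = None

    def __post_init__(self) -> None:
        self.mitosis_frames = np.asarray(self.mitosis_frames, dtype=int)
        if self.mitosis_frames.size and np.any(np.diff(self.mitosis_frames) <= 0):
            raise ValueError("mitosis_frames must be strictly increasing")
        if np.any(np.asarray(self.amplitude_true) < 0):
            raise ValueError("amplitude_true must be nonnegative")


def hill(x: np.ndarray, lam: float, n: float) -> np.ndarray:
    """Hill activation x^n / (lam^n + x^n), the boundary primitive."""
    x = np.asarray(x, dtype=float)
    return x**n / (lam**n + x**n)


def make_spatial_profile(
    params: GenotypeParams,
    n_positions: int = 100,
    lambda_posterior: float | None = None,
) -> np.ndarray:
    """Double-sigmoid AP profile on a uniform grid over [0, 1] egg length.

    Anterior is x = 0.  The anterior boundary is a Hill function with
    half-maximum at ``lambda_true``; the posterior boundary mirrors it
    (half-maximum at ``1 - lambda_posterior`` with ``lambda_posterior``
    measured from the posterior pole, equal to ``lambda_true`` unless
    overridden).  The mid-body sits at the plateau, the poles at the floor.
    """
    if n_positions < 16:
        raise ValueError("need n_positions >= 16")
    lam = params.lambda_true
    lam_post = lam if lambda_posterior is None else lambda_posterior
    if lam >= 0.5 or lam_post >= 0.5:
        raise ValueError("boundary positions >= 0.5 would overlap at mid-body")
    x = np.linspace(0.0, 1.0, n_positions)
    n = params.hill_coeff_true
    shape = hill(x, lam, n) * hill(1.0 - x, lam_post, n)
    return params.pole_floor + (params.plateau_amplitude - params.pole_floor) * shape


def positions_grid(n_positions: int = 100) -> np.ndarray:
    """Fractional egg-length grid matching :func:`make_spatial_profile`."""
    return np.linspace(0.0, 1.0, n_positions)


def make_temporal_amplitude(
    schedule: CycleSchedule, params: GenotypeParams
) -> np.ndarray:
    """Temporal amplitude over frames: saturating first-order recovery
    within each interphase, rapid collapse during each mitosis."""
    amp, _ = _amplitude_and_mitoses(schedule, params)
    return amp


def _amplitude_and_mitoses(
    schedule: CycleSchedule,
    params: GenotypeParams,
    amplitude_fractions: tuple[float, ...] = CYCLE_AMPLITUDE_FRACTIONS,
) -> tuple[np.ndarray, np.ndarray]:
    times = schedule.frame_times()
    amp = np.zeros_like(times)
    fractions = list(amplitude_fractions)
    if len(fractions) != len(schedule.cycle_ids):
        raise ValueError("one amplitude fraction per cycle")
    # mitotic collapse: fast exponential decay so the amplitude is
    # essentially zero by the end of mitosis (e^-6 of the pre-mitotic level)
    mito_tau = schedule.mitosis_duration / 6.0
    cycle_idx = 0
    mitosis_windows: list[tuple[float, float]] = []
    segments = schedule.segments()
    for si, (kind, _cid, t0, t1) in enumerate(segments):
        last = si == len(segments) - 1
        if kind == "interphase":
            target = params.plateau_amplitude * fractions[cycle_idx]
            sel = (times >= t0 - 1e-12) & (
                times <= t1 + 1e-12 if last else times < t1 - 1e-12
            )
            amp[sel] = target * (1.0 - np.exp(-(times[sel] - t0) / params.recovery_tau))
            a_end = target * (1.0 - np.exp(-(t1 - t0) / params.recovery_tau))
            cycle_idx += 1
        else:
            sel = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
            amp[sel] = a_end * np.exp(-(times[sel] - t0) / mito_tau)
            mitosis_windows.append((t0, t1))
    # dip frame = amplitude minimum inside each closed mitosis window
    # (usually the first frame of the following interphase, where the
    # nuclear signal restarts from zero)
    mitosis_frames = []
    for t0, t1 in mitosis_windows:
        sel = np.where((times >= t0 - 1e-9) & (times <= t1 + 1e-9))[0]
        mitosis_frames.append(sel[np.argmin(amp[sel])])
    return amp, np.asarray(mitosis_frames, dtype=int)


def make_kymograph(
    profile: np.ndarray,
    amplitude: np.ndarray,
    noise: NoiseParams | None = None,
    positions: np.ndarray | None = None,
    times: np.ndarray | None = None,
    mitosis_frames: np.ndarray | None = None,
    nucleus_centers: np.ndarray | None = None,
    tau_true: np.ndarray | None = None,
) -> tuple[SpaceTimeMatrix, GroundTruth]:
    """Outer product of profile and amplitude plus imaging noise.

    X[i, j] = profile[i] * amplitude[j] * (1 + eps_mult) + eps_add,
    clipped at zero.  With ``noise=None`` the matrix is exactly rank one.
    """
    profile = np.asarray(profile, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    X = np.outer(profile, amplitude)
    if noise is not None:
        rng = np.random.default_rng(noise.seed)
        X = X * (1.0 + noise.multiplicative_cv * rng.standard_normal(X.shape))
        X = X + noise.additive_sd * rng.standard_normal(X.shape)
        X = np.clip(X, 0.0, None)
    if positions is None:
        positions = np.linspace(0.0, 1.0, profile.size)
    if times is None:
        times = np.arange(amplitude.size) * 0.5
    stm = SpaceTimeMatrix(values=X, positions=positions, times=times)
    truth = GroundTruth(
        spatial_profile_true=profile,
        amplitude_true=amplitude,
        mitosis_frames=np.empty(0, dtype=int)
        if mitosis_frames is None
        else mitosis_frames,
        nucleus_centers=np.empty(0)
        if nucleus_centers is None
        else np.asarray(nucleus_centers, dtype=float),
        tau_true=np.empty(0) if tau_true is None else np.asarray(tau_true, dtype=float),
    )
    return stm, truth


#: default imaging noise for the simulate_* entry points; pass noise=None
#: explicitly for a noiseless (exactly separable) embryo
DEFAULT_NOISE = NoiseParams()


def simulate_embryo(
    params: GenotypeParams | None = None,
    schedule: CycleSchedule | None = None,
    noise: NoiseParams | None = DEFAULT_NOISE,
    n_positions: int = 100,
    n_nuclei: int = 20,
    seed: int | None = None,
) -> tuple[SpaceTimeMatrix, GroundTruth]:
    """One fully annotated synthetic embryo kymograph.

    ``seed`` overrides ``noise.seed`` when given; ``noise=None`` yields a
    noiseless, exactly rank-one kymograph.  Nucleus positions sit in the
    mid-body (x in [0.3, 0.7]) with per-nucleus recovery timescales
    jittered by 5% around the genotype value.

    The spatial factor is the dimensionless profile shape (mid-body peak
    ~ 1) and the temporal factor carries the intensity units, so the
    kymograph's cycle-14 mid-body plateau equals ``plateau_amplitude``
    and the default additive noise SD of 2 is 2% of that plateau.
    """
    params = params or GenotypeParams()
    schedule = schedule or CycleSchedule()
    if noise is not None and seed is not None:
        noise = replace(noise, seed=seed)
    base_seed = noise.seed if noise is not None else (seed if seed is not None else 0)
    profile = make_spatial_profile(params, n_positions) / params.plateau_amplitude
    amp, mitosis_frames = _amplitude_and_mitoses(schedule, params)
    rng = np.random.default_rng(np.random.SeedSequence([base_seed, 7919]))
    centers = np.linspace(0.3, 0.7, n_nuclei)
    centers = centers + rng.uniform(-0.004, 0.004, n_nuclei)
    taus = params.recovery_tau * (1.0 + 0.05 * rng.standard_normal(n_nuclei))
    taus = np.clip(taus, 0.2 * params.recovery_tau, None)
    stm, _ = make_kymograph(profile, amp, noise, times=schedule.frame_times())
    truth = GroundTruth(
        spatial_profile_true=profile,
        amplitude_true=amp,
        mitosis_frames=mitosis_frames,
        nucleus_centers=np.sort(centers),
        tau_true=taus,
        params=params,
        schedule=schedule,
    )
    return stm, truth


def default_geometry(frame_shape: tuple[int, int] = (120, 300)) -> EmbryoGeometry:
    """Ellipse comfortably inside the frame, AP axis horizontal."""
    h, w = frame_shape
    return EmbryoGeometry(
        center=(h / 2.0, w / 2.0),
        semi_major=0.44 * w,
        semi_minor=0.33 * h,
        angle=0.0,
    )


def make_movie(
    kymograph: SpaceTimeMatrix,
    geometry: EmbryoGeometry | None = None,
    truth: GroundTruth | None = None,
    frame_shape: tuple[int, int] = (120, 300),
    noise: NoiseParams | None = None,
    spot_sigma: float = 1.5,
    spot_contrast: float = 0.6,
    band_depth: tuple[float, float] = (0.05, 0.15),
) -> EmbryoMovie:
    """Render a kymograph as an elliptical embryo movie.

    Pixels inside the ellipse carry the kymograph value at their fractional
    AP coordinate.  When ``truth`` provides nucleus centres, nuclei are
    rendered as Gaussian spots in the dorsal band whose brightness follows
    the per-nucleus interphase recovery and vanishes during mitosis.  Spot
    fields are flux-normalised within the band (each spot minus its local
    band mean) so that the band average remains the tissue kymograph value:
    the kymograph is *defined* as the band mean, and the renderer keeps
    that identity.  Optional additive detector noise on every pixel.
    """
    geometry = geometry or default_geometry(frame_shape)
    h, w = frame_shape
    r0, c0 = geometry.center
    a, b = geometry.semi_major, geometry.semi_minor
    th = geometry.angle
    e1 = np.array([np.sin(th), np.cos(th)])  # anterior -> posterior
    e2 = np.array([-np.cos(th), np.sin(th)])  # toward dorsal (up)
    # ellipse must fit: check extreme points of the ellipse against bounds
    for sgn_u, sgn_v in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        pt = np.array([r0, c0]) + sgn_u * a * e1 + sgn_v * b * e2
        if not (0 <= pt[0] <= h - 1 and 0 <= pt[1] <= w - 1):
            raise ValueError("ellipse exceeds frame bounds")

    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr = rr - r0
    dc = cc - c0
    u = dr * e1[0] + dc * e1[1]
    v = dr * e2[0] + dc * e2[1]
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    iu, iv = u[inside], v[inside]
    frac = (iu + a) / (2.0 * a)  # fractional egg length of each inside pixel

    n_frames = kymograph.n_frames
    frames = np.zeros((n_frames, h, w), dtype=float)

    spot_field = None
    weights = None
    if truth is not None and truth.nucleus_centers.size:
        from .extraction import _band_coordinates

        v_b = b * np.sqrt(np.clip(1.0 - (iu / a) ** 2, 0.0, None))
        in_band = (iv >= v_b - band_depth[1] * b) & (iv <= v_b - band_depth[0] * b) & (
            iv > 0
        )
        # nucleus pixel positions: band mid-depth at each fractional centre
        centers = truth.nucleus_centers
        u_k = centers * 2.0 * a - a
        vb_k = b * np.sqrt(np.clip(1.0 - (u_k / a) ** 2, 0.0, None))
        v_k = vb_k - 0.5 * (band_depth[0] + band_depth[1]) * b
        p_k = (
            np.array([r0, c0])[None, :]
            + u_k[:, None] * e1[None, :]
            + v_k[:, None] * e2[None, :]
        )
        ir, ic = rr[inside], cc[inside]
        d2 = (ir[None, :] - p_k[:, 0:1]) ** 2 + (ic[None, :] - p_k[:, 1:2]) ** 2
        g = np.exp(-d2 / (2.0 * spot_sigma**2))  # (n_nuclei, n_inside)
        # flux normalisation: subtract from each spot its own band-sampling
        # response (depth-averaged Gaussian at the dorsal-band sample points,
        # spread along the band as a function of AP position), so the band
        # readout of the rendered frame equals the tissue kymograph exactly
        band_xy = _band_coordinates(geometry, kymograph.n_positions, band_depth, 5)
        dr_s = band_xy[0][None, :, :] - p_k[:, 0, None, None]
        dc_s = band_xy[1][None, :, :] - p_k[:, 1, None, None]
        g_resp = np.exp(-(dr_s**2 + dc_s**2) / (2.0 * spot_sigma**2)).mean(axis=2)
        gh = g.copy()
        grid = np.linspace(0.0, 1.0, kymograph.n_positions)
        for k in range(g.shape[0]):
            gh[k] -= np.interp(frac, grid, g_resp[k])
        spot_field = gh
        weights = _nuclear_weights(truth, n_frames)

    for j in range(n_frames):
        col = np.interp(frac, kymograph.positions, kymograph.values[:, j])
        if spot_field is not None:
            wj = weights[:, j]
            col = col * (1.0 + spot_contrast * (wj @ spot_field))
        img = np.zeros((h, w))
        img[inside] = col
        frames[j] = img

    if noise is not None:
        rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 104729]))
        frames *= 1.0 + noise.multiplicative_cv * rng.standard_normal(frames.shape)
        frames += noise.additive_sd * rng.standard_normal(frames.shape)
    np.clip(frames, 0.0, None, out=frames)
    return EmbryoMovie(
        frames=frames,
        frame_interval=(truth.schedule.frame_interval if truth and truth.schedule else 30.0),
    )


def _nuclear_weights(truth: GroundTruth, n_frames: int) -> np.ndarray:
    """Per-nucleus spot brightness in [0, 1] per frame: first-order
    recovery within each interphase, zero during mitosis."""
    n_nuc = truth.nucleus_centers.size
    w = np.zeros((n_nuc, n_frames))
    if truth.schedule is None:
        # no schedule: scale by normalised tissue amplitude
        amp = truth.amplitude_true[:n_frames]
        w[:] = amp / max(amp.max(), 1e-12)
        return w
    times = truth.schedule.frame_times()[:n_frames]
    for kind, _cid, t0, t1 in truth.schedule.segments():
        if kind != "interphase":
            continue
        sel = (times >= t0 - 1e-12) & (times < t1 - 1e-12)
        dt = times[sel] - t0
        w[:, sel] = 1.0 - np.exp(-dt[None, :] / truth.tau_true[:, None])
    return w


def simulate_movie(
    params: GenotypeParams | None = None,
    schedule: CycleSchedule | None = None,
    noise: NoiseParams | None = DEFAULT_NOISE,
    seed: int | None = None,
    frame_shape: tuple[int, int] = (120, 300),
    n_positions: int = 100,
    n_nuclei: int = 20,
    **movie_kwargs,
) -> tuple[EmbryoMovie, SpaceTimeMatrix, GroundTruth]:
    """Render a noiseless separable embryo and apply noise at the pixel
    level, returning (movie, noiseless kymograph, ground truth)."""
    if noise is not None and seed is not None:
        noise = replace(noise, seed=seed)
    base_seed = noise.seed if noise is not None else (seed if seed is not None else 0)
    stm, truth = simulate_embryo(
        params, schedule, noise=None, n_positions=n_positions, n_nuclei=n_nuclei,
        seed=base_seed,
    )
    movie = make_movie(
        stm, default_geometry(frame_shape), truth, frame_shape, noise=noise,
        **movie_kwargs,
    )
    return movie, stm, truth


def make_ensemble(
    genotype: GenotypeParams | None = None,
    n_embryos: int = 10,
    base_seed: int = 0,
    schedule: CycleSchedule | None = None,
    noise: NoiseParams | None = DEFAULT_NOISE,
    kind: str = "kymograph",
    param_jitter: float = 0.05,
    max_phase_jitter_frames: int = 8,
    **kwargs,
) -> list[tuple]:
    """Ensemble of synthetic embryos of one genotype.

    Embryos are not age-synchronised: each gets an independent start-phase
    offset (its first frames are cropped) and a ±5% jitter of plateau,
    boundary position and recovery timescale.  Fully deterministic given
    ``base_seed``.

    Returns a list of ``(kymograph, truth)`` pairs, or
    ``(movie, kymograph, truth)`` triples when ``kind="movie"``.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    genotype = genotype or GenotypeParams()
    schedule = schedule or CycleSchedule()
    ss = np.random.SeedSequence(base_seed)
    child_seeds = ss.generate_state(n_embryos) % (2**31)
    # start-phase offsets are drawn without replacement so ensemble members
    # are guaranteed distinct developmental ages (when the range allows)
    rng_ens = np.random.default_rng(np.random.SeedSequence([base_seed, 424243]))
    crops = rng_ens.choice(
        max_phase_jitter_frames + 1,
        size=n_embryos,
        replace=n_embryos > max_phase_jitter_frames + 1,
    )
    out = []
    for i in range(n_embryos):
        seed_i = int(child_seeds[i])
        rng = np.random.default_rng(np.random.SeedSequence([seed_i, 15485863]))
        j = lambda: 1.0 + rng.uniform(-param_jitter, param_jitter)  # noqa: E731
        lam = float(np.clip(genotype.lambda_true * j(), 0.02, 0.39))
        p_i = replace(
            genotype,
            plateau_amplitude=genotype.plateau_amplitude * j(),
            lambda_true=lam,
            recovery_tau=genotype.recovery_tau * j(),
            hill_coeff_true=genotype.hill_coeff_true * j(),
        )
        crop = int(crops[i])
        noise_i = replace(noise, seed=seed_i) if noise is not None else None
        if kind == "movie":
            movie, stm, truth = simulate_movie(
                p_i, schedule, noise_i, seed=seed_i, **kwargs
            )
            movie, stm, truth = _crop_start(movie, stm, truth, crop)
            out.append((movie, stm, truth))
        else:
            stm, truth = simulate_embryo(
                p_i, schedule, noise_i, seed=seed_i, **kwargs
            )
            _, stm, truth = _crop_start(None, stm, truth, crop)
            out.append((stm, truth))
    return out


def _crop_start(movie, stm: SpaceTimeMatrix, truth: GroundTruth, crop: int):
    """Drop the first ``crop`` frames (start-phase jitter)."""
    if crop <= 0:
        return movie, stm, truth
    stm = SpaceTimeMatrix(
        values=stm.values[:, crop:],
        positions=stm.positions,
        times=stm.times[crop:] - stm.times[crop],
        side=stm.side,
    )
    truth = GroundTruth(
        spatial_profile_true=truth.spatial_profile_true,
        amplitude_true=truth.amplitude_true[crop:],
        mitosis_frames=truth.mitosis_frames[truth.mitosis_frames >= crop] - crop,
        nucleus_centers=truth.nucleus_centers,
        tau_true=truth.tau_true,
        params=truth.params,
        schedule=truth.schedule,
    )
    if movie is not None:
        movie = EmbryoMovie(
            frames=movie.frames[crop:],
            frame_interval=movie.frame_interval,
            pixel_size=movie.pixel_size,
        )
    return movie, stm, truth


def make_nuclear_traces(
    params: GenotypeParams | None = None,
    n_nuclei: int = 20,
    duration: float = 50.0,
    frame_interval: float = 30.0,
    noise: NoiseParams | None = DEFAULT_NOISE,
    seed: int | None = None,
) -> list:
    """Synthetic cycle-14 single-nucleus traces (t = 0 at the 13th
    division): I(t) = plateau * (1 - exp(-t/tau)) plus imaging noise."""
    from .singlecell import NuclearTrace

    params = params or GenotypeParams()
    if noise is None:
        noise = NoiseParams(additive_sd=0.0, multiplicative_cv=0.0,
                            seed=seed if seed is not None else 0)
    if seed is not None:
        noise = replace(noise, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([noise.seed, 32452843]))
    times = np.arange(0.0, duration + 1e-9, frame_interval / 60.0)
    centers = np.sort(rng.uniform(0.3, 0.7, n_nuclei))
    taus = np.clip(
        params.recovery_tau * (1.0 + 0.05 * rng.standard_normal(n_nuclei)),
        0.2 * params.recovery_tau,
        None,
    )
    profile_at = lambda x: params.pole_floor + (  # noqa: E731
        params.plateau_amplitude - params.pole_floor
    ) * hill(x, params.lambda_true, params.hill_coeff_true) * hill(
        1.0 - x, params.lambda_true, params.hill_coeff_true
    )
    traces = []
    for k in range(n_nuclei):
        plateau = profile_at(centers[k])
        clean = plateau * (1.0 - np.exp(-times / taus[k]))
        y = clean * (1.0 + noise.multiplicative_cv * rng.standard_normal(times.size))
        y = y + noise.additive_sd * rng.standard_normal(times.size)
        traces.append(
            NuclearTrace(
                nucleus_id=k,
                position=float(centers[k]),
                times=times.copy(),
                intensities=np.clip(y, 0.0, None),
            )
        )
    return traces


# ---------------------------------------------------------------------------
# genotype presets: a wild-type-like background and three perturbations
# mimicking constitutive Ras-pathway activation

def wild_type() -> GenotypeParams:
    return GenotypeParams()


def mutant_presets(wt: GenotypeParams | None = None) -> dict[str, GenotypeParams]:
    """Three mutant-like parameter sets: reduced cycle-14 plateau,
    posteriorly shifted (graded) anterior boundary, and slowed
    post-mitotic recovery."""
    wt = wt or wild_type()
    return {
        "low_plateau": replace(
            wt,
            name="low_plateau",
            plateau_amplitude=0.4 * wt.plateau_amplitude,
            pole_floor=min(wt.pole_floor, 0.2 * wt.plateau_amplitude),
        ),
        "broad_boundary": replace(wt, name="broad_boundary", lambda_true=0.22),
        "slow_recovery": replace(
            wt, name="slow_recovery", recovery_tau=2.0 * wt.recovery_tau
        ),
    }
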