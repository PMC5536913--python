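"""Optional plotting helpers (matplotlib imported lazily)."""

from __future__ import annotations

import numpy as np

from .containers import SpaceTimeMatrix


def _plt():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt


def plot_kymograph(stm: SpaceTimeMatrix, ax=None, cmap="viridis"):
    """Heat map of a space-time matrix: egg length vs imaging time."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        stm.values,
        aspect="auto",
        origin="upper",
        extent=[stm.times[0], stm.times[-1], 1.0, 0.0],
        cmap=cmap,
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("egg length (L)")
    ax.figure.colorbar(im, ax=ax, label="intensity (a.u.)")
    return ax


def plot_ensemble_amplitude(ensemble, ax=None):
    """Point-wise mean amplitude with a one-SD shaded band."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    t = ensemble.aligned_times
    m, s = ensemble.pointwise_mean, ensemble.pointwise_sd
    ok = ~np.isnan(m)
    ax.plot(t[ok], m[ok], label=ensemble.genotype or "ensemble")
    band = ok & ~np.isnan(s)
    ax.fill_between(t[band], (m - s)[band], (m + s)[band], alpha=0.3)
    ax.axvline(0.0, ls=":", color="k", lw=0.8)
    ax.set_xlabel("time from 13th division (min)")
    ax.set_ylabel("amplitude (a.u.)")
    ax.legend()
    return ax


def plot_spatial_mode(positions, mode, hill_fit=None, ax=None):
    """First spatial mode with its optional Hill-boundary fit."""
    plt = _plt()
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(positions, mode, label="spatial mode")
    if hill_fit is not None:
        lo, hi = hill_fit.fit_region
        xs = np.linspace(lo, hi, 200)
        ax.plot(xs, hill_fit(xs), "--", label=f"Hill fit (λ={hill_fit.lambda_half:.3f})")
        ax.axvline(hill_fit.lambda_half, ls=":", color="gray", lw=0.8)
    ax.set_xlabel("egg length (L)")
    ax.set_ylabel("mode (unit norm)")
    ax.legend()
    return ax
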