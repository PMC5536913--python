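"""Hill parameterisation of the anterior boundary of the spatial mode.

The anterior 40% of the first spatial mode is fitted with

    f(x) = baseline + (plateau - baseline) * x^n / (lambda^n + x^n),

so f(lambda) is exactly the midpoint of baseline and plateau: lambda is
the fractional egg length of half-maximal Cic accumulation, the paper-
level summary of boundary position; n sets boundary sharpness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator


class DegenerateProfileError(ValueError):
    """Profile has too little dynamic range over the fit region."""


@dataclass
class HillFit:
    lambda_half: float
    hill_coeff: float
    baseline: float
    plateau: float
    residual_rms: float
    converged: bool
    fit_region: tuple[float, float] = (0.0, 0.4)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return _hill_model(np.asarray(x, float), self.baseline, self.plateau,
                           self.lambda_half, self.hill_coeff)


def _hill_model(x, baseline, plateau, lam, n):
    return baseline + (plateau - baseline) * x**n / (lam**n + x**n)


class HillBoundaryFit(BaseEstimator):
    """Least-squares Hill fit to the anterior boundary, sklearn style.

    Parameters
    ----------
    fit_region : (float, float)
        Fractional egg-length interval used for the fit; the anterior 40%
        by default.
    lambda_bounds, n_bounds : (float, float)
        Box constraints on the half-maximal position and Hill coefficient.
    min_dynamic_range : float
        Minimum (max - min) of the profile over the region, as a multiple
        of the estimated noise floor, below which the profile is declared
        degenerate (e.g. a flat mode with no boundary to fit).

    Attributes (after ``fit``)
    --------------------------
    lambda_half_, hill_coeff_, baseline_, plateau_, residual_rms_,
    converged_, fit_ (a :class:`HillFit`).
    """

    def __init__(
        self,
        fit_region: tuple[float, float] = (0.0, 0.4),
        lambda_bounds: tuple[float, float] = (0.01, 0.39),
        n_bounds: tuple[float, float] = (0.5, 30.0),
        min_dynamic_range: float = 5.0,
    ):
        self.fit_region = fit_region
        self.lambda_bounds = lambda_bounds
        self.n_bounds = n_bounds
        self.min_dynamic_range = min_dynamic_range

    def fit(self, X, y=None):
        """Fit the boundary model.

        X : positions (fractional egg length); y : the spatial mode.
        For convenience ``fit((mode, positions))``-style calling is
        handled by :func:`fit_hill_anterior`.
        """
        x = np.asarray(X, dtype=float).ravel()
        f = np.asarray(y, dtype=float).ravel()
        if x.shape != f.shape:
            raise ValueError("positions and mode must have equal length")
        if np.any(f < 0):
            raise ValueError("mode must be nonnegative")
        lo, hi = self.fit_region
        if x.min() > lo + 1e-9 or x.max() < hi - 1e-9:
            raise ValueError("positions must cover the fit region")
        sel = (x >= lo) & (x <= hi)
        xs, fs = x[sel], f[sel]
        rng_span = fs.max() - fs.min()
        # noise floor: robust SD of the second difference (smooth trend removed)
        d2 = np.diff(fs, n=2)
        noise = np.median(np.abs(d2)) / 0.6745 / np.sqrt(6.0) if d2.size else 0.0
        noise = max(noise, 1e-12 * max(fs.max(), 1.0))
        if rng_span < self.min_dynamic_range * noise:
            raise DegenerateProfileError(
                "profile dynamic range over the fit region is below "
                f"{self.min_dynamic_range}x the noise floor"
            )
        mid = 0.5 * (fs.min() + fs.max())
        above = np.where(fs >= mid)[0]
        lam0 = float(xs[above[0]]) if above.size else 0.5 * (lo + hi)
        lam0 = float(np.clip(lam0, *self.lambda_bounds))
        p0 = [fs.min(), fs.max(), lam0, 4.0]
        bounds = (
            [-np.inf, -np.inf, self.lambda_bounds[0], self.n_bounds[0]],
            [np.inf, np.inf, self.lambda_bounds[1], self.n_bounds[1]],
        )
        converged = True
        try:
            popt, _ = curve_fit(
                _hill_model, xs, fs, p0=p0, bounds=bounds, maxfev=20000
            )
        except RuntimeError:
            converged = False
            popt = p0
        baseline, plateau, lam, n = map(float, popt)
        if plateau <= baseline:
            converged = False
        resid = fs - _hill_model(xs, *popt)
        self.baseline_ = baseline
        self.plateau_ = plateau
        self.lambda_half_ = lam
        self.hill_coeff_ = n
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        self.converged_ = converged
        self.fit_ = HillFit(
            lambda_half=lam,
            hill_coeff=n,
            baseline=baseline,
            plateau=plateau,
            residual_rms=self.residual_rms_,
            converged=converged,
            fit_region=self.fit_region,
        )
        return self

    def predict(self, X):
        if not hasattr(self, "fit_"):
            raise AttributeError("HillBoundaryFit is not fitted")
        return self.fit_(np.asarray(X, dtype=float))


def fit_hill_anterior(
    spatial_mode: np.ndarray, positions: np.ndarray, **params
) -> HillFit:
    """Hill fit of the anterior 40% of a spatial mode (functional form)."""
    est = HillBoundaryFit(**params)
    est.fit(positions, spatial_mode)
    return est.fit_


def compare_lambda(fits_by_genotype: dict[str, list[HillFit]], **test_kwargs):
    """Per-genotype summary of lambda plus pairwise two-tailed t-tests.

    Each genotype needs at least 3 fitted embryos.  Returns
    (summary DataFrame, list of ComparisonResult).
    """
    import pandas as pd

    from .compare import compare_all

    for g, fits in fits_by_genotype.items():
        if len(fits) < 3:
            raise ValueError(f"genotype {g!r} has fewer than 3 embryos")
    lam = {g: np.array([f.lambda_half for f in fits])
           for g, fits in fits_by_genotype.items()}
    summary = pd.DataFrame(
        {
            "genotype": list(lam),
            "n": [v.size for v in lam.values()],
            "lambda_mean": [v.mean() for v in lam.values()],
            "lambda_sd": [v.std(ddof=1) for v in lam.values()],
        }
    )
    results = compare_all(lam, metric="lambda", **test_kwargs)
    return summary, results
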