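"""Noise-masking analysis of the m-Tau peak-time curve.

Under the small-angle approximation, the m-Tau peak leads contact by

    t_c - t_hat = sqrt(x^2 + 2 x / mu),          x = R / |v|,

which is a concave, *nonlinear* function of the stimulus ratio x; its
local slope (x + 1/mu) / sqrt(x^2 + 2 x / mu) decreases toward 1 (the
value it attains exactly as mu -> infinity).  Experimental peak-time
data, however, are conventionally summarised by straight-line fits.
This module quantifies when measurement noise masks the curvature:
synthetic peak delays with trial-averaged noise of standard deviation
proportional to x are fitted by weighted least squares, and residual
normality (Kolmogorov-Smirnov), the regression F test and r^2 are used
as linearity diagnostics.  Repeating the experiment yields the fraction
of random repeats in which linearity is not rejected.  The scatter of
the fitted (intercept, slope) pairs is summarised by a one-standard-
deviation covariance ellipse (eigenvectors of the 2x2 sample covariance,
axes scaled by the square roots of the eigenvalues).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "LineFit",
    "EllipseSummary",
    "m_tau_peak_curve",
    "noisify_peaks",
    "weighted_line_fit",
    "masking_experiment",
    "masked_fraction",
    "intercept_slope_ellipse",
]


@dataclass(frozen=True)
class LineFit:
    """Weighted straight-line fit with residual diagnostics."""

    slope: float
    intercept: float
    slope_sd: float
    r2: float
    ks_stat_p: float
    f_p: float
    weights_used: bool


@dataclass(frozen=True)
class EllipseSummary:
    """One-standard-deviation covariance ellipse of (intercept, slope)."""

    center: tuple[float, float]
    axis_lengths: tuple[float, float]
    axis_directions: tuple[tuple[float, float], tuple[float, float]]


def m_tau_peak_curve(mu: float, x_values) -> np.ndarray:
    """Small-angle m-Tau peak delay t_c - t_hat = sqrt(x^2 + 2x/mu)."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    x = np.asarray(x_values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x values must be positive")
    return np.sqrt(x * x + 2.0 * x / mu)


def noisify_peaks(
    delays, x_values, noise_coeff_c: float, n_trials: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged noisy peak delays with sd proportional to x.

    Per stimulus ratio x, draws ``n_trials`` values delay + (c*x)*N(0,1)
    and returns the trial means together with the per-x sample variances
    (of the raw trials, ddof=1; zeros for n_trials == 1 or c == 0).
    """
    if noise_coeff_c < 0:
        raise ValueError("noise coefficient must be >= 0")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    delays = np.asarray(delays, dtype=float)
    x = np.asarray(x_values, dtype=float)
    if delays.shape != x.shape:
        raise ValueError("delays and x_values must have equal length")
    rng = np.random.default_rng(seed)
    draws = delays[:, None] + (noise_coeff_c * x)[:, None] * rng.standard_normal(
        (x.size, n_trials)
    )
    means = draws.mean(axis=1)
    variances = draws.var(axis=1, ddof=1) if n_trials > 1 else np.zeros_like(means)
    return means, variances


def weighted_line_fit(x, y, weights=None) -> LineFit:
    """Weighted least-squares straight line with linearity diagnostics.

    Unit (or absent) weights reduce exactly to ordinary least squares.
    Residual normality is assessed by a KS test on the standardised
    weighted residuals; the overall-regression F test p-value is also
    reported.  A perfect fit (vanishing residuals) reports ks_stat_p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values identical")
    if weights is None:
        w = np.ones_like(x)
        weights_used = False
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        weights_used = True
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = res.params
    slope_sd = float(res.bse[1])
    wresid = res.wresid
    scale = float(np.std(wresid, ddof=2)) if wresid.size > 2 else 0.0
    if scale < 1e-13 * max(1.0, float(np.max(np.abs(y)))):
        ks_p = 1.0
        f_p = 0.0
    else:
        ks_p = float(stats.kstest((wresid - np.mean(wresid)) / scale, "norm").pvalue)
        f_p = float(res.f_pvalue)
    return LineFit(
        slope=float(slope),
        intercept=float(intercept),
        slope_sd=slope_sd,
        r2=float(res.rsquared),
        ks_stat_p=ks_p,
        f_p=f_p,
        weights_used=weights_used,
    )


def masking_experiment(
    mu: float,
    x_values,
    noise_coeff_c: float,
    n_trials: int,
    n_repeats: int,
    seed: int,
) -> list[LineFit]:
    """Repeat noisify-then-fit ``n_repeats`` times on the m-Tau peak curve.

    Each repeat averages ``n_trials`` noisy draws per x and fits a
    weighted line (weights inversely proportional to the variance of the
    trial mean; unit weights when noise-free).  Use :func:`masked_fraction`
    to summarise how often linearity is not rejected.
    """
    x = np.asarray(x_values, dtype=float)
    delays = m_tau_peak_curve(mu, x)
    fits = []
    for r in range(n_repeats):
        rep_seed = np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31)
        means, variances = noisify_peaks(delays, x, noise_coeff_c, n_trials, int(rep_seed))
        var_mean = variances / n_trials
        if np.all(var_mean > 0):
            weights = 1.0 / var_mean
        else:
            weights = None
        fits.append(weighted_line_fit(x, means, weights))
    return fits


def masked_fraction(fits: Sequence[LineFit], alpha: float = 0.05) -> float:
    """Fraction of repeats consistent with a straight line.

    A repeat counts as masked when residual normality is not rejected
    (KS p > alpha) and the regression slope is significant (F p < alpha).
    """
    if not fits:
        raise ValueError("no fits")
    ok = [f.ks_stat_p > alpha and f.f_p < alpha for f in fits]
    return float(np.mean(ok))


def intercept_slope_ellipse(pairs) -> EllipseSummary:
    """One-SD covariance ellipse of fitted (intercept, slope) pairs.

    Center is the componentwise mean; the axes are the eigenvectors of
    the 2x2 sample covariance, with lengths equal to the square roots of
    the associated eigenvalues (largest first).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (intercept, slope) pairs")
    if np.allclose(arr, arr[0]):
        raise ValueError("all pairs identical: covariance undefined")
    center = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    return EllipseSummary(
        center=(float(center[0]), float(center[1])),
        axis_lengths=(float(np.sqrt(eigvals[0])), float(np.sqrt(eigvals[1]))),
        axis_directions=(
            (float(eigvecs[0, 0]), float(eigvecs[1, 0])),
            (float(eigvecs[0, 1]), float(eigvecs[1, 1])),
        ),
    )
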