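"""Simulation of a before/after time-to-contact discrimination experiment.

An observer watches a looming disc that disappears at presentation time
t_p, well before the programmed contact time t_c, and judges whether
contact would have occurred before or after an acoustically marked
reference time t_ref.  The model observer runs the corrected m-Tau
function Xi on noisified optical input; because Xi estimates remaining
time to contact, the predicted contact time at t_p is

    t_contact_hat = t_p + mean of the last n_avg samples of Xi,

where the short averaging window tames trial-to-trial jitter.  A trial is
judged "later" when t_contact_hat > t_ref (exact ties count as "before").
Pooling trials per condition gives the proportion of later responses as a
function of true ttc; a cumulative Gaussian Phi((ttc - m)/s) fitted to
that curve summarises the psychometric performance by its point of
subjective simultaneity m (PSE) and spread s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import norm

from .functions import XiParams, corrected_m_tau
from .kinematics import ApproachStimulus, OpticalTrace, generate_trace
from .noise import NoiseSpec, noisify_trace

__all__ = [
    "TrialConfig",
    "PsychometricPoint",
    "GCDFFit",
    "Condition",
    "ExperimentDesign",
    "ttc_estimate",
    "simulate_trial",
    "proportion_later",
    "fit_gcdf",
    "synth_observer_dataset",
]


@dataclass(frozen=True)
class TrialConfig:
    """Per-trial decision settings.

    n_avg is the number of samples in the averaging window ending at t_p
    (inclusive); with dt = 1 ms the default 50 samples average over the
    final 50 ms of the presentation.
    """

    presentation_time_tp: float
    reference_time_tref: float
    n_avg: int = 50
    n_trials: int = 200
    dt: float = 1e-3

    def __post_init__(self) -> None:
        if self.presentation_time_tp <= 0:
            raise ValueError("presentation_time_tp must be positive")
        if self.n_avg < 1 or self.n_trials < 1:
            raise ValueError("n_avg and n_trials must be positive integers")
        if self.n_avg * self.dt > self.presentation_time_tp:
            raise ValueError("averaging window longer than the presentation")


@dataclass(frozen=True)
class PsychometricPoint:
    """Proportion of later responses for one (ttc, t_p, size) condition."""

    ttc: float
    presentation_time: float
    size_label: str
    proportion_later: float
    n_trials: int
    est_sd: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.proportion_later <= 1.0:
            raise ValueError("proportion_later must lie in [0, 1]")


@dataclass(frozen=True)
class GCDFFit:
    """Cumulative-Gaussian summary of one psychometric curve."""

    pse_mean: float
    sd: float
    sse: float
    degenerate: bool = False


@dataclass(frozen=True)
class Condition:
    """One resolved experimental condition."""

    ttc: float
    size_label: str
    half_size: float
    presentation_time: float
    d0: float

    @property
    def speed(self) -> float:
        return self.d0 / self.ttc


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design: ttc levels x two sizes x presentation times.

    Starting distances d0 are drawn uniformly per condition from
    ``d0_interval`` (deterministically from ``d0_seed``), and the approach
    speed follows as v = d0 / ttc, so that neither distance nor speed is a
    reliable proxy for ttc.  Sizes are given as half-sizes (radii), small
    first.  Pairings where the presentation time does not precede the
    contact time are skipped at enumeration.
    """

    ttc_levels: tuple[float, ...] = (2.0, 2.25, 2.5, 2.75, 3.0, 3.25, 3.5)
    size_levels: tuple[float, ...] = (0.02, 0.04)
    presentation_levels: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5)
    t_ref: float = 2.75
    d0_interval: tuple[float, float] = (10.0, 25.0)
    d0_seed: int = 12345

    size_labels: tuple[str, ...] = field(default=("small", "big"), repr=False)

    def __post_init__(self) -> None:
        if len(self.size_levels) != len(self.size_labels):
            raise ValueError("size_levels and size_labels length mismatch")
        if min(self.presentation_levels) >= max(self.ttc_levels):
            raise ValueError("no presentation time precedes any ttc level")
        if self.d0_interval[0] <= 0 or self.d0_interval[1] < self.d0_interval[0]:
            raise ValueError("invalid d0 interval")

    def conditions(self) -> list[Condition]:
        """Enumerate conditions with their per-condition starting distance."""
        lo, hi = self.d0_interval
        out = []
        for i, ttc in enumerate(self.ttc_levels):
            for j, (half, label) in enumerate(zip(self.size_levels, self.size_labels)):
                for k, tp in enumerate(self.presentation_levels):
                    if tp >= ttc:
                        continue
                    rng = np.random.default_rng(
                        np.random.SeedSequence([self.d0_seed, i, j, k])
                    )
                    d0 = lo + (hi - lo) * rng.random()
                    out.append(Condition(ttc, label, half, tp, d0))
        return out


def ttc_estimate(
    xi_series, times, cfg: TrialConfig
) -> tuple[float, float]:
    """Windowed remaining-time estimate at the presentation time.

    Returns the mean and standard deviation of the last ``n_avg`` samples
    of the Xi series up to and including t_p.
    """
    xi_series = np.asarray(xi_series, dtype=float)
    times = np.asarray(times, dtype=float)
    idx = np.flatnonzero(times <= cfg.presentation_time_tp + 1e-12)
    if idx.size < cfg.n_avg:
        raise ValueError("averaging window underflow: too few samples before t_p")
    window = xi_series[idx[-cfg.n_avg:]]
    return float(np.mean(window)), float(np.std(window))


def _xi_on_noisy_trace(
    clean: OpticalTrace,
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    extra_entropy: Sequence[int],
) -> np.ndarray:
    if noise_spec.p_theta == 0.0 and noise_spec.p_theta_dot == 0.0:
        return corrected_m_tau(clean, xi_params)
    noisy = noisify_trace(clean, noise_spec, extra_entropy=extra_entropy)
    return corrected_m_tau(noisy, xi_params)


def simulate_trial(
    stim: ApproachStimulus,
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    cfg: TrialConfig,
    trial_index: int,
) -> bool:
    """Run one trial; return True if the observer judges contact "later".

    The clean trace on [0, t_p] is noisified with a stream derived from
    the noise seed and the trial index, Xi is evaluated, and the windowed
    estimate decides against the reference time.
    """
    clean = generate_trace(stim, 0.0, cfg.presentation_time_tp)
    xi = _xi_on_noisy_trace(clean, xi_params, noise_spec, (trial_index,))
    est, _ = ttc_estimate(xi, clean.times, cfg)
    return bool(cfg.presentation_time_tp + est > cfg.reference_time_tref)


def _batch_xi(
    clean: OpticalTrace,
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    cond_entropy: int,
    n_trials: int,
) -> np.ndarray:
    """Xi for n_trials noisy replicates of one clean trace, rows = trials.

    One stream per condition and channel; row i holds trial i's deviates,
    so trial i is reproducible regardless of the total trial count.
    """
    from scipy.signal import lfilter

    T = len(clean)
    theta_c = clean.theta[None, :]
    theta_dot_c = clean.theta_dot[None, :]
    if noise_spec.p_theta == 0.0 and noise_spec.p_theta_dot == 0.0:
        theta, theta_dot = np.broadcast_to(theta_c, (n_trials, T)), np.broadcast_to(
            theta_dot_c, (n_trials, T)
        )
    else:
        ss = np.random.SeedSequence([int(noise_spec.seed), int(cond_entropy)])
        ss_theta, ss_theta_dot = ss.spawn(2)
        n1 = np.random.default_rng(ss_theta).standard_normal((n_trials, T))
        n2 = np.random.default_rng(ss_theta_dot).standard_normal((n_trials, T))
        if noise_spec.mode == "relative":
            theta = theta_c * (1.0 + noise_spec.p_theta * n1)
            theta_dot = theta_dot_c * (1.0 + noise_spec.p_theta_dot * n2)
        else:
            theta = theta_c + noise_spec.p_theta * n1
            theta_dot = theta_dot_c + noise_spec.p_theta_dot * n2
        if noise_spec.floor_at_zero:
            theta = np.maximum(theta, 0.0)
            theta_dot = np.maximum(theta_dot, 0.0)
    mu, eps = xi_params.mu, xi_params.eps
    denom = mu + theta_dot
    denom = np.where(denom <= 0, eps, denom)
    base = theta / denom

    def lp(x, xi):
        if xi == 0.0:
            return x
        init = x[:, :1]
        rest, _ = lfilter(
            [1.0 - xi], [1.0, -xi], x[:, 1:], axis=1, zi=xi * init
        )
        return np.concatenate([init, rest], axis=1)

    th_lp = lp(theta, xi_params.xi_theta)
    thd_lp = lp(theta_dot, xi_params.xi_theta_dot)
    corr = mu * th_lp / (thd_lp * (mu + thd_lp) + eps)
    return base + xi_params.w * corr + xi_params.kappa


def _simulate_condition(
    cond: Condition,
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    cfg: TrialConfig,
    cond_entropy: int,
    dt: float,
) -> PsychometricPoint:
    stim = ApproachStimulus(cond.half_size, cond.speed, cond.ttc, dt=dt)
    clean = generate_trace(stim, 0.0, cfg.presentation_time_tp)
    xi = _batch_xi(clean, xi_params, noise_spec, cond_entropy, cfg.n_trials)
    idx = np.flatnonzero(clean.times <= cfg.presentation_time_tp + 1e-12)
    if idx.size < cfg.n_avg:
        raise ValueError("averaging window underflow: too few samples before t_p")
    window = xi[:, idx[-cfg.n_avg:]]
    est = window.mean(axis=1)
    sds = window.std(axis=1)
    n_later = int(np.sum(cfg.presentation_time_tp + est > cfg.reference_time_tref))
    return PsychometricPoint(
        ttc=cond.ttc,
        presentation_time=cond.presentation_time,
        size_label=cond.size_label,
        proportion_later=n_later / cfg.n_trials,
        n_trials=cfg.n_trials,
        est_sd=float(np.mean(sds)),
    )


def proportion_later(
    design: ExperimentDesign,
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    cfg: TrialConfig,
    dt: float = 1e-3,
) -> list[PsychometricPoint]:
    """Simulate every condition of the design with n_trials trials each.

    The per-trial noise streams are keyed by (condition index, trial
    index) on top of the noise seed, so the underlying Gaussian deviates
    are common random numbers across different observer parameterisations.
    """
    points = []
    for ci, cond in enumerate(design.conditions()):
        cfg_c = replace(cfg, presentation_time_tp=cond.presentation_time, dt=dt)
        points.append(
            _simulate_condition(cond, xi_params, noise_spec, cfg_c, ci, dt)
        )
    return points


def synth_observer_dataset(
    xi_params: XiParams,
    noise_spec: NoiseSpec,
    design: ExperimentDesign,
    cfg: TrialConfig,
    dt: float = 1e-3,
) -> list[PsychometricPoint]:
    """Ground-truth observation table from a known observer parameterisation."""
    return proportion_later(design, xi_params, noise_spec, cfg, dt=dt)


def fit_gcdf(points: Sequence[PsychometricPoint], dt: float = 1e-3) -> GCDFFit:
    """Least-squares cumulative-Gaussian fit to one psychometric curve.

    Fits Phi((ttc - m)/s) to the proportions over ttc for a single size
    and presentation time; m is the point of subjective simultaneity, s
    the spread.  Initialisation takes m from the 50% crossing of linear
    interpolation; s is bounded below by the sampling step dt.  Flat or
    otherwise uninformative data yield a flagged degenerate fit.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 distinct ttc levels")
    order = np.argsort([p.ttc for p in points])
    x = np.array([points[i].ttc for i in order], dtype=float)
    y = np.array([points[i].proportion_later for i in order], dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct ttc levels")
    if np.ptp(y) < 1e-12:
        return GCDFFit(pse_mean=float(np.mean(x)), sd=float(np.ptp(x)), sse=float("nan"), degenerate=True)

    # 50% crossing of the linearly interpolated curve as the PSE start
    if y[0] <= 0.5 <= y[-1]:
        m0 = float(np.interp(0.5, y, x)) if np.all(np.diff(y) >= 0) else float(
            x[np.argmin(np.abs(y - 0.5))]
        )
    else:
        m0 = float(x[np.argmin(np.abs(y - 0.5))])
    s0 = max(float(np.ptp(x)) / 4.0, dt)

    def model(xx, m, s):
        return norm.cdf((xx - m) / s)

    try:
        popt, _ = curve_fit(
            model,
            x,
            y,
            p0=(m0, s0),
            bounds=([x[0] - 10 * np.ptp(x), dt], [x[-1] + 10 * np.ptp(x), 100 * np.ptp(x)]),
            maxfev=10000,
        )
    except RuntimeError:
        return GCDFFit(pse_mean=m0, sd=s0, sse=float("inf"), degenerate=True)
    resid = y - model(x, *popt)
    sse = float(np.sum(resid**2))
    degenerate = not math.isfinite(sse)
    return GCDFFit(pse_mean=float(popt[0]), sd=float(popt[1]), sse=sse, degenerate=degenerate)
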