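"""Fitting looming functions to firing-rate time courses.

Collision-sensitive neurons (e.g. the locust LGMD/DCMD) respond to an
approaching object with a firing-rate transient that peaks before
contact, at a time that depends linearly on the stimulus ratio
x = R/|v|.  This module fits members of the looming-function family to
rate traces indexed by time relative to collision (negative before
contact):

    rate(t) ~= A * f(t - delta) + baseline

where f is the eta function (shape parameter alpha), m-Tau (shape
parameter mu), inverse tau, or the angular acceleration theta_ddot.
The last two have no shape parameter that could move their maximum, so
only amplitude, delay and baseline are free for them.  The delay delta
is a rigid time shift of the stimulus function, matching the common
identification of a line-fit intercept with a neuronal latency.

For fixed shape and delay the model is linear in (A, baseline), so those
are solved in closed form and the outer optimisation runs over the one
or two remaining parameters from multiple log-spaced starts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize

from .functions import EtaParams, numeric_peak
from .kinematics import ApproachStimulus
from .linearity import LineFit, weighted_line_fit

__all__ = [
    "FiringRateTrace",
    "FitResult",
    "MODEL_REGISTRY",
    "fit_model_to_trace",
    "goodness_of_fit",
    "synth_firing_trace",
    "peak_linearity_report",
]

_D_FLOOR = 1e-9  # distance floor; fits never evaluate post-contact geometry


@dataclass
class FiringRateTrace:
    """A firing-rate time course with its stimulus geometry.

    times are seconds relative to collision (negative before contact);
    rate is in spikes/s or arbitrary units.
    """

    times: np.ndarray
    rate: np.ndarray
    stim_half_size: float
    stim_speed: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.times.size != self.rate.size:
            raise ValueError("times and rate must have equal length")
        if self.times.size < 5:
            raise ValueError("trace too short")
        if self.stim_half_size <= 0 or self.stim_speed <= 0:
            raise ValueError("stimulus half-size and speed must be positive")

    @property
    def x_ratio(self) -> float:
        """Half-size-to-speed ratio R/|v|, seconds."""
        return self.stim_half_size / self.stim_speed


@dataclass(frozen=True)
class FitResult:
    """Summary of one looming-function fit to a rate trace."""

    model_name: str
    fitted_params: dict[str, float]
    rmse: float
    r2: float
    f_stat: float
    f_dof: tuple[int, int]
    t_peak_pred: float
    t_peak_obs: float
    converged: bool = True


def _geometry(trace: FiringRateTrace, delay: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """theta, theta_dot, theta_ddot at the delay-shifted times.

    Positive delay advances the stimulus function, so the predicted peak
    leads contact by the shape-determined lead plus delta (intercept of
    the peak-vs-x line equals the delay).
    """
    R, v = trace.stim_half_size, trace.stim_speed
    d = np.maximum(-v * (trace.times + delay), _D_FLOOR)
    theta = 2.0 * np.arctan(R / d)
    theta_dot = 2.0 * R * v / (d * d + R * R)
    theta_ddot = 4.0 * R * v**2 * d / (d * d + R * R) ** 2
    return theta, theta_dot, theta_ddot


def _shape_eta(trace, shape, delay):
    theta, theta_dot, _ = _geometry(trace, delay)
    return theta_dot * np.exp(-shape * theta)


def _shape_m_tau(trace, shape, delay):
    theta, theta_dot, _ = _geometry(trace, delay)
    return theta / (shape + theta_dot)


def _shape_inverse_tau(trace, shape, delay):
    theta, theta_dot, _ = _geometry(trace, delay)
    return theta_dot / theta


def _shape_theta_ddot(trace, shape, delay):
    _, _, theta_ddot = _geometry(trace, delay)
    return theta_ddot


#: model name -> (shape-function, has_shape_parameter)
MODEL_REGISTRY: dict[str, tuple[Callable, bool]] = {
    "eta": (_shape_eta, True),
    "m_tau": (_shape_m_tau, True),
    "inverse_tau": (_shape_inverse_tau, False),
    "theta_ddot": (_shape_theta_ddot, False),
}


def _linear_amplitude(f: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Closed-form (A, baseline) minimising ||A f + b - y||^2; returns SSE."""
    X = np.column_stack([f, np.ones_like(f)])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 2:
        raise np.linalg.LinAlgError("rank-deficient design (constant shape function)")
    resid = y - X @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def goodness_of_fit(obs, pred, n_params: int) -> dict[str, float | tuple[int, int]]:
    """rmse, r2 and the F statistic against the constant-mean model."""
    obs = np.asarray(obs, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("obs and pred must have equal length")
    n = obs.size
    if n_params >= n:
        raise ValueError("need n_params < number of points")
    resid = obs - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / n))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    df1 = max(n_params - 1, 1)
    df2 = n - n_params
    if ss_res > 0:
        f_stat = ((ss_tot - ss_res) / df1) / (ss_res / df2)
    else:
        f_stat = float("inf")
    return {"rmse": rmse, "r2": r2, "f_stat": float(f_stat), "f_dof": (df1, df2)}


def fit_model_to_trace(
    trace: FiringRateTrace,
    model_name: str,
    delay_bounds: tuple[float, float] | None = None,
    shape_starts: Sequence[float] | None = None,
) -> FitResult:
    """Nonlinear least squares of A*f(t - delta) + baseline to the rate.

    Shape starts are log-spaced over four decades (1e-2..1e2 by default);
    amplitude and baseline are profiled out in closed form.  Ties in SSE
    break toward the smaller shape parameter.  Non-convergence returns a
    flagged result with the best parameters found.
    """
    if model_name not in MODEL_REGISTRY:
        raise ValueError(f"unknown model {model_name!r}; registry: {sorted(MODEL_REGISTRY)}")
    shape_fn, has_shape = MODEL_REGISTRY[model_name]
    y = trace.rate
    if np.ptp(y) == 0:
        raise ValueError("rank-deficient data: constant rate trace")
    t = trace.times
    span = float(t[-1] - t[0])
    if delay_bounds is None:
        # the shifted times must stay pre-contact: t - delta < 0
        hi = min(0.25 * span, -float(t[-1]) + 0.5 * span) if t[-1] < 0 else 0.0
        delay_bounds = (-0.25 * span, max(hi, 0.0))
    if shape_starts is None:
        shape_starts = np.logspace(-2, 2, 5)

    def sse_of(vec) -> float:
        if has_shape:
            log_shape, delay = vec
            shape = float(np.exp(log_shape))
        else:
            (delay,) = vec
            shape = 0.0
        delay = float(np.clip(delay, *delay_bounds))
        f = shape_fn(trace, shape, delay)
        if not np.all(np.isfinite(f)) or np.ptp(f) == 0:
            return float("inf")
        try:
            _, _, sse = _linear_amplitude(f, y)
        except np.linalg.LinAlgError:
            return float("inf")
        return sse

    best = None  # (sse, shape, delay, converged)
    starts = (
        [(float(np.log(s)), 0.0) for s in shape_starts] if has_shape else [(0.0,)]
    )
    for x0 in starts:
        res = minimize(sse_of, x0=np.array(x0), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000})
        if has_shape:
            shape = float(np.exp(res.x[0]))
            delay = float(np.clip(res.x[1], *delay_bounds))
        else:
            shape = 0.0
            delay = float(np.clip(res.x[0], *delay_bounds))
        cand = (float(res.fun), shape, delay, bool(res.success))
        if best is None or cand[0] < best[0] - 1e-15 or (
            abs(cand[0] - best[0]) <= 1e-15 and cand[1] < best[1]
        ):
            best = cand
    sse, shape, delay, converged = best
    f = shape_fn(trace, shape, delay)
    A, baseline, _ = _linear_amplitude(f, y)
    pred = A * f + baseline
    n_params = 4 if has_shape else 3
    gof = goodness_of_fit(y, pred, n_params)
    peak_pred = numeric_peak(pred, t)
    peak_obs = numeric_peak(y, t)
    fitted: dict[str, float] = {"amplitude": A, "baseline": baseline, "delay": delay}
    if has_shape:
        fitted["alpha" if model_name == "eta" else "mu"] = shape
    return FitResult(
        model_name=model_name,
        fitted_params=fitted,
        rmse=gof["rmse"],
        r2=gof["r2"],
        f_stat=gof["f_stat"],
        f_dof=gof["f_dof"],
        t_peak_pred=peak_pred.t_peak,
        t_peak_obs=peak_obs.t_peak,
        converged=converged,
    )


def synth_firing_trace(
    stim: ApproachStimulus,
    eta_params: EtaParams,
    noise_rel: float = 0.0,
    seed: int = 0,
    window: tuple[float, float] | None = None,
) -> FiringRateTrace:
    """Synthetic eta-shaped rate trace with seeded relative Gaussian noise.

    Samples A*theta_dot*exp(-alpha*theta) + baseline over ``window``
    (seconds relative to collision; defaults to the whole approach up to
    one dt before contact) and perturbs multiplicatively by
    (1 + noise_rel * N).  The trace carries the stimulus geometry so the
    fitters can reconstruct the optical variables.
    """
    tc = stim.collision_time_tc
    if window is None:
        window = (-tc + stim.dt, -stim.dt)
    t_rel = np.arange(window[0], window[1] + 0.5 * stim.dt, stim.dt)
    t_abs = t_rel + tc
    d = np.maximum(stim.speed_v * (tc - t_abs - eta_params.delay_delta), _D_FLOOR)
    R, v = stim.half_size_R, stim.speed_v
    theta = 2.0 * np.arctan(R / d)
    theta_dot = 2.0 * R * v / (d * d + R * R)
    clean = (
        eta_params.amplitude_C * theta_dot * np.exp(-eta_params.alpha * theta)
        + eta_params.baseline
    )
    if noise_rel > 0:
        rng = np.random.default_rng(seed)
        rate = clean * (1.0 + noise_rel * rng.standard_normal(clean.size))
    else:
        rate = clean
    return FiringRateTrace(
        times=t_rel, rate=rate, stim_half_size=R, stim_speed=v
    )


def peak_linearity_report(fits: Sequence[FitResult], x_ratios: Sequence[float]) -> LineFit:
    """Regression of observed peak lead time on the stimulus ratio R/|v|.

    The lead time is -t_peak_obs (time before collision).  Requires at
    least 3 distinct x ratios; returns the full line-fit diagnostics.
    """
    if len(fits) != len(x_ratios):
        raise ValueError("fits and x_ratios must have equal length")
    x = np.asarray(x_ratios, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct x ratios")
    lead = np.array([-f.t_peak_obs for f in fits], dtype=float)
    return weighted_line_fit(x, lead)
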