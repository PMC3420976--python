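"""The looming-function family: tau, eta, m-Tau and corrected m-Tau (Xi).

Time-to-contact (ttc) can be recovered from monocular optical variables
alone.  For small angular sizes the classic tau function

    tau = theta / theta_dot  ~=  t_c - t

estimates the remaining time to contact.  Collision-sensitive neurons such
as the locust LGMD/DCMD instead show a transient peak before contact that
is well described by the eta function

    eta = C * theta_dot * exp(-alpha * theta),

whose maximum always occurs at the fixed angular size 2*arctan(1/alpha),
i.e. at distance d = alpha*R, so the peak leads contact by alpha*R/v plus a
fixed delay.

The modified tau (m-Tau) model

    m_tau = theta / (mu + theta_dot)

adds a leakage constant mu (rad/s) to the denominator.  This stabilises the
ratio and creates an eta-like pre-contact maximum: under the small-angle
approximation tau ~= t_c - t the maximum sits at distance
d_hat = sqrt(R^2 + 2 R v / mu).  The corrected m-Tau model (Xi) restores
the ttc-estimation property by adding back a low-pass-filtered version of
the correction term

    rho = mu * theta / (theta_dot * (mu + theta_dot))     (= tau - m_tau)

so that

    Xi = theta/(mu + theta_dot)
         + w * mu * theta_lp / (theta_dot_lp * (mu + theta_dot_lp) + eps)
         + kappa,

where theta_lp, theta_dot_lp are first-order low-pass filtered angular
variables, w is a single weight switching between eta-like (w=0) and
tau-like (w=1) behaviour, eps guards the denominator, and kappa is an
offset that is negligible in practice.  Xi is bounded by two limit
functions: ordinary tau (mu -> 0) and tau computed from the filtered
variables (mu -> infinity), the latter with far better noise suppression.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .kinematics import ApproachStimulus, OpticalTrace

__all__ = [
    "XiParams",
    "EtaParams",
    "PeakResult",
    "tau",
    "m_tau",
    "m_tau_peak_closed_form",
    "eta",
    "eta_peak_closed_form",
    "correction_rho",
    "lowpass_filter",
    "corrected_m_tau",
    "lp_tau",
    "inverse_tau",
    "numeric_peak",
    "tau_min_distance_ratio",
    "THETA_DDOT_PEAK_RATIO",
]

#: theta_ddot peaks at distance d = R / sqrt(3).
THETA_DDOT_PEAK_RATIO = 1.0 / np.sqrt(3.0)


@lru_cache(maxsize=1)
def tau_min_distance_ratio() -> float:
    """Distance (in units of R) of the tau minimum on a clean approach.

    tau(t) has a minimum shortly before contact where 2 d arctan(R/d) = R;
    the same critical equation locates the inverse-tau maximum.  The root
    is d/R = 0.4289779...
    """
    return brentq(lambda x: 2.0 * x * np.arctan(1.0 / x) - 1.0, 0.05, 1.0, xtol=1e-14)


@dataclass(frozen=True)
class XiParams:
    """Parameters of the corrected m-Tau model.

    mu : leakage constant, rad/s, >= 0.
    w : weight on the filtered correction term, >= 0 (0 -> m-Tau,
        1 with no filtering -> tau).
    xi_theta, xi_theta_dot : filter memory coefficients in [0, 1);
        0 means no filtering, values near 1 mean long memory.
    kappa : additive offset in seconds (negligible in practice).
    eps : denominator guard against division by zero.
    """

    mu: float = 1.0
    w: float = 1.0
    xi_theta: float = 0.0
    xi_theta_dot: float = 0.0
    kappa: float = 0.0
    eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.w < 0:
            raise ValueError("w must be >= 0")
        for name in ("xi_theta", "xi_theta_dot"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")


@dataclass(frozen=True)
class EtaParams:
    """Parameters of the eta function C * theta_dot * exp(-alpha*theta)."""

    alpha: float = 1.0
    amplitude_C: float = 1.0
    delay_delta: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.amplitude_C <= 0:
            raise ValueError("amplitude_C must be positive")


@dataclass(frozen=True)
class PeakResult:
    """Location and height of a function maximum along an approach."""

    t_peak: float
    value_peak: float
    theta_at_peak: float | None = None
    at_boundary: bool = False
    degenerate: bool = False
    before_onset: bool = False


def tau(theta, theta_dot):
    """tau = theta / theta_dot, seconds; requires theta_dot > 0."""
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    if np.any(theta_dot <= 0):
        raise ValueError("tau undefined for theta_dot <= 0")
    return theta / theta_dot


def m_tau(theta, theta_dot, mu: float):
    """Modified tau: theta / (mu + theta_dot).

    Equals tau times the gain factor g = theta_dot/(mu + theta_dot), so
    m_tau <= tau pointwise and m_tau -> tau as mu -> 0.
    """
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    denom = mu + theta_dot
    if np.any(denom <= 0):
        raise ValueError("m_tau undefined for mu + theta_dot <= 0")
    return theta / denom


def inverse_tau(theta, theta_dot):
    """theta_dot / theta (1/s); its maximum coincides with the tau minimum."""
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    if np.any(theta <= 0):
        raise ValueError("inverse_tau undefined for theta <= 0")
    return theta_dot / theta


def eta(theta, theta_dot, p: EtaParams):
    """eta = C * theta_dot * exp(-alpha * theta) + baseline."""
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    return p.amplitude_C * theta_dot * np.exp(-p.alpha * theta) + p.baseline


def correction_rho(theta, theta_dot, mu: float, eps: float = 0.0):
    """Positive correction factor rho = mu*theta / (theta_dot*(mu+theta_dot) + eps).

    With eps = 0 this is exactly tau - m_tau.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    theta = np.asarray(theta, dtype=float)
    theta_dot = np.asarray(theta_dot, dtype=float)
    return mu * theta / (theta_dot * (mu + theta_dot) + eps)


def m_tau_peak_closed_form(stim: ApproachStimulus, mu: float) -> PeakResult:
    """Small-angle closed-form maximum of m-Tau.

    Under tau ~= t_c - t the maximum sits at distance
    d_hat = sqrt(R^2 + 2 R v / mu), i.e. at t_peak = t_c - d_hat / v.
    Larger mu pushes the peak toward contact; larger R pulls it earlier
    (size effect); larger v at fixed t_c pushes it later (velocity effect).
    """
    if mu <= 0:
        raise ValueError("mu must be positive for a finite peak")
    R, v, tc = stim.half_size_R, stim.speed_v, stim.collision_time_tc
    d_hat = np.sqrt(R * R + 2.0 * R * v / mu)
    t_peak = tc - d_hat / v
    # peak height of (t_c - t) * theta_dot/(mu + theta_dot) at d_hat
    theta_dot_hat = 2.0 * R * v / (d_hat * d_hat + R * R)
    value = (d_hat / v) * theta_dot_hat / (mu + theta_dot_hat)
    theta_hat = 2.0 * np.arctan(R / d_hat)
    return PeakResult(
        t_peak=float(t_peak),
        value_peak=float(value),
        theta_at_peak=float(theta_hat),
        before_onset=bool(t_peak < 0),
    )


def eta_peak_closed_form(stim: ApproachStimulus, p: EtaParams) -> PeakResult:
    """Closed-form maximum of eta: at distance d = alpha*R, so
    t_c - t_peak = alpha * R / v + delay, with theta at the peak fixed at
    2*arctan(1/alpha) regardless of R/v."""
    R, v, tc = stim.half_size_R, stim.speed_v, stim.collision_time_tc
    lead = p.alpha * R / v + p.delay_delta
    t_peak = tc - lead
    d_hat = p.alpha * R
    theta_dot_hat = 2.0 * R * v / (d_hat * d_hat + R * R)
    theta_hat = 2.0 * np.arctan(1.0 / p.alpha)
    value = p.amplitude_C * theta_dot_hat * np.exp(-p.alpha * theta_hat) + p.baseline
    return PeakResult(
        t_peak=float(t_peak),
        value_peak=float(value),
        theta_at_peak=float(theta_hat),
        before_onset=bool(t_peak < 0),
    )


def lowpass_filter(series, xi: float, init: float | None = None) -> np.ndarray:
    """First-order low-pass filter with memory coefficient xi in [0, 1).

    y[0] = init (defaults to the first sample, avoiding initial filter
    transients); y[k] = xi * y[k-1] + (1 - xi) * x[k].  xi = 0 reproduces
    the input.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    if not 0.0 <= xi < 1.0:
        raise ValueError("xi must lie in [0, 1)")
    if init is None:
        init = float(x[0])
    if x.size == 1:
        return np.array([init])
    # y[k] for k >= 1 follows the IIR recursion seeded with state xi*init
    rest, _ = lfilter([1.0 - xi], [1.0, -xi], x[1:], zi=np.array([xi * init]))
    return np.concatenate(([init], rest))


def corrected_m_tau(trace: OpticalTrace, params: XiParams) -> np.ndarray:
    """Corrected m-Tau (Xi) evaluated per trace sample, seconds.

    Xi[k] = theta[k]/(mu + theta_dot[k])
            + w * mu * th[k] / (thd[k]*(mu + thd[k]) + eps) + kappa,
    where th, thd are the low-pass-filtered angular variables, initialised
    with the first trace samples.  With w=1 and no filtering (xi=0, eps=0,
    kappa=0) this is algebraically identical to tau; with w=0, kappa=0 it
    is m-Tau.

    On noisy traces a non-positive first denominator is replaced by the
    eps guard rather than raising.
    """
    mu = params.mu
    theta, theta_dot = trace.theta, trace.theta_dot
    denom = mu + theta_dot
    bad = denom <= 0
    if np.any(bad):
        denom = np.where(bad, params.eps, denom)
    base = theta / denom
    th_lp = lowpass_filter(theta, params.xi_theta)
    thd_lp = lowpass_filter(theta_dot, params.xi_theta_dot)
    corr = mu * th_lp / (thd_lp * (mu + thd_lp) + params.eps)
    return base + params.w * corr + params.kappa


def lp_tau(trace: OpticalTrace, xi_theta: float, xi_theta_dot: float) -> np.ndarray:
    """tau computed from low-pass-filtered angular variables.

    This is the large-mu limit function of Xi; with xi = 0 it equals tau.
    """
    th = lowpass_filter(trace.theta, xi_theta)
    thd = lowpass_filter(trace.theta_dot, xi_theta_dot)
    if np.any(thd <= 0):
        raise ValueError("lp_tau undefined: filtered theta_dot <= 0")
    return th / thd


def numeric_peak(series, times) -> PeakResult:
    """Grid argmax refined by 3-point parabolic interpolation.

    Interior maxima are preferred over boundary values; a maximum on the
    boundary is flagged, an all-equal series is flagged degenerate, and
    ties between equal interior maxima break to the earliest sample.
    """
    y = np.asarray(series, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.size != t.size:
        raise ValueError("series and times must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    if np.all(y == y[0]):
        return PeakResult(t_peak=float(t[0]), value_peak=float(y[0]), degenerate=True)
    ymax = y.max()
    # prefer interior maxima; np.argmax already takes the earliest of ties
    interior = np.flatnonzero(y[1:-1] == ymax)
    if interior.size:
        k = int(interior[0]) + 1
        if np.count_nonzero(y == ymax) > 1:
            # tied maxima: report the earliest grid point, no refinement
            return PeakResult(t_peak=float(t[k]), value_peak=float(y[k]))
        dt = t[1] - t[0]
        y0, y1, y2 = y[k - 1], y[k], y[k + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:  # strictly concave triple: refine the vertex
            shift = 0.5 * (y0 - y2) / denom
            shift = float(np.clip(shift, -0.5, 0.5))
            t_peak = t[k] + shift * dt
            v_peak = y1 - 0.25 * (y0 - y2) * shift
        else:  # flat-topped tie: keep the grid point
            t_peak, v_peak = t[k], y1
        return PeakResult(t_peak=float(t_peak), value_peak=float(v_peak))
    k = int(np.argmax(y))
    return PeakResult(t_peak=float(t[k]), value_peak=float(y[k]), at_boundary=True)
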