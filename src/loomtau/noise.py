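"""Noisification of optical variables with reproducible randomness.

Sensor-level fluctuations (finite photoreceptor spacing, limited spatial
resolution) are emulated by perturbing angular size and angular velocity
independently with centred Gaussian deviates.  In *relative* mode the
perturbation scales with the signal,

    x_noisy[k] = x[k] * (1 + p * N[k]),

which keeps the signal-to-noise ratio constant along the approach and
makes smaller objects intrinsically noisier in absolute terms.  In
*absolute* mode the deviates are added directly, x[k] + p * N[k], so the
SNR improves as the object looms.  The two channels use independent
streams split deterministically from one seed, so trial ``i`` is
reproducible regardless of how many trials are run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .kinematics import OpticalTrace

__all__ = ["NoiseSpec", "noisify_trace"]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels p in [0, 1] per channel, mode, and seed."""

    p_theta: float = 0.0
    p_theta_dot: float = 0.0
    mode: str = "relative"
    seed: int = 0
    floor_at_zero: bool = False

    def __post_init__(self) -> None:
        for name in ("p_theta", "p_theta_dot"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mode not in ("relative", "absolute"):
            raise ValueError("mode must be 'relative' or 'absolute'")

    def with_seed(self, seed: int) -> "NoiseSpec":
        return replace(self, seed=seed)


def _channel_rngs(seed: int, extra_entropy: Sequence[int]) -> tuple[np.random.Generator, np.random.Generator]:
    ss = np.random.SeedSequence([int(seed), *[int(e) for e in extra_entropy]])
    child_theta, child_theta_dot = ss.spawn(2)
    return np.random.default_rng(child_theta), np.random.default_rng(child_theta_dot)


def noisify_trace(
    trace: OpticalTrace, spec: NoiseSpec, extra_entropy: Sequence[int] = ()
) -> OpticalTrace:
    """Return a noisified copy of a clean optical trace.

    ``extra_entropy`` (e.g. a trial index) is folded into the seed so that
    per-trial streams are independent yet individually reproducible.
    Noisifying an already-noisy trace raises, preventing double
    application.
    """
    if trace.is_noisy:
        raise ValueError("trace is already noisy; refusing to noisify twice")
    n = len(trace)
    rng_theta, rng_theta_dot = _channel_rngs(spec.seed, extra_entropy)
    n_theta = rng_theta.standard_normal(n)
    n_theta_dot = rng_theta_dot.standard_normal(n)
    if spec.mode == "relative":
        theta = trace.theta * (1.0 + spec.p_theta * n_theta)
        theta_dot = trace.theta_dot * (1.0 + spec.p_theta_dot * n_theta_dot)
    else:
        theta = trace.theta + spec.p_theta * n_theta
        theta_dot = trace.theta_dot + spec.p_theta_dot * n_theta_dot
    if spec.floor_at_zero:
        theta = np.maximum(theta, 0.0)
        theta_dot = np.maximum(theta_dot, 0.0)
    return OpticalTrace(
        times=trace.times.copy(),
        theta=theta,
        theta_dot=theta_dot,
        theta_ddot=None,
        is_noisy=True,
        stimulus=trace.stimulus,
    )
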