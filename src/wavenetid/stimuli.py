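"""Applied-current generators: stepwise random plateaus and a stochastic
oscillatory process.

The stepwise series holds uniformly distributed random values from the
physiological interval 𝓘 for ΔT each, long enough for the neuron to settle
into the corresponding equilibrium or limit cycle; it drives both training
and one kind of testing.  The oscillatory testing current follows a
mean-reverting (Ornstein–Uhlenbeck-type) process whose target oscillates
slowly around a baseline drawn from 𝓘.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StepwiseStimulusConfig",
    "OscillatoryStimulusConfig",
    "generate_stepwise",
    "generate_oscillatory",
]


@dataclass(frozen=True)
class StepwiseStimulusConfig:
    """Piecewise-constant random current: ``n_values`` plateaus of ``delta_t`` ms."""

    n_values: int
    delta_t: float
    interval: tuple
    dt: float
    seed: int | None = None

    def __post_init__(self):
        if self.n_values < 1:
            raise ValueError("n_values must be >= 1")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        lo, hi = self.interval
        if not lo < hi:
            raise ValueError("interval must satisfy lo < hi")


@dataclass(frozen=True)
class OscillatoryStimulusConfig:
    """Mean-reverting stochastic current with a slow cosine drift target.

    ``dI = (1/tau) (I0 + nu cos(omega t + phase) - I) dt + noise``.  With the
    default ``intrinsic_noise`` scaling the Wiener increment is damped by the
    same relaxation rate (diffusion sigma/tau), keeping the stationary spread
    sigma/sqrt(2 tau) small compared to the physiological interval; the
    literal unscaled diffusion is available with ``intrinsic_noise=False``.
    Times are in ms.
    """

    tau: float
    nu: float
    sigma_noise: float
    omega: float
    i_app0: float
    dt: float
    duration: float
    phase: float = 0.0
    seed: int | None = None
    intrinsic_noise: bool = True

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def stationary_sd(self) -> float:
        """Stationary standard deviation of the noise-driven fluctuations."""
        if self.intrinsic_noise:
            return self.sigma_noise / np.sqrt(2.0 * self.tau)
        return self.sigma_noise * np.sqrt(self.tau / 2.0)


def generate_stepwise(cfg: StepwiseStimulusConfig) -> np.ndarray:
    """Sampled stepwise current; exactly ``delta_t/dt`` samples per plateau."""
    ratio = cfg.delta_t / cfg.dt
    samples_per = int(round(ratio))
    if abs(ratio - samples_per) > 1e-9 * max(ratio, 1.0):
        raise ValueError(
            f"delta_t={cfg.delta_t} is not an integer multiple of dt={cfg.dt}"
        )
    rng = np.random.default_rng(cfg.seed)
    values = rng.uniform(cfg.interval[0], cfg.interval[1], size=cfg.n_values)
    return np.repeat(values, samples_per)


def generate_oscillatory(cfg: OscillatoryStimulusConfig) -> np.ndarray:
    """Euler–Maruyama discretization of the oscillatory process.

    ``I[m+1] = I[m] + (dt/tau)(I0 + nu cos(omega t_m + phase) - I[m])
    + s sqrt(dt) z_m`` with ``z_m`` standard normal and ``s`` the diffusion
    (``sigma/tau`` by default, ``sigma`` in literal mode).  ``I[0] = I0``.
    A zero-noise trace is deterministic and independent of the seed.
    """
    n = int(round(cfg.duration / cfg.dt))
    t = np.arange(n) * cfg.dt
    drift_target = cfg.i_app0 + cfg.nu * np.cos(cfg.omega * t + cfg.phase)
    diffusion = cfg.sigma_noise / cfg.tau if cfg.intrinsic_noise else cfg.sigma_noise
    if cfg.sigma_noise > 0:
        rng = np.random.default_rng(cfg.seed)
        kicks = diffusion * np.sqrt(cfg.dt) * rng.standard_normal(n - 1)
    else:
        kicks = np.zeros(n - 1)
    out = np.empty(n)
    out[0] = cfg.i_app0
    a = cfg.dt / cfg.tau
    for m in range(n - 1):
        out[m + 1] = out[m] + a * (drift_target[m] - out[m]) + kicks[m]
    return out
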