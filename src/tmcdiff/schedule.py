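"""Variance-preserving noise schedules for the diffusion chain.

Conventions: step t runs 0..T with clean data at t=0; the forward marginal is
``x_t = alpha_t * x_0 + sigma_t * eps`` with ``alpha_t^2 + sigma_t^2 = 1``.
``alpha_0 = 1`` exactly (identity) and ``alpha_T`` is clipped slightly above 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCHEDULE_KINDS = ("polynomial", "cosine")


@dataclass(frozen=True)
class NoiseSchedule:
    kind: str
    T: int
    alpha: np.ndarray   # (T+1,), alpha[0] = 1, decreasing
    sigma: np.ndarray   # (T+1,), sqrt(1 - alpha^2)

    def step_coeffs(self, t: int, s: int) -> tuple[float, float]:
        """Transition coefficients from step s to t (s < t):
        alpha_{t|s} = alpha_t / alpha_s, sigma_{t|s}^2 = sigma_t^2 - alpha_{t|s}^2 sigma_s^2."""
        a_ts = self.alpha[t] / self.alpha[s]
        var = self.sigma[t] ** 2 - a_ts**2 * self.sigma[s] ** 2
        return float(a_ts), float(max(var, 0.0))


def make_schedule(T: int, kind: str = "polynomial") -> NoiseSchedule:
    """Build a monotone variance-preserving schedule.

    ``polynomial`` (default): alpha_t = (1 - (t/T)^2)^2, the smooth power-2
    schedule common for molecular point clouds. ``cosine``: alpha_t^2
    proportional to cos^2((t/T + s)/(1 + s) * pi/2).
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    t = np.arange(T + 1, dtype=np.float64)
    if kind == "polynomial":
        alpha = (1.0 - (t / T) ** 2) ** 2
    elif kind == "cosine":
        s = 0.008
        f = np.cos((t / T + s) / (1 + s) * np.pi / 2) ** 2
        alpha = np.sqrt(f / f[0])
    else:
        raise ValueError(f"unknown schedule kind {kind!r}; known kinds: {SCHEDULE_KINDS}")
    # keep alpha strictly inside (0, 1] and strictly decreasing for stable ratios
    alpha = np.clip(alpha, 1e-4, 1.0)
    alpha = np.minimum.accumulate(alpha)
    for i in range(1, T + 1):
        if alpha[i] >= alpha[i - 1]:
            alpha[i] = alpha[i - 1] * (1 - 1e-7)
    sigma = np.sqrt(1.0 - alpha**2)
    return NoiseSchedule(kind=kind, T=T, alpha=alpha, sigma=sigma)
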