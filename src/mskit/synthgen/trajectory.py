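"""Latent motion-sickness-level trajectories.

Symptoms accumulate with stimulus exposure, so the latent trajectory is a
logistic ramp (onset time and rise time drawn per session) scaled by the
participant's susceptibility, plus stationary AR(1) noise, clipped to be
non-negative.  A susceptibility of zero yields an identically zero
trajectory; higher susceptibility yields stochastically larger terminal
values.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter


def ar1_noise(n: int, rng: np.random.Generator, sigma: float,
              phi: float = 0.9) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sigma``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    w = rng.standard_normal(n) * sigma * np.sqrt(1 - phi ** 2)
    x = lfilter([1.0], [1.0, -phi], w)
    x[0] = rng.standard_normal() * sigma
    return np.asarray(x)


def generate_msl_trajectory(duration_s: float, susceptibility: float,
                            ms_type: str = "CMS",
                            seed: int | np.random.SeedSequence = 0,
                            rate_hz: float = 1.0) -> np.ndarray:
    """Latent MSL sampled at ``rate_hz`` (default 1 Hz), dimensionless >= 0."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if susceptibility < 0:
        raise ValueError("susceptibility must be >= 0")
    n = int(round(duration_s * rate_hz))
    if susceptibility == 0:
        return np.zeros(n)
    rng = np.random.default_rng(seed)
    type_scale = {"CMS": 1.0, "VIMS": 0.85, "Co-MS": 1.2}.get(ms_type, 1.0)
    t = np.arange(n) / rate_hz
    t0 = rng.uniform(0.25, 0.6) * duration_s
    tau = rng.uniform(0.07, 0.13) * duration_s
    ramp = susceptibility * type_scale / (1.0 + np.exp(-(t - t0) / tau))
    noise = ar1_noise(n, rng, sigma=0.08 * susceptibility, phi=0.9)
    return np.clip(ramp + noise, 0.0, None)


def fms_reports(msl: np.ndarray, rng: np.random.Generator,
                interval_s: float = 30.0, rate_hz: float = 1.0,
                ) -> list[tuple[float, float]]:
    """Quantized 1-5 FMS reports derived from the latent trajectory.

    The latent value is mapped by a clipped affine transform (1 + 2 x MSL),
    perturbed by small observation noise, and rounded to the report scale.
    A baseline report at t = 0 precedes the 30-s cadence.
    """
    duration = len(msl) / rate_hz
    times = np.arange(0.0, duration, interval_s)
    out = []
    for t in times:
        latent = msl[min(int(round(t * rate_hz)), len(msl) - 1)]
        val = 1.0 + 2.0 * latent + rng.normal(0.0, 0.15)
        out.append((float(t), float(np.clip(np.round(val), 1, 5))))
    return out
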