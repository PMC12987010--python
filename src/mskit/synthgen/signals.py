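"""Per-sensor synthetic signal construction.

Each stream is a baseline oscillatory/noise process whose amplitude (or
spectral balance, for gaze and EEG) is modulated by the latent MSL through
the planted loadings:

- PPG: harmonic pulse wave with slow heart-rate variability.
- EDA: tonic Ornstein-Uhlenbeck drift plus phasic (sudomotor-like) bumps,
  both scaled by the ``eda_amplitude`` loading; stored as resistance kOhm.
- EEG: per-channel pink noise plus a 10-Hz rhythm whose amplitude rises as
  the (negative) ``eeg_sample_entropy`` loading demands — a more rhythmic
  signal is a more regular one.
- SKT: slow temperature drift.
- Head pose / IMU: band-limited motion noise; the pitch/surge channels are
  scaled by ``head_pitch_surge_energy``.
- Eye: gaze yaw/pitch mix a slow and a fast process; the mixing weight (and
  hence the spectral flatness) rises with ``eye_direction_psd_entropy``.
  Blinks null the per-eye positions and directions.

Noise correlation times are kept well below the 30-s analysis window so
that, with all loadings zero, window features are approximately independent
across windows.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter


def _ou(n: int, rate: float, tau_s: float, sigma: float,
        rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck process sampled at ``rate``."""
    if n == 0:
        return np.zeros(0)
    phi = float(np.exp(-1.0 / (tau_s * rate)))
    w = rng.standard_normal(n) * sigma * np.sqrt(1 - phi ** 2)
    w[0] = rng.standard_normal() * sigma
    return np.asarray(lfilter([1.0], [1.0, -phi], w))


def _pink(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f-amplitude noise via spectral shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if len(f) > 1 else 1.0
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _amp(msl_norm: np.ndarray, loading: float) -> np.ndarray:
    """Multiplicative amplitude factor: clip(1 + loading x MSL, 0.05, 3)."""
    return np.clip(1.0 + loading * msl_norm, 0.05, 3.0)


def msl_at_rate(msl_1hz: np.ndarray, rate: float, n: int) -> np.ndarray:
    """Latent MSL resampled to a sensor clock, normalized and clipped."""
    t = np.arange(n) / rate
    src_t = np.arange(len(msl_1hz))
    return np.clip(np.interp(t, src_t, msl_1hz), 0.0, 2.0)


def gen_ppg(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
            rng: np.random.Generator) -> np.ndarray:
    hr = 1.1 + 0.05 * np.sin(2 * np.pi * 0.25 * np.arange(n) / rate)
    hr = hr + _ou(n, rate, 2.0, 0.02, rng)
    phase = 2 * np.pi * np.cumsum(hr) / rate
    x = np.sin(phase) + 0.3 * np.sin(2 * phase) + 0.1 * np.sin(3 * phase)
    return x + 0.05 * rng.standard_normal(n)


def gen_eda_kohm(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
                 rng: np.random.Generator) -> np.ndarray:
    """Skin resistance in kOhm (sensor convention); conductance is 1000/R."""
    a = _amp(msl_norm, loadings.get("eda_amplitude", 0.0))
    # build at a coarse clock, then upsample
    sub = 16.0
    m = int(np.ceil(n * sub / rate))
    a_sub = a[np.minimum((np.arange(m) * rate / sub).astype(int), n - 1)]
    tonic = _ou(m, sub, 5.0, 0.15, rng) * a_sub
    phasic = np.zeros(m)
    n_events = rng.poisson(0.08 * m / sub)
    kernel_t = np.arange(0, 10.0, 1 / sub)
    kernel = (kernel_t / 1.0) * np.exp(1 - kernel_t / 3.0)
    kernel /= kernel.max()
    for _ in range(n_events):
        i0 = int(rng.uniform(0, m))
        amp = rng.lognormal(np.log(0.3), 0.4) * a_sub[i0]
        seg = kernel[:m - i0]
        phasic[i0:i0 + len(seg)] += amp * seg
    g0 = rng.uniform(4.0, 8.0)
    g_sub = g0 + tonic + phasic
    t_full = np.arange(n) / rate
    g = np.interp(t_full, np.arange(m) / sub, g_sub)
    g = g + 0.01 * rng.standard_normal(n)
    g = np.clip(g, 0.2, None)
    return 1000.0 / g


def gen_eeg(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
            rng: np.random.Generator, n_channels: int = 8) -> np.ndarray:
    """8-channel EEG: pink background + common 10-Hz rhythm, microvolt scale."""
    osc_amp = _amp(msl_norm, -loadings.get("eeg_sample_entropy", 0.0))
    t = np.arange(n) / rate
    envelope = 1.0 + 0.3 * _ou(n, rate, 2.0, 1.0, rng)
    alpha = np.sin(2 * np.pi * 10.0 * t + rng.uniform(0, 2 * np.pi))
    common = _pink(n, rng)
    out = np.empty((n, n_channels))
    # occipital channels (last two) carry a stronger rhythm
    gains = np.array([0.8, 0.8, 0.9, 0.9, 1.0, 1.0, 1.3, 1.3])[:n_channels]
    for c in range(n_channels):
        chan_noise = _pink(n, rng)
        out[:, c] = (10.0 * (0.6 * common + 0.8 * chan_noise)
                     + 8.0 * gains[c] * osc_amp * envelope * alpha)
    return out


def gen_skt(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
            rng: np.random.Generator) -> np.ndarray:
    return 33.0 + _ou(n, rate, 60.0, 0.3, rng) + 0.02 * rng.standard_normal(n)


def gen_head_pose(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
                  rng: np.random.Generator) -> np.ndarray:
    """Positions sway/heave/surge (m) and rotations pitch/yaw/roll (deg)."""
    a = _amp(msl_norm, loadings.get("head_pitch_surge_energy", 0.0))
    cols = []
    for name, sigma, scaled in (("pos_sway", 0.010, False),
                                ("pos_heave", 0.010, False),
                                ("pos_surge", 0.012, True),
                                ("rot_pitch", 2.0, True),
                                ("rot_yaw", 2.0, False),
                                ("rot_roll", 1.5, False)):
        x = _ou(n, rate, 0.5, sigma, rng)
        cols.append(x * a if scaled else x)
    return np.column_stack(cols)


def gen_head_imu(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
                 rng: np.random.Generator) -> np.ndarray:
    """Accelerations sway/heave/surge (m/s^2), angular rates p/y/r (deg/s)."""
    a = _amp(msl_norm, loadings.get("head_pitch_surge_energy", 0.0))
    cols = []
    for name, sigma, scaled in (("acc_sway", 0.20, False),
                                ("acc_heave", 0.20, False),
                                ("acc_surge", 0.25, True),
                                ("gyro_pitch", 5.0, True),
                                ("gyro_yaw", 5.0, False),
                                ("gyro_roll", 4.0, False)):
        x = _ou(n, rate, 0.4, sigma, rng)
        cols.append(x * a if scaled else x)
    return np.column_stack(cols)


def _angles_to_dir(yaw_deg: np.ndarray, pitch_deg: np.ndarray) -> np.ndarray:
    yaw = np.radians(yaw_deg)
    pitch = np.radians(pitch_deg)
    return np.column_stack([np.cos(pitch) * np.sin(yaw),
                            np.sin(pitch),
                            np.cos(pitch) * np.cos(yaw)])


def gen_eye(n: int, rate: float, msl_norm: np.ndarray, loadings: dict,
            rng: np.random.Generator) -> np.ndarray:
    """18-column eye stream: L/R/C positions then L/R/C gaze directions.

    Blinks (Poisson, ~12 per minute, 150-300 ms) null the per-eye positions
    and directions; the center gaze holds its last value.
    """
    w = np.clip(0.3 + loadings.get("eye_direction_psd_entropy", 0.0)
                * msl_norm, 0.05, 0.95)

    def mixed_angle(scale: float) -> np.ndarray:
        slow = _ou(n, rate, 2.0, scale, rng)
        fast = _ou(n, rate, 0.12, scale, rng)
        return (1 - w) * slow + w * fast

    yaw = mixed_angle(6.0)
    pitch = mixed_angle(4.0)
    dir_c = _angles_to_dir(yaw, pitch)
    # binocular convergence: eyes toe in by ~1.5 degrees
    dir_l = _angles_to_dir(yaw + 1.5, pitch)
    dir_r = _angles_to_dir(yaw - 1.5, pitch)
    pos_c = np.zeros((n, 3))
    pos_l = np.tile([-0.032, 0.0, 0.0], (n, 1))
    pos_r = np.tile([0.032, 0.0, 0.0], (n, 1))
    pos_l += 0.0002 * rng.standard_normal((n, 3))
    pos_r += 0.0002 * rng.standard_normal((n, 3))

    duration = n / rate
    n_blinks = rng.poisson(12.0 * duration / 60.0)
    blink = np.zeros(n, dtype=bool)
    for _ in range(n_blinks):
        t0 = rng.uniform(0, duration)
        dur = rng.uniform(0.15, 0.30)
        i0, i1 = int(t0 * rate), int((t0 + dur) * rate)
        blink[i0:min(i1, n)] = True
    for arr in (pos_l, pos_r, dir_l, dir_r):
        arr[blink] = np.nan
    return np.column_stack([pos_l, pos_r, pos_c, dir_l, dir_r, dir_c])


GENERATORS = {
    "ppg": gen_ppg,
    "eda": gen_eda_kohm,
    "eeg": gen_eeg,
    "skt": gen_skt,
    "head_pose": gen_head_pose,
    "head_imu": gen_head_imu,
    "eye": gen_eye,
}
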