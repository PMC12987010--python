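"""EEG region-band signals, power ratios, and functional-brain-network metrics.

The eight 10-20 channels are grouped into five scalp regions; crossing the
regions with six bands (whole + five standard bands) yields the 30 SwF
source signals.  Seven band-power ratios summarize the global spectrum, and
the functional brain network (FBN) contributes magnitude-squared coherence
and phase-locking value for each of the 28 channel pairs per band
(6 x 28 x 2 = 336 window-derived features).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.signal import coherence as _coherence, decimate, hilbert

from .swf import BAND_SCHEMES, WelchSpec, welch_psd

EEG_CHANNELS = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")
EEG_REGIONS: dict[str, tuple[str, ...]] = {
    "global": EEG_CHANNELS,
    "frontal": ("F3", "F4"),
    "central": ("C3", "C4"),
    "parietal": ("P3", "P4"),
    "occipital": ("O1", "O2"),
}
EEG_BANDS = ("whole", "delta", "theta", "alpha", "beta", "gamma")
#: Registry order of the seven band-power-ratio WdFs.
EEG_RATIO_NAMES = ("beta_alpha", "alphatheta_beta", "theta_alpha", "theta_beta",
                   "alphatheta_alphabeta", "beta_alphatheta", "Ftheta_Palpha")

_ENTROPY_RATE_HZ = 125.0


def downsample_for_entropy(x: np.ndarray, rate: float) -> np.ndarray:
    """Decimate to 125 Hz (zero-phase FIR) for sample-entropy computation."""
    factor = int(round(rate / _ENTROPY_RATE_HZ))
    if factor <= 1:
        return np.asarray(x, dtype=float)
    return decimate(np.asarray(x, dtype=float), factor, ftype="fir",
                    zero_phase=True, axis=0)


def eeg_region_band_signals(
    channels: dict[str, np.ndarray],
    band_filtered: dict[str, dict[str, np.ndarray]],
) -> dict[tuple[str, str], np.ndarray]:
    """Average per-channel band signals into the 30 region-band signals.

    ``band_filtered[band][channel]`` holds the zero-phase band-pass filtered
    copy of each channel (``"whole"`` maps to the processed signal itself).
    """
    missing = [c for c in EEG_CHANNELS if c not in channels]
    if missing:
        raise ValueError(f"missing EEG channels: {missing}")
    out: dict[tuple[str, str], np.ndarray] = {}
    for region, chs in EEG_REGIONS.items():
        for band in EEG_BANDS:
            sigs = [band_filtered[band][c] for c in chs]
            out[(region, band)] = np.mean(sigs, axis=0)
    return out


def eeg_power_ratios(band_powers: dict[tuple[str, str], float]) -> dict[str, float]:
    """Seven spectral-ratio WdFs from region-band powers.

    Six ratios use the global region; the frontal-theta / parietal-alpha
    ratio crosses regions.  Zero denominators yield NaN (missing-flagged).
    """
    g = {b: band_powers[("global", b)] for b in ("alpha", "beta", "theta")}
    a, b, t = g["alpha"], g["beta"], g["theta"]
    f_t = band_powers[("frontal", "theta")]
    p_a = band_powers[("parietal", "alpha")]

    def _div(num: float, den: float) -> float:
        return float(num / den) if den > 0 else float("nan")

    return {
        "beta_alpha": _div(b, a),
        "alphatheta_beta": _div(a + t, b),
        "theta_alpha": _div(t, a),
        "theta_beta": _div(t, b),
        "alphatheta_alphabeta": _div(a + t, a + b),
        "beta_alphatheta": _div(b, a + t),
        "Ftheta_Palpha": _div(f_t, p_a),
    }


def plv(x: np.ndarray, y: np.ndarray) -> float:
    """Phase-locking value from analytic-signal instantaneous phases."""
    px = np.angle(hilbert(np.asarray(x, dtype=float)))
    py = np.angle(hilbert(np.asarray(y, dtype=float)))
    return float(np.abs(np.exp(1j * (px - py)).mean()))


def band_coherence(x: np.ndarray, y: np.ndarray, rate: float,
                   band: tuple[float, float], spec: WelchSpec) -> float:
    """Magnitude-squared coherence averaged over the in-band Welch bins."""
    nperseg = min(spec.segment_length, len(x))
    if len(x) < 2 * nperseg:
        # fewer than two Welch segments: coherence is degenerate (always 1)
        return float("nan")
    f, c = _coherence(x, y, fs=rate, nperseg=nperseg,
                      nfft=max(spec.fft_length, nperseg), noverlap=nperseg // 2)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        return float("nan")
    return float(c[mask].mean())


def eeg_fbn(
    band_filtered: dict[str, dict[str, np.ndarray]],
    rate: float,
    spec: WelchSpec | None = None,
    coherence_nperseg: int | None = None,
) -> dict[tuple[str, str, str, str], float]:
    """Coherence and PLV for every channel pair per band.

    Returns a mapping ``(band, ch_a, ch_b, metric) -> value`` with
    28 pairs x 6 bands x 2 metrics = 336 entries.  ``coherence_nperseg``
    optionally shortens the Welch segments so short windows still contain
    two segments.
    """
    if spec is None:
        spec = WelchSpec(fft_length=2048, segment_length=2048)
    if coherence_nperseg is not None:
        spec = WelchSpec(fft_length=max(spec.fft_length, coherence_nperseg),
                         segment_length=coherence_nperseg)
    scheme = BAND_SCHEMES["eeg"]
    out: dict[tuple[str, str, str, str], float] = {}
    for band in EEG_BANDS:
        sigs = band_filtered[band]
        lo, hi = scheme[band]
        for ch_a, ch_b in combinations(EEG_CHANNELS, 2):
            out[(band, ch_a, ch_b, "coherence")] = band_coherence(
                sigs[ch_a], sigs[ch_b], rate, (lo, hi), spec)
            out[(band, ch_a, ch_b, "plv")] = plv(sigs[ch_a], sigs[ch_b])
    return out
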