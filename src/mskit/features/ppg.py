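"""PPG window-derived features: beat detection, HRV indices, LF/HF, breath rate.

The beat detector operates on the 0.66-3.33 Hz pre-filtered window: local
maxima above an adaptive (mean + 0.5 SD) threshold with a refractory period
of 0.3 s.  SD1/SD2 use the Poincaré fallback identities
``SD1 = RMSSD / sqrt(2)`` and ``SD2^2 = 2 SDNN^2 - SDSD^2 / 2``; the
sympathetic and vagal indices follow the Toichi formulas ``CSI = L / T`` and
``CVI = log10(L x T)`` with ``T = 4 SD1`` and ``L = 4 SD2``.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks, welch

from .swf import BAND_SCHEMES

#: Registry order of the 12 PPG window-derived features.
PPG_WDF_NAMES = ("HR", "IBI", "SDNN", "RMSSD", "SD1", "SD2", "SD1_SD2",
                 "CSI", "CVI", "CSI_CVI", "LF_HF", "BR")

_REFRACTORY_S = 0.3
_RESAMPLE_HZ = 4.0


def detect_beats(x: np.ndarray, rate: float) -> np.ndarray:
    """Return beat times (s) in a band-limited PPG window."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.array([])
    thresh = x.mean() + 0.5 * x.std()
    peaks, _ = find_peaks(x, height=thresh,
                          distance=max(int(round(_REFRACTORY_S * rate)), 1))
    return peaks / rate


def _nan_wdfs() -> dict[str, float]:
    return {k: float("nan") for k in PPG_WDF_NAMES}


def ppg_wdfs(x: np.ndarray, rate: float) -> dict[str, float]:
    """Compute the 12 PPG WdFs for one pre-filtered window.

    Windows with fewer than five detectable beats return all-NaN
    (missing-flagged) values.
    """
    beats = detect_beats(x, rate)
    if len(beats) < 5:
        return _nan_wdfs()
    ibi = np.diff(beats) * 1000.0  # ms
    out = _nan_wdfs()
    mean_ibi = float(ibi.mean())
    out["IBI"] = mean_ibi
    out["HR"] = 60000.0 / mean_ibi
    sdnn = float(np.std(ibi, ddof=1))
    dibi = np.diff(ibi)
    rmssd = float(np.sqrt(np.mean(dibi ** 2)))
    sdsd = float(np.std(dibi, ddof=1))
    out["SDNN"] = sdnn
    out["RMSSD"] = rmssd
    sd1 = rmssd / np.sqrt(2.0)
    sd2sq = 2.0 * sdnn ** 2 - 0.5 * sdsd ** 2
    sd2 = float(np.sqrt(sd2sq)) if sd2sq > 0 else 0.0
    out["SD1"] = sd1
    out["SD2"] = sd2
    if sd2 > 0:
        out["SD1_SD2"] = sd1 / sd2
    t_axis, l_axis = 4.0 * sd1, 4.0 * sd2
    if t_axis > 0:
        out["CSI"] = l_axis / t_axis
    if l_axis * t_axis > 0:
        out["CVI"] = float(np.log10(l_axis * t_axis))
    if not np.isnan(out["CVI"]) and out["CVI"] != 0 and not np.isnan(out["CSI"]):
        out["CSI_CVI"] = out["CSI"] / out["CVI"]

    # Spectral indices from the evenly resampled, detrended IBI series.
    if len(ibi) >= 4:
        t_mid = beats[1:]
        grid = np.arange(t_mid[0], t_mid[-1], 1.0 / _RESAMPLE_HZ)
        if len(grid) >= 8:
            series = np.interp(grid, t_mid, ibi)
            series = series - np.polyval(np.polyfit(grid, series, 1), grid)
            nper = min(len(series), int(_RESAMPLE_HZ * 20))
            f, p = welch(series, fs=_RESAMPLE_HZ, nperseg=nper,
                         nfft=max(256, nper))
            lf_lo, lf_hi = BAND_SCHEMES["ppg"]["LF"]
            hf_lo, hf_hi = BAND_SCHEMES["ppg"]["HF"]
            lf = p[(f >= lf_lo) & (f < lf_hi)].sum()
            hf = p[(f >= hf_lo) & (f < hf_hi)].sum()
            if hf > 0:
                out["LF_HF"] = float(lf / hf)
            # Breath rate from respiratory modulation of the IBI series,
            # constrained to the physiological 4-60 breaths/min range.
            resp = (f >= 4.0 / 60.0) & (f <= 1.0)
            if resp.any() and p[resp].max() > 0:
                f_br = f[resp][int(np.argmax(p[resp]))]
                out["BR"] = float(np.clip(f_br * 60.0, 4.0, 60.0))
    return out
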