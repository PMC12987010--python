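"""Signal-wise feature (SwF) templates and band decomposition.

Every source signal receives the same eight-feature template:

- time domain: mean, variance, kurtosis, skewness, sample entropy
  (m = 2, r = 0.2 x SD), peak-to-peak amplitude;
- frequency domain: band power and PSD entropy (Shannon entropy, base 2, of
  the band-normalized Welch PSD).

Windows that preprocessing has split into discontinuous segments are handled
by computing each feature per segment and averaging across segments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from ..prefilter import bandpass

#: Time-domain template feature names, in registry order.
TIME_FEATURES = ("mean", "var", "kurtosis", "skewness", "sample_entropy", "ptp")
#: Frequency-domain template feature names.
FREQ_FEATURES = ("band_power", "psd_entropy")

#: Named sub-band schemes per sensor.  "whole" always denotes the sensor's
#: full processed band.
BAND_SCHEMES: dict[str, dict[str, tuple[float, float]]] = {
    "ppg": {"whole": (0.1, 10.0), "LF": (0.1, 0.15), "HF": (0.15, 0.4)},
    "eda": {"whole": (0.03, 5.0), "SCL": (0.0, 0.05), "SCR": (0.05, 2.0),
            "LF": (0.045, 0.25)},
    "eeg": {"whole": (1.0, 50.0), "delta": (1.0, 4.0), "theta": (4.0, 8.0),
            "alpha": (8.0, 13.0), "beta": (13.0, 30.0), "gamma": (30.0, 50.0)},
}


@dataclass(frozen=True)
class WelchSpec:
    """Welch PSD parameters. DC exclusion and negative clipping are always on."""

    fft_length: int
    segment_length: int

    def __post_init__(self) -> None:
        if self.segment_length > self.fft_length:
            raise ValueError("segment_length must be <= fft_length")


#: Welch presets: 128-Hz PPG/EDA use a long FFT for narrow-band resolution;
#: 500-Hz EEG uses FFT 2048 (~0.24 Hz/bin); 30/4/1-Hz streams use rate x 20 s.
WELCH_SPECS: dict[str, WelchSpec] = {
    "ppg": WelchSpec(fft_length=8192, segment_length=2560),
    "eda": WelchSpec(fft_length=8192, segment_length=2560),
    "eeg": WelchSpec(fft_length=2048, segment_length=2048),
}


def welch_spec_for(sensor: str, rate: float) -> WelchSpec:
    spec = WELCH_SPECS.get(sensor)
    if spec is None:
        n = max(int(round(rate * 20.0)), 2)
        spec = WelchSpec(fft_length=n, segment_length=n)
    return spec


def sample_entropy(x: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Sample entropy with Chebyshev matching (embedding ``m``, r = 0.2 SD).

    A zero-variance segment has no irregularity and is defined to have
    entropy 0.  If either template count vanishes the estimate is undefined
    and NaN is returned (propagated downstream as a missing value).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"need at least {m + 2} samples, got {n}")
    sd = float(np.std(x))
    if sd == 0.0:
        return 0.0
    r = r_factor * sd

    def _count(mm: int) -> int:
        from scipy.spatial import cKDTree
        emb = np.ascontiguousarray(
            np.lib.stride_tricks.sliding_window_view(x, mm))
        tree = cKDTree(emb)
        # pairs i < j with Chebyshev distance <= r
        return len(tree.query_pairs(r, p=np.inf, output_type="ndarray"))

    b = _count(m)
    a = _count(m + 1)
    if b == 0 or a == 0:
        return float("nan")
    return float(-np.log(a / b))


def _segment_list(segments) -> list[np.ndarray]:
    if isinstance(segments, np.ndarray) and segments.ndim == 1:
        segments = [segments]
    segs = [np.asarray(s, dtype=float) for s in segments]
    segs = [s[~np.isnan(s)] for s in segs]  # NaN frames excluded (e.g. vergence)
    segs = [s for s in segs if len(s) > 0]
    if not segs:
        raise ValueError("window contains no valid samples")
    return segs


def swf_time(segments, m: int = 2, r_factor: float = 0.2,
             entropy_signal=None, names=None) -> dict[str, float]:
    """Time-domain SwF template, averaged across discontinuous segments.

    ``entropy_signal`` optionally supplies separate segments for the sample
    entropy (e.g. EEG downsampled to 125 Hz) while the moments use the full
    rate signal.  ``names`` restricts computation to a subset of the
    template (sample entropy is costly enough to skip when unused).
    """
    segs = _segment_list(segments)
    want = set(TIME_FEATURES if names is None else names)

    def _agg(vals: list[float]) -> float:
        arr = np.asarray(vals, dtype=float)
        ok = ~np.isnan(arr)
        return float(arr[ok].mean()) if ok.any() else float("nan")

    out: dict[str, float] = {}
    moment_segs = [s for s in segs if len(s) >= 4]
    if not moment_segs:
        moment_segs = segs
    if "mean" in want:
        out["mean"] = _agg([float(np.mean(s)) for s in segs])
    if "var" in want:
        out["var"] = _agg([float(np.var(s, ddof=1)) if len(s) > 1 else 0.0
                           for s in moment_segs])
    if "kurtosis" in want:
        out["kurtosis"] = _agg([float(spstats.kurtosis(s)) for s in moment_segs])
    if "skewness" in want:
        out["skewness"] = _agg([float(spstats.skew(s)) for s in moment_segs])
    if "ptp" in want:
        out["ptp"] = _agg([float(np.ptp(s)) for s in segs])
    if "sample_entropy" in want:
        ent_segs = segs if entropy_signal is None else _segment_list(entropy_signal)
        ents = [sample_entropy(s, m=m, r_factor=r_factor)
                for s in ent_segs if len(s) >= m + 2]
        out["sample_entropy"] = _agg(ents) if ents else float("nan")
    return out


def welch_psd(x: np.ndarray, rate: float, spec: WelchSpec,
              ) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with DC bin excluded and numerical negatives clipped to 0."""
    x = np.asarray(x, dtype=float)
    nperseg = min(spec.segment_length, len(x))
    f, p = sps.welch(x, fs=rate, nperseg=nperseg, nfft=max(spec.fft_length, nperseg),
                     noverlap=nperseg // 2, window="hann", detrend="constant")
    keep = f > 0.0
    return f[keep], np.clip(p[keep], 0.0, None)


def _band_mask(f: np.ndarray, low: float, high: float, upper_inclusive: bool) -> np.ndarray:
    if upper_inclusive:
        return (f >= low) & (f <= high)
    return (f >= low) & (f < high)


def swf_freq(segments, rate: float, band: tuple[float, float],
             spec: WelchSpec, upper_inclusive: bool = True) -> dict[str, float]:
    """Frequency-domain SwF template: band power and PSD entropy (bits).

    Band power sums the Welch PSD bins inside the band times the bin width;
    PSD entropy is the base-2 Shannon entropy of the PSD normalized to unit
    sum over the band.
    """
    low, high = band
    if not (0 <= low < high <= rate / 2.0):
        raise ValueError(f"band ({low}, {high}) outside [0, Nyquist]")
    segs = _segment_list(segments)
    powers, entropies = [], []
    for s in segs:
        if len(s) < 8:
            continue
        f, p = welch_psd(s, rate, spec)
        mask = _band_mask(f, low, high, upper_inclusive)
        if not mask.any():
            raise ValueError(f"band ({low}, {high}) contains no PSD bins")
        df = f[1] - f[0]
        pb = p[mask]
        powers.append(float(pb.sum() * df))
        tot = pb.sum()
        if tot > 0:
            q = pb / tot
            q = q[q > 0]
            entropies.append(float(-(q * np.log2(q)).sum()))
        else:
            entropies.append(float("nan"))
    if not powers:
        return {"band_power": float("nan"), "psd_entropy": float("nan")}
    ent = np.asarray(entropies)
    ent_ok = ent[~np.isnan(ent)]
    return {
        "band_power": float(np.mean(powers)),
        "psd_entropy": float(ent_ok.mean()) if len(ent_ok) else float("nan"),
    }


def band_signals(x: np.ndarray, rate: float, scheme: dict[str, tuple[float, float]],
                 mode: str = "time", spec: WelchSpec | None = None):
    """Decompose a signal into named sub-bands.

    ``mode="time"`` returns zero-phase band-pass filtered copies (the whole
    band is passed through unfiltered — it is already the processed signal).
    ``mode="freq"`` partitions the Welch PSD of the full-band signal by band
    edges; each interior bin belongs to exactly one band (lower edge
    inclusive, upper exclusive, except at the uppermost edge of the scheme).
    """
    x = np.asarray(x, dtype=float)
    if mode == "time":
        out: dict[str, np.ndarray] = {}
        for name, (low, high) in scheme.items():
            if name == "whole":
                out[name] = x
            else:
                out[name] = bandpass(x, rate, max(low, 0.0), high) if low > 0 \
                    else bandpass(x, rate, 0.0, high)
        return out
    if mode == "freq":
        if spec is None:
            raise ValueError("freq mode requires a WelchSpec")
        f, p = welch_psd(x, rate, spec)
        top = max(high for _, high in scheme.values())
        parts: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for name, (low, high) in scheme.items():
            mask = _band_mask(f, low, high, upper_inclusive=(high == top))
            parts[name] = (f[mask], p[mask])
        return parts
    raise ValueError(f"unknown mode {mode!r}")
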