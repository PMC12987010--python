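"""Per-sensor preprocessing chains.

Each physiological stream gets a fixed, deterministic, length-preserving
chain:

- PPG:  notch {30, 60} Hz -> band-pass 0.1-10 Hz
- EDA:  resistance->conductance -> notch {60} Hz -> band-pass 0.03-5 Hz
- EEG:  notch {60, 120, 180, 240} Hz (+/-5 Hz) -> band-pass 1-50 Hz ->
        common average reference -> artifact-removal hook
- SKT:  three-point moving average only (1 Hz stream; no resolvable line noise)

The notch is realized as zero-phase narrowband suppression in the frequency
domain (>=20 dB attenuation inside the notch, no ripple outside).  Band-pass
filters are Blackman-windowed linear-phase FIR designs applied with centred
(zero-phase) convolution over a reflection-padded signal; the filter order is
chosen so that one octave outside the band is attenuated by >=20 dB.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.signal import fftconvolve, firwin


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one sensor's preprocessing chain."""

    notch_freqs: tuple[float, ...] = ()
    notch_halfwidth: float = 1.0
    band: tuple[float, float] | None = None
    window_family: str = "blackman"
    extras: tuple[str, ...] = ()


def notch_suppress(
    signal: np.ndarray,
    rate: float,
    freqs: Sequence[float],
    halfwidth: float = 1.0,
) -> np.ndarray:
    """Zero-phase spectral suppression of narrow bands around ``freqs``.

    Power within each ``[f - halfwidth, f + halfwidth]`` is attenuated by far
    more than 20 dB (the core of the notch is zeroed); the transition tapers
    lie entirely inside the notch band, so the passband is untouched.
    """
    x = np.asarray(signal, dtype=float)
    nyq = rate / 2.0
    for f in freqs:
        if f >= nyq:
            raise ValueError(f"notch frequency {f} Hz >= Nyquist {nyq} Hz")
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    n = x.shape[0]
    freqs_fft = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = np.ones(len(freqs_fft))
    edge = 0.25 * halfwidth  # taper width, inside the notch band
    for f in freqs:
        d = np.abs(freqs_fft - f)
        core = d <= (halfwidth - edge)
        taper = (d > (halfwidth - edge)) & (d <= halfwidth)
        mask[core] = 0.0
        ramp = (d[taper] - (halfwidth - edge)) / edge
        mask[taper] = np.minimum(mask[taper], 0.5 - 0.5 * np.cos(np.pi * ramp))
    spec = np.fft.rfft(x, axis=0)
    if x.ndim == 2:
        spec *= mask[:, None]
    else:
        spec *= mask
    return np.fft.irfft(spec, n=n, axis=0)


def _bandpass_taps(rate: float, low: float, high: float,
                   window: str = "blackman", max_taps: int = 262_143) -> np.ndarray:
    nyq = rate / 2.0
    # Transition budget: reach the stopband one octave outside each edge.
    widths = []
    if low > 0:
        widths.append(low / 2.0)
    widths.append(min(high, nyq - high) if 2 * high > nyq else high)
    trans = max(min(widths), 1e-6)
    numtaps = int(np.ceil(5.5 * rate / trans))
    numtaps = min(numtaps | 1, max_taps)
    if low > 0:
        return firwin(numtaps, [low, high], pass_zero=False, window=window, fs=rate)
    return firwin(numtaps, high, pass_zero=True, window=window, fs=rate)


def bandpass(signal: np.ndarray, rate: float, low: float, high: float,
             window: str = "blackman") -> np.ndarray:
    """Zero-phase Blackman-window FIR band-pass (low-pass when ``low == 0``)."""
    if not (0 <= low < high < rate / 2.0):
        raise ValueError(f"invalid band ({low}, {high}) at rate {rate} Hz")
    x = np.asarray(signal, dtype=float)
    h = _bandpass_taps(rate, low, high, window=window)
    pad = (len(h) - 1) // 2
    pad = min(pad, max(x.shape[0] - 1, 1))
    if x.ndim == 2:
        xp = np.pad(x, ((pad, pad), (0, 0)), mode="reflect")
        y = fftconvolve(xp, h[:, None], mode="same", axes=0)
    else:
        xp = np.pad(x, pad, mode="reflect")
        y = fftconvolve(xp, h, mode="same")
    return y[pad:pad + x.shape[0]]


#: Pre-window-derived-feature PPG band (typical heart rates 40-200 bpm).
PPG_WDF_BAND = (0.66, 3.33)


def eda_resistance_to_conductance(r_kohm: np.ndarray) -> np.ndarray:
    """Convert skin resistance in kOhm to conductance in microsiemens (G = 1/R)."""
    r = np.asarray(r_kohm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("resistance must be positive")
    return 1000.0 / r


def eeg_common_average_reference(multichannel: np.ndarray) -> np.ndarray:
    """Subtract the per-sample mean across channels (CAR)."""
    x = np.asarray(multichannel, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return x - x.mean(axis=1, keepdims=True)


def eeg_artifact_hook(
    multichannel: np.ndarray,
    remover: Callable[[np.ndarray], np.ndarray] | None = None,
) -> np.ndarray:
    """Pluggable artifact-removal stage (e.g. an external ICA-based cleaner).

    The default remover is the identity: synthetic data carries no ocular or
    muscular components to strip.  Any callable may be plugged in as long as
    it preserves the (n_samples, n_channels) shape.
    """
    x = np.asarray(multichannel, dtype=float)
    if remover is None:
        return x
    out = np.asarray(remover(x), dtype=float)
    if out.shape != x.shape:
        raise ValueError(
            f"artifact remover changed shape {x.shape} -> {out.shape}"
        )
    return out


def skt_moving_average(signal: np.ndarray) -> np.ndarray:
    """Centred three-point moving average; edges use the available two points."""
    x = np.asarray(signal, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("signal too short for a three-point moving average")
    out = np.empty_like(x)
    out[1:-1] = (x[:-2] + x[1:-1] + x[2:]) / 3.0
    out[0] = (x[0] + x[1]) / 2.0
    out[-1] = (x[-2] + x[-1]) / 2.0
    return out


FILTER_SPECS: dict[str, FilterSpec] = {
    "ppg": FilterSpec(notch_freqs=(30.0, 60.0), notch_halfwidth=1.0,
                      band=(0.1, 10.0)),
    "eda": FilterSpec(notch_freqs=(60.0,), notch_halfwidth=1.0,
                      band=(0.03, 5.0), extras=("conductance",)),
    "eeg": FilterSpec(notch_freqs=(60.0, 120.0, 180.0, 240.0),
                      notch_halfwidth=5.0, band=(1.0, 50.0),
                      extras=("car", "artifact_hook")),
    "skt": FilterSpec(extras=("moving_average",)),
}


@dataclass
class Chain:
    """Ordered preprocessing chain for one sensor."""

    sensor: str
    steps: tuple[str, ...]
    spec: FilterSpec
    artifact_remover: Callable[[np.ndarray], np.ndarray] | None = None

    def apply(self, signal: np.ndarray, rate: float) -> np.ndarray:
        x = np.asarray(signal, dtype=float)
        for step in self.steps:
            if step == "conductance":
                x = eda_resistance_to_conductance(x)
            elif step == "notch":
                x = notch_suppress(x, rate, self.spec.notch_freqs,
                                   self.spec.notch_halfwidth)
            elif step == "bandpass":
                low, high = self.spec.band  # type: ignore[misc]
                x = bandpass(x, rate, low, high, window=self.spec.window_family)
            elif step == "car":
                x = eeg_common_average_reference(x)
            elif step == "artifact_hook":
                x = eeg_artifact_hook(x, self.artifact_remover)
            elif step == "moving_average":
                x = skt_moving_average(x)
            else:  # pragma: no cover - registry is static
                raise ValueError(f"unknown chain step {step!r}")
        return x


def build_chain(sensor: str,
                artifact_remover: Callable[[np.ndarray], np.ndarray] | None = None,
                ) -> Chain:
    """Chain registry: fixed step orderings per sensor."""
    spec = FILTER_SPECS.get(sensor)
    if spec is None:
        raise KeyError(f"no preprocessing chain for sensor {sensor!r}")
    orders = {
        "ppg": ("notch", "bandpass"),
        "eda": ("conductance", "notch", "bandpass"),
        "eeg": ("notch", "bandpass", "car", "artifact_hook"),
        "skt": ("moving_average",),
    }
    return Chain(sensor=sensor, steps=orders[sensor], spec=spec,
                 artifact_remover=artifact_remover)


def apply_chain(sensor: str, signal: np.ndarray, rate: float,
                artifact_remover: Callable[[np.ndarray], np.ndarray] | None = None,
                ) -> np.ndarray:
    """Apply the registered preprocessing chain of ``sensor`` to ``signal``."""
    return build_chain(sensor, artifact_remover).apply(signal, rate)
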