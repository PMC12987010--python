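"""Session-level feature extraction into a long-form feature table.

``extract_session`` takes preprocessed, grid-aligned streams for one session
and returns one row per (window, feature) with an explicit missing flag.
The ``descriptors`` argument restricts extraction to a registry subset, which
keeps targeted analyses (and their runtimes) proportional to what they use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import eye as eyemod
from . import head as headmod
from .eeg import (EEG_CHANNELS, EEG_REGIONS, downsample_for_entropy,
                  eeg_power_ratios)
from .ppg import ppg_wdfs
from .registry import (FeatureDescriptor, HEADIMU_SIGNALS, HEADPOSE_SIGNALS,
                       build_registry)
from .swf import (BAND_SCHEMES, FREQ_FEATURES, TIME_FEATURES, swf_freq,
                  swf_time, welch_spec_for)
from .windows import Window, WindowSet, map_fms, windowize  # noqa: F401
from ..prefilter import PPG_WDF_BAND, bandpass


def _nan_row(desc: FeatureDescriptor, widx: int) -> dict:
    return {"window": widx, "feature_id": desc.feature_id,
            "domain": desc.domain, "value": np.nan, "missing": True}


def _swf_rows(descs: list[FeatureDescriptor], widx: int,
              time_segments, freq_segments, rate: float, band: tuple,
              spec, entropy_segments=None) -> list[dict]:
    rows = []
    want_time = [d for d in descs if d.kind == "SwF-time"]
    want_freq = [d for d in descs if d.kind == "SwF-freq"]
    tvals: dict[str, float] = {}
    fvals: dict[str, float] = {}
    if want_time:
        try:
            tvals = swf_time(time_segments, entropy_signal=entropy_segments,
                             names=[d.name for d in want_time])
        except ValueError:
            tvals = {name: np.nan for name in TIME_FEATURES}
    if want_freq:
        try:
            fvals = swf_freq(freq_segments, rate, band, spec)
        except ValueError:
            fvals = {name: np.nan for name in FREQ_FEATURES}
    for d in want_time + want_freq:
        v = tvals.get(d.name) if d.kind == "SwF-time" else fvals.get(d.name)
        v = np.nan if v is None else v
        rows.append({"window": widx, "feature_id": d.feature_id,
                     "domain": d.domain, "value": v,
                     "missing": bool(np.isnan(v))})
    return rows


def _window_slice(values: np.ndarray, rate: float, w: Window) -> np.ndarray:
    i0 = int(round(w.start_s * rate))
    i1 = int(round(w.end_s * rate))
    return values[i0:i1]


def _extract_banded(domain: str, signal_name: str, x: np.ndarray, rate: float,
                    scheme: dict, descs: list[FeatureDescriptor],
                    windows: WindowSet, sensor: str) -> list[dict]:
    """SwF extraction for a sensor with named sub-bands (PPG, EDA)."""
    rows: list[dict] = []
    bands_needed = sorted({d.band for d in descs})
    spec = welch_spec_for(sensor, rate)
    time_copies: dict[str, np.ndarray] = {}
    for band in bands_needed:
        lo, hi = scheme[band]
        if band == "whole":
            time_copies[band] = x
        else:
            time_copies[band] = bandpass(x, rate, lo, hi)
    for widx, w in enumerate(windows):
        whole_seg = [_window_slice(x, rate, w)]
        for band in bands_needed:
            band_descs = [d for d in descs if d.band == band]
            seg = [_window_slice(time_copies[band], rate, w)]
            rows += _swf_rows(band_descs, widx, seg, whole_seg, rate,
                              scheme[band], spec)
    return rows


def _extract_plain(domain: str, x: np.ndarray, rate: float,
                   descs: list[FeatureDescriptor], windows: WindowSet,
                   sensor: str) -> list[dict]:
    """SwF extraction for an unbanded signal (whole band = full Nyquist)."""
    rows: list[dict] = []
    spec = welch_spec_for(sensor, rate)
    band = (0.0, rate / 2.0)
    for widx, w in enumerate(windows):
        seg = [_window_slice(x, rate, w)]
        rows += _swf_rows(descs, widx, seg, seg, rate, band, spec)
    return rows


def extract_session(
    streams: dict[str, np.ndarray],
    rates: dict[str, float],
    fms_reports: list[tuple[float, float]] | None = None,
    descriptors: list[FeatureDescriptor] | None = None,
    effective_length_s: float | None = None,
    window_s: float = 30.0,
    eeg_fbn_nperseg: int | None = None,
) -> pd.DataFrame:
    """Extract the requested features for one session.

    ``streams`` holds preprocessed, grid-aligned arrays keyed by sensor:
    ``ppg``, ``eda`` (conductance), ``skt`` (1-D); ``eeg`` (n, 8) in channel
    order F3,F4,C3,C4,P3,P4,O1,O2; ``head_pose`` (n, 6) as positions
    sway/heave/surge then rotations pitch/yaw/roll; ``head_imu`` (n, 6) as
    accelerations sway/heave/surge then angular velocities pitch/yaw/roll;
    ``eye`` (n, 18) as left/right/center positions then left/right/center
    gaze directions.  Returns a long-form table with columns
    window, feature_id, domain, value, missing (plus fms when reports given).
    """
    if descriptors is None:
        descriptors = [d for d in build_registry() if d.domain != "Demographic"]
    if effective_length_s is None:
        ref = next(iter(streams))
        effective_length_s = len(streams[ref]) / rates[ref]
    windows = windowize(effective_length_s, window_s)
    by_domain: dict[str, list[FeatureDescriptor]] = {}
    for d in descriptors:
        by_domain.setdefault(d.domain, []).append(d)

    rows: list[dict] = []

    if "PPG" in by_domain and "ppg" in streams:
        descs = by_domain["PPG"]
        swfs = [d for d in descs if d.kind.startswith("SwF")]
        wdfs = [d for d in descs if d.kind == "WdF"]
        rate = rates["ppg"]
        if swfs:
            rows += _extract_banded("PPG", "ppg", streams["ppg"], rate,
                                    BAND_SCHEMES["ppg"], swfs, windows, "ppg")
        if wdfs:
            x_wdf = bandpass(streams["ppg"], rate, *PPG_WDF_BAND)
            for widx, w in enumerate(windows):
                vals = ppg_wdfs(_window_slice(x_wdf, rate, w), rate)
                for d in wdfs:
                    v = vals.get(d.name, np.nan)
                    rows.append({"window": widx, "feature_id": d.feature_id,
                                 "domain": d.domain, "value": v,
                                 "missing": bool(np.isnan(v))})

    if "EDA" in by_domain and "eda" in streams:
        rows += _extract_banded("EDA", "eda", streams["eda"], rates["eda"],
                                BAND_SCHEMES["eda"], by_domain["EDA"],
                                windows, "eda")

    if "SKT" in by_domain and "skt" in streams:
        rows += _extract_plain("SKT", streams["skt"], rates["skt"],
                               by_domain["SKT"], windows, "skt")

    if "EEG" in by_domain and "eeg" in streams:
        rows += _extract_eeg(streams["eeg"], rates["eeg"], by_domain["EEG"],
                             windows, eeg_fbn_nperseg)

    if "HeadPose" in by_domain and "head_pose" in streams:
        rows += _extract_head_pose(streams["head_pose"], rates["head_pose"],
                                   by_domain["HeadPose"], windows)

    if "HeadIMU" in by_domain and "head_imu" in streams:
        hp = streams["head_imu"]
        rate = rates["head_imu"]
        for ci, sig in enumerate(HEADIMU_SIGNALS):
            descs = [d for d in by_domain["HeadIMU"] if d.signal == sig]
            if descs:
                rows += _extract_plain("HeadIMU", hp[:, ci], rate, descs,
                                       windows, "head_imu")

    if "Eye" in by_domain and "eye" in streams:
        rows += _extract_eye(streams["eye"], rates["eye"], by_domain["Eye"],
                             windows, streams.get("head_pose"),
                             rates.get("head_pose"))

    df = pd.DataFrame(rows)
    if fms_reports is not None and len(df):
        fms = {i: map_fms(fms_reports, w) for i, w in enumerate(windows)}
        df["fms"] = df["window"].map(fms)
    return df


def _extract_eeg(eeg: np.ndarray, rate: float, descs: list[FeatureDescriptor],
                 windows: WindowSet, fbn_nperseg: int | None) -> list[dict]:
    scheme = BAND_SCHEMES["eeg"]
    spec = welch_spec_for("eeg", rate)
    swfs = [d for d in descs if d.kind.startswith("SwF")]
    ratio_descs = [d for d in descs if d.signal == "ratios"]
    fbn_descs = [d for d in descs if "-" in d.signal]

    chan = {c: eeg[:, i] for i, c in enumerate(EEG_CHANNELS)}
    bands_needed = sorted({d.band for d in swfs}
                          | ({"alpha", "beta", "theta"} if ratio_descs else set())
                          | {d.band for d in fbn_descs})
    need_time_bands = sorted({d.band for d in swfs if d.kind == "SwF-time"}
                             | {d.band for d in fbn_descs})
    band_filtered: dict[str, dict[str, np.ndarray]] = {}
    for band in need_time_bands:
        lo, hi = scheme[band]
        if band == "whole":
            band_filtered[band] = chan
        else:
            band_filtered[band] = {c: bandpass(x, rate, lo, hi)
                                   for c, x in chan.items()}

    rows: list[dict] = []
    # region-band SwFs
    regions_needed = sorted({d.signal for d in swfs if d.signal in EEG_REGIONS})
    for region in regions_needed:
        chs = EEG_REGIONS[region]
        region_whole = np.mean([chan[c] for c in chs], axis=0)
        for band in sorted({d.band for d in swfs if d.signal == region}):
            band_descs = [d for d in swfs if d.signal == region and d.band == band]
            if band in band_filtered:
                sig = np.mean([band_filtered[band][c] for c in chs], axis=0)
            else:
                sig = None
            ent_full = downsample_for_entropy(sig, rate) if sig is not None else None
            ent_rate = rate / max(int(round(rate / 125.0)), 1)
            for widx, w in enumerate(windows):
                tseg = [_window_slice(sig, rate, w)] if sig is not None else None
                eseg = ([_window_slice(ent_full, ent_rate, w)]
                        if ent_full is not None else None)
                fseg = [_window_slice(region_whole, rate, w)]
                rows += _swf_rows(band_descs, widx,
                                  tseg if tseg is not None else fseg,
                                  fseg, rate, scheme[band], spec,
                                  entropy_segments=eseg)

    if ratio_descs:
        for widx, w in enumerate(windows):
            powers: dict[tuple[str, str], float] = {}
            for region in ("global", "frontal", "parietal"):
                chs = EEG_REGIONS[region]
                seg = [_window_slice(np.mean([chan[c] for c in chs], axis=0),
                                     rate, w)]
                for band in ("alpha", "beta", "theta"):
                    powers[(region, band)] = swf_freq(seg, rate, scheme[band],
                                                      spec)["band_power"]
            vals = eeg_power_ratios(powers)
            for d in ratio_descs:
                v = vals.get(d.name, np.nan)
                rows.append({"window": widx, "feature_id": d.feature_id,
                             "domain": "EEG", "value": v,
                             "missing": bool(np.isnan(v))})

    if fbn_descs:
        # compute only the requested pairs to bound cost
        from .eeg import band_coherence, plv as _plv
        from .swf import WelchSpec
        s2 = spec if fbn_nperseg is None else WelchSpec(
            fft_length=max(spec.fft_length, fbn_nperseg),
            segment_length=fbn_nperseg)
        for widx, w in enumerate(windows):
            win_bands = {band: {c: _window_slice(band_filtered[band][c], rate, w)
                                for c in EEG_CHANNELS}
                         for band in sorted({d.band for d in fbn_descs})}
            for d in fbn_descs:
                ch_a, ch_b = d.signal.split("-")
                sigs = win_bands[d.band]
                if d.name == "plv":
                    v = _plv(sigs[ch_a], sigs[ch_b])
                else:
                    v = band_coherence(sigs[ch_a], sigs[ch_b], rate,
                                       scheme[d.band], s2)
                rows.append({"window": widx, "feature_id": d.feature_id,
                             "domain": "EEG", "value": v,
                             "missing": bool(np.isnan(v))})
    return rows


def _extract_head_pose(hp: np.ndarray, rate: float,
                       descs: list[FeatureDescriptor],
                       windows: WindowSet) -> list[dict]:
    rows: list[dict] = []
    for ci, sig in enumerate(HEADPOSE_SIGNALS[:6]):
        col_descs = [d for d in descs if d.signal == sig]
        if col_descs:
            rows += _extract_plain("HeadPose", hp[:, ci], rate, col_descs,
                                   windows, "head_pose")
    dir_descs = [d for d in descs if d.signal in ("dir_yaw", "dir_pitch")]
    if dir_descs:
        from .swf import welch_spec_for as _wsf
        spec = _wsf("head_pose", rate)
        for widx, w in enumerate(windows):
            rot = _window_slice(hp[:, 3:6], rate, w)
            try:
                yaw, pitch = headmod.head_direction_signals(rot)
            except ValueError:
                for d in dir_descs:
                    rows.append(_nan_row(d, widx))
                continue
            for sig, arr in (("dir_yaw", yaw), ("dir_pitch", pitch)):
                sig_descs = [d for d in dir_descs if d.signal == sig]
                if sig_descs:
                    rows += _swf_rows(sig_descs, widx, [arr], [arr], rate,
                                      (0.0, rate / 2.0), spec)
    return rows


def _extract_eye(eye: np.ndarray, rate: float, descs: list[FeatureDescriptor],
                 windows: WindowSet, head_pose: np.ndarray | None,
                 head_rate: float | None) -> list[dict]:
    from .swf import welch_spec_for as _wsf
    spec = _wsf("eye", rate)
    pos_l, pos_r, pos_c = eye[:, 0:3], eye[:, 3:6], eye[:, 6:9]
    dir_l, dir_r, dir_c = eye[:, 9:12], eye[:, 12:15], eye[:, 15:18]

    cs_l = eyemod.denoise_closure(eyemod.eye_closure(pos_l, pos_c))
    cs_r = eyemod.denoise_closure(eyemod.eye_closure(pos_r, pos_c))
    cs_and, cs_or = eyemod.closure_combination(cs_l, cs_r)
    with np.errstate(invalid="ignore"):
        conv = eyemod.convergence_distance(pos_l, pos_r, dir_l, dir_r)
        dir_c_safe = np.where(np.isnan(dir_c), [[0.0, 0.0, 1.0]], dir_c)
        yaw, pitch = eyemod.gaze_angles(dir_c_safe)

    signals: dict[str, np.ndarray] = {
        "closure_and": cs_and.astype(float),
        "closure_or": cs_or.astype(float),
        "convergence_distance": conv,
        "gaze_yaw": yaw,
        "gaze_pitch": pitch,
    }
    swfs = [d for d in descs if d.kind.startswith("SwF")]
    wdf_descs = [d for d in descs if d.kind == "WdF"]
    rows: list[dict] = []
    for sig_name, arr in signals.items():
        sig_descs = [d for d in swfs if d.signal == sig_name]
        if sig_descs:
            rows += _extract_plain("Eye", arr, rate, sig_descs, windows, "eye")

    vel_descs = [d for d in swfs if d.signal == "gaze_velocity"]
    need_vel = bool(vel_descs) or any(
        d.name in ("saccade_ratio", "fixation_ratio", "path_length", "vor")
        for d in wdf_descs)
    for widx, w in enumerate(windows):
        if need_vel:
            dirs = _window_slice(dir_c_safe, rate, w)
            try:
                v, kin = eyemod.gaze_velocity(dirs, rate)
            except ValueError:
                v, kin = np.array([]), {"saccade_ratio": np.nan,
                                        "fixation_ratio": np.nan,
                                        "path_length": np.nan}
            if vel_descs and len(v):
                rows += _swf_rows(vel_descs, widx, [v], [v], rate,
                                  (0.0, rate / 2.0), spec)
            elif vel_descs:
                rows += [_nan_row(d, widx) for d in vel_descs]
        for d in wdf_descs:
            if d.name == "blink_rate":
                val = eyemod.blink_rate(_window_slice(cs_l, rate, w),
                                        _window_slice(cs_r, rate, w),
                                        w.length_s)
            elif d.name == "vergence_loss":
                cw = _window_slice(conv, rate, w)
                val = float(np.isnan(cw).mean()) if len(cw) else np.nan
            elif d.name in ("saccade_ratio", "fixation_ratio", "path_length"):
                val = kin.get(d.name, np.nan) if need_vel else np.nan
            elif d.name == "heatmap_entropy":
                try:
                    val = eyemod.heatmap_entropy(_window_slice(yaw, rate, w),
                                                 _window_slice(pitch, rate, w))
                except ValueError:
                    val = np.nan
            elif d.name == "vor":
                if head_pose is None or head_rate is None:
                    val = np.nan
                else:
                    rot = _window_slice(head_pose[:, 3:6], head_rate, w)
                    try:
                        hdirs = headmod.head_directions(rot)
                        hv, _ = eyemod.gaze_velocity(hdirs, head_rate)
                        gv = v if need_vel else None
                        if gv is None or len(gv) == 0:
                            val = np.nan
                        else:
                            m = min(len(gv), len(hv))
                            # align by resampling the shorter series
                            gv_i = np.interp(np.linspace(0, 1, m),
                                             np.linspace(0, 1, len(gv)), gv)
                            hv_i = np.interp(np.linspace(0, 1, m),
                                             np.linspace(0, 1, len(hv)), hv)
                            val = headmod.vor(gv_i, hv_i)
                    except ValueError:
                        val = np.nan
            else:
                val = np.nan
            rows.append({"window": widx, "feature_id": d.feature_id,
                         "domain": "Eye", "value": val,
                         "missing": bool(np.isnan(val))})
    return rows
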