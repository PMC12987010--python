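"""Recording degradations: fragmentation with overlap and chunk-timing jitter."""

from __future__ import annotations

import numpy as np

from ..types import SensorStream


def inject_fragmentation(stream: SensorStream, events: list[float],
                         overlap_s: float = 10.0) -> list[SensorStream]:
    """Split a stream into overlapping fragments at interruption times.

    An interruption at ``t`` ends the current fragment at ``t`` and restarts
    recording ``overlap_s`` earlier, so consecutive fragments share an
    ``overlap_s`` stretch of (identical) samples.  Zero events return the
    stream itself as a single fragment.
    """
    if overlap_s < 5:
        raise ValueError("overlap_s must be >= 5")
    t = stream.times
    t_start, t_end = float(t[0]), float(t[-1])
    events = sorted(events)
    for e in events:
        if not (t_start + overlap_s < e < t_end):
            raise ValueError(f"fragmentation event at {e} s outside session span")
    if not events:
        return [stream]
    fragments: list[SensorStream] = []
    cur_start = t_start
    for e in events + [np.inf]:
        mask = (t >= cur_start) & (t < e)
        fragments.append(SensorStream(
            name=stream.name, rate=stream.rate, values=stream.values[mask],
            channels=stream.channels, timestamps=t[mask]))
        cur_start = e - overlap_s
    return fragments


def perturb_chunk_timing(stream: SensorStream, chunk_rate_hz: float = 16.0,
                         max_dev_chunks: int = 1,
                         seed: int | np.random.SeedSequence = 0) -> SensorStream:
    """Jitter per-second sample counts by up to ``max_dev_chunks`` chunks.

    The transport delivers samples in chunks at roughly 15-20 Hz; scheduling
    and OS timing limits make the count logged in a 1-s interval deviate by
    about one chunk.  Because sample timing is synchronized to the reference
    clock, the deviation shows up as samples missing from (or interleaved
    into) a second rather than as re-timed samples: a short second drops one
    chunk's worth of samples, evenly spread across the second, and a long
    second gains interstitial samples read off the series midway between
    grid points.  The covered duration is unchanged and
    ``max_dev_chunks = 0`` is the identity.
    """
    if max_dev_chunks < 0:
        raise ValueError("max_dev_chunks must be >= 0")
    if max_dev_chunks == 0:
        return stream
    rng = np.random.default_rng(seed)
    t = stream.times
    v = np.asarray(stream.values, dtype=float)
    rate = stream.rate
    chunk = max(int(round(rate / chunk_rate_hz)), 1)
    n_seconds = int(np.ceil(stream.duration_s))
    t0 = float(t[0])
    keep = np.ones(len(t), dtype=bool)
    ins_t: list[np.ndarray] = []
    for s in range(n_seconds):
        dev = int(rng.integers(-max_dev_chunks, max_dev_chunks + 1))
        if dev == 0:
            continue
        sec = np.flatnonzero((t >= t0 + s) & (t < t0 + s + 1))
        if len(sec) < 2:
            continue
        k = min(abs(dev) * chunk, len(sec) - 1)
        if dev < 0:
            # drop k samples, evenly spread so gaps stay isolated
            drop = sec[np.linspace(0, len(sec) - 1, k, dtype=int)]
            keep[drop] = False
        else:
            # extra samples midway between existing grid points
            src = sec[np.linspace(0, len(sec) - 2, k, dtype=int)]
            ins_t.append(t[src] + 0.5 / rate)
    new_t = t[keep]
    new_v = v[keep]
    if ins_t:
        extra_t = np.concatenate(ins_t)
        if v.ndim == 2:
            extra_v = np.column_stack([np.interp(extra_t, t, v[:, c])
                                       for c in range(v.shape[1])])
        else:
            extra_v = np.interp(extra_t, t, v)
        new_t = np.concatenate([new_t, extra_t])
        order = np.argsort(new_t, kind="stable")
        new_v = np.concatenate([new_v, extra_v], axis=0)[order]
        new_t = new_t[order]
    return SensorStream(name=stream.name, rate=rate, values=new_v,
                        channels=stream.channels, timestamps=new_t)
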