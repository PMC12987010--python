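"""Timeline reconstruction: fragment merging, edge trimming, expected-grid alignment.

A recording session is nominally continuous, but acquisition interruptions
leave chronologically overlapping fragments, and chunked transport jitters
the per-second sample counts.  Reconstruction proceeds in three steps:

1. :func:`merge_fragments` — join overlapping fragments, placing the seam at
   the midpoint of each overlap.
2. :func:`trim_edges` — drop the unstable first and last seconds of the
   session (30 s by default, leaving 1140 s of a 1200-s session).
3. :func:`align_to_grid` — map every sample to the nearest index of the
   expected sample grid (nominal rate x duration) and fill empty indices by
   shape-preserving piecewise cubic Hermite (PCHIP) interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator

from .types import SensorStream


class ReconstructionError(ValueError):
    """Raised when fragments cannot be merged into a continuous timeline."""


@dataclass(frozen=True)
class ExpectedGrid:
    """Uniform grid of expected sample times for one sensor."""

    rate: float
    duration_s: float
    n_expected: int
    reference_clock: str = "eeg-500hz"

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(self.n_expected) / self.rate


@dataclass
class ReconstructedStream:
    """Grid-aligned samples with per-index fill provenance.

    ``filled_mask[i]`` is True where no observed sample mapped to grid index
    ``i`` and the value was interpolated (or extrapolated at the boundary).
    ``provenance[i]`` is the fragment id of the assigned sample, or -1 for
    filled indices.
    """

    grid: ExpectedGrid
    values: np.ndarray
    filled_mask: np.ndarray
    provenance: np.ndarray

    @property
    def n_observed(self) -> int:
        return int((~self.filled_mask).sum())


def build_expected_grid(
    rate: float, duration_s: float, reference_clock: str = "eeg-500hz"
) -> ExpectedGrid:
    """Construct the expected sample grid: ``n = rate x duration`` indices.

    The product must be an integer count (e.g. 128 Hz x 1140 s = 145,920);
    a non-integer product indicates an inconsistent rate/duration pair.
    """
    if rate <= 0:
        raise ValueError(f"rate must be positive, got {rate}")
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    product = rate * duration_s
    n = round(product)
    if abs(product - n) > 1e-6:
        raise ValueError(
            f"rate x duration = {product} is not an integer sample count"
        )
    return ExpectedGrid(rate=float(rate), duration_s=float(duration_s),
                        n_expected=int(n), reference_clock=reference_clock)


def merge_fragments(fragments: list[SensorStream], min_trim_s: float = 5.0) -> SensorStream:
    """Merge chronologically overlapping fragments into one continuous stream.

    Consecutive fragments must overlap (or abut); a gap raises
    :class:`ReconstructionError` reporting the gap span.  At each overlap the
    seam is placed at the overlap midpoint: the earlier fragment keeps samples
    strictly before the seam, the later keeps samples at or after it.  Three
    or more fragments are handled pairwise left to right.
    """
    if not fragments:
        raise ReconstructionError("no fragments to merge")
    frs = sorted(fragments, key=lambda f: float(f.times[0]))
    merged = frs[0]
    m_t = merged.times
    m_v = merged.values
    prov = np.zeros(len(m_t), dtype=int)
    for frag_id, frag in enumerate(frs[1:], start=1):
        f_t = frag.times
        f_v = frag.values
        prev_end = m_t[-1] + 1.0 / merged.rate
        next_start = f_t[0]
        overlap = prev_end - next_start
        if overlap < -1e-9:
            raise ReconstructionError(
                f"gap of {-overlap:.3f} s between fragments "
                f"({prev_end:.3f} s to {next_start:.3f} s)"
            )
        if 0 < overlap < 2 * min_trim_s:
            # Short overlap: the midpoint seam discards less than min_trim_s
            # per side; still deterministic, but coverage of the seam region
            # rests on fewer redundant samples.
            pass
        seam = next_start + overlap / 2.0
        keep_left = m_t < seam
        keep_right = f_t >= seam
        m_t = np.concatenate([m_t[keep_left], f_t[keep_right]])
        m_v = np.concatenate([m_v[keep_left], f_v[keep_right]])
        prov = np.concatenate([prov[keep_left],
                               np.full(int(keep_right.sum()), frag_id, dtype=int)])
    out = SensorStream(name=merged.name, rate=merged.rate, values=m_v,
                       channels=merged.channels, timestamps=m_t)
    out.fragment_ids = prov  # type: ignore[attr-defined]
    return out


def trim_edges(stream: SensorStream, trim_s: float = 30.0) -> SensorStream:
    """Drop ``trim_s`` seconds from both ends and re-anchor time at zero."""
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    if trim_s == 0:
        return stream
    t = stream.times
    span = stream.duration_s
    if span < 2 * trim_s:
        raise ValueError(
            f"stream of {span:.1f} s too short to trim {trim_s} s per side"
        )
    lo = t[0] + trim_s
    hi = t[0] + span - trim_s
    keep = (t >= lo - 1e-9) & (t < hi - 1e-9)
    out = SensorStream(name=stream.name, rate=stream.rate,
                       values=stream.values[keep], channels=stream.channels,
                       timestamps=t[keep] - lo)
    if hasattr(stream, "fragment_ids"):
        out.fragment_ids = stream.fragment_ids[keep]  # type: ignore[attr-defined]
    return out


def align_to_grid(
    timestamps: np.ndarray,
    values: np.ndarray,
    grid: ExpectedGrid,
    fragment_ids: np.ndarray | None = None,
) -> ReconstructedStream:
    """Assign observed samples to nearest grid indices and PCHIP-fill gaps.

    When several samples map to one index the temporally closest wins, ties
    going to the earlier sample.  Interior empty indices are filled by
    shape-preserving piecewise cubic Hermite interpolation over the observed
    anchors; boundary gaps (before the first / after the last observation)
    take the nearest observed value.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    values = np.asarray(values, dtype=float)
    if timestamps.size == 0:
        raise ValueError("empty input")
    if timestamps.size > 1 and np.ptp(timestamps) == 0:
        raise ValueError("all timestamps identical")
    n = grid.n_expected
    idx = np.clip(np.round(timestamps * grid.rate).astype(np.int64), 0, n - 1)
    dist = np.abs(timestamps - idx / grid.rate)
    # Stable sort by (index, distance): first entry per index is the winner,
    # with ties broken toward the earlier (lower original position) sample.
    order = np.lexsort((np.arange(len(idx)), dist, idx))
    idx_sorted = idx[order]
    first = np.ones(len(idx_sorted), dtype=bool)
    first[1:] = idx_sorted[1:] != idx_sorted[:-1]
    winners = order[first]

    multichannel = values.ndim == 2
    shape = (n, values.shape[1]) if multichannel else (n,)
    out = np.full(shape, np.nan)
    out[idx[winners]] = values[winners]
    filled = np.ones(n, dtype=bool)
    filled[idx[winners]] = False

    prov = np.full(n, -1, dtype=int)
    if fragment_ids is not None:
        prov[idx[winners]] = np.asarray(fragment_ids)[winners]
    else:
        prov[idx[winners]] = 0

    obs_idx = np.flatnonzero(~filled)
    if filled.any() and len(obs_idx) >= 2:
        gap_idx = np.flatnonzero(filled)
        interior = (gap_idx > obs_idx[0]) & (gap_idx < obs_idx[-1])
        interp = PchipInterpolator(obs_idx.astype(float), out[obs_idx], axis=0)
        if interior.any():
            out[gap_idx[interior]] = interp(gap_idx[interior].astype(float))
        before = gap_idx[gap_idx < obs_idx[0]]
        after = gap_idx[gap_idx > obs_idx[-1]]
        out[before] = out[obs_idx[0]]
        out[after] = out[obs_idx[-1]]
    elif filled.any():
        out[filled] = out[obs_idx[0]]

    return ReconstructedStream(grid=grid, values=out, filled_mask=filled,
                               provenance=prov)


def reconstruct_stream(
    fragments: list[SensorStream] | SensorStream,
    trim_s: float = 30.0,
    min_trim_s: float = 5.0,
) -> ReconstructedStream:
    """Full per-sensor reconstruction: merge, trim, grid-align."""
    if isinstance(fragments, SensorStream):
        fragments = [fragments]
    merged = merge_fragments(fragments, min_trim_s=min_trim_s)
    trimmed = trim_edges(merged, trim_s=trim_s)
    # Jitter leaves the observed span fractionally short of the nominal
    # session length; the grid is built from the nominal (integer-second) one.
    duration = round(merged.duration_s) - 2 * trim_s
    grid = build_expected_grid(trimmed.rate, duration)
    frag_ids = getattr(trimmed, "fragment_ids", None)
    return align_to_grid(trimmed.times, trimmed.values, grid, fragment_ids=frag_ids)
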