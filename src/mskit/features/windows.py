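"""30-s windowing of reconstructed sessions and FMS mapping.

A 1140-s effective session yields floor(1140 / 30) = 38 aligned windows.
Each window carries its signal content as a list of segments so that
preprocessing-induced discontinuities can be handled per segment; with
continuous reconstructed data every window holds a single segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Window:
    start_s: float
    end_s: float
    #: per-signal list of contiguous segments inside the window
    segments: dict[str, list[np.ndarray]] = field(default_factory=dict)
    fms: float = float("nan")

    @property
    def length_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class WindowSet:
    window_length_s: float
    windows: list[Window]

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]


def windowize(effective_length_s: float, length_s: float = 30.0) -> WindowSet:
    """Partition an effective session into aligned, non-overlapping windows."""
    if length_s <= 0:
        raise ValueError("window length must be positive")
    if effective_length_s < length_s:
        raise ValueError(
            f"session of {effective_length_s} s shorter than one "
            f"{length_s}-s window"
        )
    count = int(np.floor(effective_length_s / length_s))
    windows = [Window(start_s=i * length_s, end_s=(i + 1) * length_s)
               for i in range(count)]
    return WindowSet(window_length_s=length_s, windows=windows)


def slice_stream(values: np.ndarray, rate: float, window: Window,
                 ) -> list[np.ndarray]:
    """Extract the window's samples from a grid-aligned stream as one segment."""
    i0 = int(round(window.start_s * rate))
    i1 = int(round(window.end_s * rate))
    return [np.asarray(values[i0:i1])]


def map_fms(reports: list[tuple[float, float]], window: Window,
            ) -> float:
    """Time-weighted mean of the piecewise-constant FMS trajectory in a window.

    Each report holds until the next one.  Times before the first report are
    back-filled with the first report's value (the protocol guarantees a
    report at or before every window end, but not necessarily at t = 0).
    """
    if not reports:
        raise ValueError("no FMS reports")
    reps = sorted(reports, key=lambda r: r[0])
    times = np.asarray([r[0] for r in reps], dtype=float)
    vals = np.asarray([r[1] for r in reps], dtype=float)
    if times[0] > window.end_s:
        raise ValueError(
            f"no FMS report at or before window end {window.end_s} s"
        )
    # breakpoints of the piecewise-constant trajectory inside the window
    edges = np.concatenate([[window.start_s],
                            times[(times > window.start_s) & (times < window.end_s)],
                            [window.end_s]])
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        k = np.searchsorted(times, a, side="right") - 1
        v = vals[max(k, 0)]  # back-fill before the first report
        total += v * (b - a)
    return total / window.length_s
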