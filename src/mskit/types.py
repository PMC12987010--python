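"""Shared in-memory containers for sensor streams and sessions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class SensorStream:
    """One channel-set of samples with a nominal rate and sensor identity.

    ``values`` has shape ``(n,)`` for single-channel sensors or ``(n, c)``
    for multichannel ones.  ``timestamps`` is optional: uniformly sampled
    streams imply ``t0 + arange(n) / rate``; fragmented or jittered streams
    carry explicit timestamps.
    """

    name: str
    rate: float
    values: np.ndarray
    channels: tuple[str, ...] = ()
    t0: float = 0.0
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != len(self.values):
                raise ValueError("timestamps and values length mismatch")

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 1 else self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        if self.timestamps is not None:
            return self.timestamps
        return self.t0 + np.arange(self.n_samples) / self.rate

    @property
    def duration_s(self) -> float:
        """Nominal covered span in seconds (sample period granularity)."""
        if self.timestamps is not None:
            if len(self.timestamps) == 0:
                return 0.0
            return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.rate
        return self.n_samples / self.rate

    def copy(self) -> "SensorStream":
        return SensorStream(
            name=self.name,
            rate=self.rate,
            values=self.values.copy(),
            channels=self.channels,
            t0=self.t0,
            timestamps=None if self.timestamps is None else self.timestamps.copy(),
        )


@dataclass
class SessionRecord:
    """All streams plus questionnaire records for one participant x MS-type session.

    ``streams`` maps sensor name to either a single :class:`SensorStream` or,
    for fragmented recordings, a list of fragments in arbitrary order.
    ``fms_reports`` is a list of ``(time_s, value)`` symptom reports on the
    1-5 scale used during exposure.
    """

    participant: str
    ms_type: str
    streams: dict[str, Any] = field(default_factory=dict)
    fms_reports: list[tuple[float, float]] = field(default_factory=list)
    questionnaires: dict[str, Any] = field(default_factory=dict)
    demographics: dict[str, Any] = field(default_factory=dict)
    session_length_s: float = 1200.0
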