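"""Synthetic-cohort configuration and ground truth containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SensorSpec:
    name: str
    rate: float
    channels: tuple[str, ...]


#: Default sensor set: acquisition rates of the emulated hardware.
DEFAULT_SENSOR_SPECS: tuple[SensorSpec, ...] = (
    SensorSpec("ppg", 128.0, ("ppg",)),
    SensorSpec("eda", 128.0, ("resistance_kohm",)),
    SensorSpec("eeg", 500.0, ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")),
    SensorSpec("skt", 1.0, ("temp_c",)),
    SensorSpec("head_pose", 30.0, ("pos_sway", "pos_heave", "pos_surge",
                                   "rot_pitch", "rot_yaw", "rot_roll")),
    SensorSpec("head_imu", 4.0, ("acc_sway", "acc_heave", "acc_surge",
                                 "gyro_pitch", "gyro_yaw", "gyro_roll")),
    SensorSpec("eye", 30.0, ("pos_l_x", "pos_l_y", "pos_l_z",
                             "pos_r_x", "pos_r_y", "pos_r_z",
                             "pos_c_x", "pos_c_y", "pos_c_z",
                             "dir_l_x", "dir_l_y", "dir_l_z",
                             "dir_r_x", "dir_r_y", "dir_r_z",
                             "dir_c_x", "dir_c_y", "dir_c_z")),
)

#: Planted signal-MSL associations: signed loading per feature family.
#: Signs follow the reported univariate effect directions (electrodermal
#: amplitude down, head pitch/surge energy up, eye-direction spectral
#: entropy up, EEG sample entropy down as MSL rises).
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "eda_amplitude": -0.3,
    "head_pitch_surge_energy": 0.3,
    "eye_direction_psd_entropy": 0.3,
    "eeg_sample_entropy": -0.3,
}

MS_TYPES = ("CMS", "VIMS", "Co-MS")


@dataclass
class SyntheticConfig:
    n_participants: int = 16
    ms_types: tuple[str, ...] = MS_TYPES
    session_length_s: float = 1200.0
    sensor_specs: tuple[SensorSpec, ...] = DEFAULT_SENSOR_SPECS
    effect_sizes: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    fragmentation_rate: float = 0.3   # expected interruption events / session
    fragment_overlap_s: float = 10.0  # restart rewinds this far
    jitter_chunks: int = 1            # max per-second chunk deviation
    chunk_rate_hz: float = 16.0       # transport chunk rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if self.session_length_s <= 60:
            raise ValueError("session_length_s must exceed 60 s")
        for spec in self.sensor_specs:
            if spec.rate <= 0:
                raise ValueError(f"invalid rate for sensor {spec.name!r}")
        if self.jitter_chunks < 0:
            raise ValueError("jitter_chunks must be >= 0")
        if self.fragmentation_rate < 0:
            raise ValueError("fragmentation_rate must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: latent trajectories, loadings, design assignment."""

    latent_msl: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    planted_loadings: dict[str, float] = field(default_factory=dict)
    assignment: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    susceptibility: dict[str, float] = field(default_factory=dict)
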