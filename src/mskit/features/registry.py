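"""The feature registry: every (domain, signal, band, feature) combination.

Applying the uniform eight-feature SwF template to every source signal and
adding the window-derived features yields:

==========  =======================================  =====
domain      signals / WdFs                           count
==========  =======================================  =====
PPG         3 band signals x 8 + 12 WdFs                36
EDA         4 band signals x 8                          32
EEG         30 region-band signals x 8 + 7 ratios
            + 336 FBN metrics                          583
SKT         1 signal x 8                                 8
Eye         6 signals x 8 + 7 WdFs                      55
HeadPose    8 signals x 8                               64
HeadIMU     6 signals x 8                               48
Demographic gender, susceptibility group                 2
==========  =======================================  =====
Total                                                  828
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .eeg import EEG_BANDS, EEG_CHANNELS, EEG_RATIO_NAMES, EEG_REGIONS
from .eye import EYE_WDF_NAMES
from .ppg import PPG_WDF_NAMES
from .swf import FREQ_FEATURES, TIME_FEATURES

DOMAINS = ("PPG", "EDA", "EEG", "SKT", "Eye", "HeadPose", "HeadIMU",
           "Demographic")

EYE_SIGNALS = ("closure_and", "closure_or", "convergence_distance",
               "gaze_yaw", "gaze_pitch", "gaze_velocity")
HEADPOSE_SIGNALS = ("pos_sway", "pos_heave", "pos_surge", "rot_pitch",
                    "rot_yaw", "rot_roll", "dir_yaw", "dir_pitch")
HEADIMU_SIGNALS = ("acc_sway", "acc_heave", "acc_surge", "gyro_pitch",
                   "gyro_yaw", "gyro_roll")
DEMOGRAPHIC_FEATURES = ("gender", "susceptibility_group")


@dataclass(frozen=True)
class FeatureDescriptor:
    """Identity of one extracted feature."""

    domain: str
    signal: str
    band: str
    name: str
    kind: str  # SwF-time | SwF-freq | WdF | static

    @property
    def feature_id(self) -> str:
        return f"{self.domain}:{self.signal}:{self.band}:{self.name}"


def _swf_template(domain: str, signal: str, band: str) -> list[FeatureDescriptor]:
    descs = [FeatureDescriptor(domain, signal, band, name, "SwF-time")
             for name in TIME_FEATURES]
    descs += [FeatureDescriptor(domain, signal, band, name, "SwF-freq")
              for name in FREQ_FEATURES]
    return descs


def build_registry() -> list[FeatureDescriptor]:
    """Enumerate all 828 feature descriptors in stable order."""
    reg: list[FeatureDescriptor] = []

    for band in ("whole", "LF", "HF"):
        reg += _swf_template("PPG", "ppg", band)
    reg += [FeatureDescriptor("PPG", "ppg", "whole", name, "WdF")
            for name in PPG_WDF_NAMES]

    for band in ("whole", "SCL", "SCR", "LF"):
        reg += _swf_template("EDA", "eda", band)

    for region in EEG_REGIONS:
        for band in EEG_BANDS:
            reg += _swf_template("EEG", region, band)
    reg += [FeatureDescriptor("EEG", "ratios", "whole", name, "WdF")
            for name in EEG_RATIO_NAMES]
    for band in EEG_BANDS:
        for ch_a, ch_b in combinations(EEG_CHANNELS, 2):
            for metric in ("coherence", "plv"):
                reg.append(FeatureDescriptor("EEG", f"{ch_a}-{ch_b}", band,
                                             metric, "WdF"))

    reg += _swf_template("SKT", "skt", "whole")

    for sig in EYE_SIGNALS:
        reg += _swf_template("Eye", sig, "whole")
    reg += [FeatureDescriptor("Eye", "eye", "whole", name, "WdF")
            for name in EYE_WDF_NAMES]

    for sig in HEADPOSE_SIGNALS:
        reg += _swf_template("HeadPose", sig, "whole")
    for sig in HEADIMU_SIGNALS:
        reg += _swf_template("HeadIMU", sig, "whole")

    reg += [FeatureDescriptor("Demographic", "participant", "whole", name,
                              "static")
            for name in DEMOGRAPHIC_FEATURES]

    ids = [d.feature_id for d in reg]
    assert len(ids) == len(set(ids)), "duplicate feature descriptors"
    return reg


def registry_counts(registry: list[FeatureDescriptor] | None = None,
                    ) -> dict[str, int]:
    """Descriptor counts per domain plus the total."""
    reg = registry if registry is not None else build_registry()
    counts: dict[str, int] = {}
    for d in reg:
        counts[d.domain] = counts.get(d.domain, 0) + 1
    counts["total"] = len(reg)
    return counts
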