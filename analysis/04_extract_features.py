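#!/usr/bin/env python
"""Extract 30-s windowed features into a long-form feature table.

Reads preprocessed session directories, slices each stream into the aligned
30-s windows, applies the SwF templates and window-derived features, maps
the per-window time-weighted FMS, and writes one long-form CSV plus the
feature registry as JSON.  By default only the feature families whose
source streams are present are extracted.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from mskit.features import build_registry, extract_session
from mskit.synthgen import read_session

RATES = {"ppg": 128.0, "eda": 128.0, "eeg": 500.0, "skt": 1.0,
         "head_pose": 30.0, "head_imu": 4.0, "eye": 30.0}
DOMAIN_SENSOR = {"PPG": "ppg", "EDA": "eda", "EEG": "eeg", "SKT": "skt",
                 "Eye": "eye", "HeadPose": "head_pose", "HeadIMU": "head_imu"}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", required=True,
                    help="preprocessed session directories")
    ap.add_argument("--raw", required=True,
                    help="raw cohort directory (for FMS reports)")
    ap.add_argument("--out", required=True)
    ap.add_argument("--registry", default=None)
    args = ap.parse_args()

    registry = build_registry()
    if args.registry:
        Path(args.registry).write_text(json.dumps(
            [asdict(d) for d in registry], indent=1))

    frames = []
    for sdir in sorted(Path(args.indir).iterdir()):
        if not sdir.is_dir():
            continue
        raw = read_session(Path(args.raw) / sdir.name)
        streams = {}
        for csv in sdir.glob("*.csv"):
            if csv.stem not in RATES:
                continue
            df = pd.read_csv(csv)
            x = df.drop(columns="timestamp_s").to_numpy()
            streams[csv.stem] = x[:, 0] if x.shape[1] == 1 else x
        descs = [d for d in registry
                 if DOMAIN_SENSOR.get(d.domain) in streams]
        table = extract_session(streams, RATES, fms_reports=raw.fms_reports,
                                descriptors=descs)
        table["participant"] = raw.participant
        table["session"] = raw.ms_type
        frames.append(table)
        print(f"{sdir.name}: {table['feature_id'].nunique()} features x "
              f"{table['window'].nunique()} windows "
              f"({table['missing'].mean():.1%} missing)")
    out = pd.concat(frames, ignore_index=True)
    out.to_csv(args.out, index=False)
    print(f"wrote {len(out)} rows to {args.out}")


if __name__ == "__main__":
    main()
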