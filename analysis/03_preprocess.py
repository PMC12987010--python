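#!/usr/bin/env python
"""Apply the per-sensor preprocessing chains to reconstructed streams.

PPG: notch {30, 60} Hz then 0.1-10 Hz band-pass.  EDA: resistance to
conductance, notch 60 Hz, 0.03-5 Hz band-pass.  EEG: harmonic notches,
1-50 Hz band-pass, common average reference, artifact hook.  SKT:
three-point moving average.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mskit.prefilter import apply_chain

RATES = {"ppg": 128.0, "eda": 128.0, "eeg": 500.0, "skt": 1.0}


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", required=True)
    ap.add_argument("--out", required=True)
    ap.add_argument("--sensors", default="ppg,eda,eeg,skt")
    args = ap.parse_args()

    sensors = [s.strip() for s in args.sensors.split(",")]
    outroot = Path(args.out)
    for sdir in sorted(Path(args.indir).iterdir()):
        if not sdir.is_dir():
            continue
        odir = outroot / sdir.name
        for sensor in sensors:
            src = sdir / f"{sensor}.csv"
            if not src.exists():
                continue
            df = pd.read_csv(src)
            t = df["timestamp_s"]
            x = df.drop(columns="timestamp_s").to_numpy()
            if x.shape[1] == 1:
                x = x[:, 0]
            y = apply_chain(sensor, x, RATES[sensor])
            odir.mkdir(parents=True, exist_ok=True)
            out = pd.DataFrame(y if y.ndim == 2 else y[:, None],
                               columns=list(df.columns[1:]))
            out.insert(0, "timestamp_s", t)
            out.to_csv(odir / f"{sensor}.csv", index=False,
                       float_format="%.6f")
            print(f"{sdir.name}/{sensor}: filtered {len(out)} samples")
        # passthrough for sensors without a filter chain
        for src in sdir.glob("*.csv"):
            if src.stem not in RATES and src.stem != "reconstruction":
                odir.mkdir(parents=True, exist_ok=True)
                (odir / src.name).write_bytes(src.read_bytes())


if __name__ == "__main__":
    main()
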