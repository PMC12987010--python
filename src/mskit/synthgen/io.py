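"""On-disk session layout: one directory per participant x session.

Streams are CSVs with a ``timestamp_s`` column followed by one column per
channel (each recording fragment in its own numbered file); questionnaires,
FMS reports and ground truth are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..types import SensorStream, SessionRecord
from .config import GroundTruth


def _session_dirname(record: SessionRecord) -> str:
    return f"{record.participant}_{record.ms_type.replace('-', '')}"


def write_session(root: Path | str, record: SessionRecord) -> Path:
    root = Path(root)
    sdir = root / _session_dirname(record)
    sdir.mkdir(parents=True, exist_ok=True)
    for name, fragments in record.streams.items():
        if isinstance(fragments, SensorStream):
            fragments = [fragments]
        for i, frag in enumerate(fragments):
            vals = frag.values if frag.values.ndim == 2 else frag.values[:, None]
            df = pd.DataFrame(vals, columns=list(frag.channels) or [name])
            df.insert(0, "timestamp_s", frag.times)
            df.to_csv(sdir / f"{name}_frag{i:02d}.csv", index=False,
                      float_format="%.6f")
    meta = {
        "participant": record.participant,
        "ms_type": record.ms_type,
        "session_length_s": record.session_length_s,
        "fms_reports": record.fms_reports,
        "questionnaires": record.questionnaires,
        "demographics": record.demographics,
        "stream_rates": {n: (f[0].rate if isinstance(f, list) else f.rate)
                         for n, f in record.streams.items()},
    }
    (sdir / "session.json").write_text(json.dumps(meta, indent=1))
    return sdir


def read_session(sdir: Path | str) -> SessionRecord:
    sdir = Path(sdir)
    meta = json.loads((sdir / "session.json").read_text())
    rec = SessionRecord(participant=meta["participant"],
                        ms_type=meta["ms_type"],
                        session_length_s=meta["session_length_s"],
                        fms_reports=[tuple(r) for r in meta["fms_reports"]],
                        questionnaires=meta["questionnaires"],
                        demographics=meta["demographics"])
    rates = meta["stream_rates"]
    for csv in sorted(sdir.glob("*_frag*.csv")):
        name = csv.name.rsplit("_frag", 1)[0]
        df = pd.read_csv(csv)
        t = df["timestamp_s"].to_numpy()
        vals = df.drop(columns="timestamp_s").to_numpy()
        if vals.shape[1] == 1:
            vals = vals[:, 0]
        frag = SensorStream(name=name, rate=rates[name], values=vals,
                            channels=tuple(df.columns[1:]), timestamps=t)
        rec.streams.setdefault(name, []).append(frag)
    return rec


def write_cohort(root: Path | str, sessions: list[SessionRecord],
                 truth: GroundTruth | None = None) -> None:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for rec in sessions:
        write_session(root, rec)
    if truth is not None:
        payload = {
            "planted_loadings": truth.planted_loadings,
            "assignment": {k: list(v) for k, v in truth.assignment.items()},
            "susceptibility": truth.susceptibility,
            "latent_msl": {f"{p}|{s}": np.asarray(v).tolist()
                           for (p, s), v in truth.latent_msl.items()},
        }
        (root / "ground_truth.json").write_text(json.dumps(payload))
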