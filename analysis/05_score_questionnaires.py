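#!/usr/bin/env python
"""Score the questionnaire records of a cohort.

Computes pre/post SSQ and delta-SSQ subscale scores, the susceptibility
score/percentile with tertile and merged grouping, and Film IEQ subscale
sums; writes one row per participant x session.
"""

import argparse
from pathlib import Path

import pandas as pd

from mskit.scales import delta_ssq, score_ieq, score_mssq, score_ssq
from mskit.synthgen import read_session


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--in", dest="indir", required=True)
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    rows = []
    for sdir in sorted(Path(args.indir).iterdir()):
        if not (sdir / "session.json").exists():
            continue
        rec = read_session(sdir)
        q = rec.questionnaires
        d = delta_ssq(q["ssq_post"], q["ssq_pre"])
        mssq = score_mssq([tuple(i) for i in q["mssq_child"]],
                          [tuple(i) for i in q["mssq_adult"]])
        ieq = score_ieq(q["ieq"])
        rows.append({
            "participant": rec.participant, "session": rec.ms_type,
            "gender": rec.demographics.get("gender"),
            "dssq_T": d.T, "dssq_N": d.N, "dssq_O": d.O, "dssq_D": d.D,
            "mssq_score": mssq.score, "mssq_percentile": mssq.percentile,
            "susceptibility_group": mssq.group,
            "susceptibility_merged": mssq.merged_group,
            **{f"ieq_{k}": v for k, v in ieq.items()},
        })
    df = pd.DataFrame(rows)
    df.to_csv(args.out, index=False)
    print(f"scored {df['participant'].nunique()} participants; "
          f"group sizes: {df.groupby('susceptibility_group')['participant'].nunique().to_dict()}")


if __name__ == "__main__":
    main()
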