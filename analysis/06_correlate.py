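#!/usr/bin/env python
"""Repeated-measures correlation between features and motion-sickness level.

For every extracted feature, computes the within-participant (repeated
measures) correlation against the per-window FMS, tags each result with the
SESOI tier it reaches jointly with p < 0.05, and writes the result table.
This scan is exploratory and deliberately unadjusted; named BH families are
available for the confirmatory analyses.
"""

import argparse

import pandas as pd

from mskit.stats import rmcorr, sesoi_screen


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--features", required=True)
    ap.add_argument("--out", required=True)
    ap.add_argument("--tier", default="conservative",
                    choices=["medium", "conservative", "large"])
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    results = {}
    for fid, sub in table.groupby("feature_id"):
        vals = sub["value"].where(~sub["missing"].astype(bool))
        results[fid] = rmcorr(vals, sub["fms"],
                              sub["participant"] + "|" + sub["session"])
    screened = sesoi_screen(results)
    screened = screened.rename(columns={"key": "descriptor_id"})
    screened["msl_measure"] = "FMS"
    screened.to_csv(args.out, index=False)
    n_tier = (screened["tier"] == args.tier).sum()
    top = screened.loc[screened["valid"]].reindex(
        screened["r"].abs().sort_values(ascending=False).index).head(5)
    print(f"{len(screened)} features screened; "
          f"{n_tier} at the {args.tier} tier")
    print(top[["descriptor_id", "r", "p", "tier"]].to_string(index=False))


if __name__ == "__main__":
    main()
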