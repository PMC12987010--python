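"""Repeated-measures correlation, multiplicity control, and SESOI tiers.

The repeated-measures correlation (rmcorr) estimates the common
within-participant association between two variables measured repeatedly on
the same people.  It is the analysis-of-covariance formulation with a common
slope: both variables are centered within participant, the correlation of
the centered values gives |r| and the common slope gives the sign, the error
degrees of freedom are ``N - k - 1`` for N observations and k participants,
and the p-value comes from ``t = r sqrt(df / (1 - r^2))`` on a central t
distribution.

Effect-size gates follow the smallest-effect-size-of-interest (SESOI)
convention: a result is tagged with the highest tier whose |r| threshold it
strictly exceeds while also reaching p < 0.05 (medium 0.20, conservative
0.25, large 0.30).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class RmcorrResult:
    r: float
    df: int
    p: float
    n_obs: int
    n_participants: int
    valid: bool = True
    reason: str = ""


@dataclass(frozen=True)
class SESOITier:
    alpha: float = 0.05
    thresholds: tuple[tuple[str, float], ...] = (
        ("medium", 0.20), ("conservative", 0.25), ("large", 0.30))


#: Named Benjamini-Hochberg families.  The exploratory feature-MSL scan is
#: deliberately NOT adjusted (nominal alpha with a SESOI gate instead).
BH_FAMILIES = {
    "anova_per_dv": "per-dependent-variable ANOVA effect family",
    "ieq_ssq_16": "16 IEQ-subscale x SSQ-subscale correlation tests",
    "msl_intercorrelation_6": "6 pairwise MSL-measure correlation tests",
}


def _invalid(reason: str, n_obs: int = 0, n_participants: int = 0) -> RmcorrResult:
    return RmcorrResult(r=float("nan"), df=0, p=float("nan"), n_obs=n_obs,
                        n_participants=n_participants, valid=False,
                        reason=reason)


def rmcorr(x, y, participant_ids) -> RmcorrResult:
    """Repeated-measures correlation between paired observations.

    Missing values are deleted pairwise; participants with fewer than two
    complete observations are excluded.  Returns an invalid-flagged result
    when the error degrees of freedom drop below 1 or a variable has no
    within-participant variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.asarray(participant_ids)
    if not (len(x) == len(y) == len(ids)):
        raise ValueError("x, y and participant_ids must have equal length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y, ids = x[ok], y[ok], ids[ok]
    if len(x) == 0:
        return _invalid("no complete observations")
    # keep participants with >= 2 observations
    uniq, counts = np.unique(ids, return_counts=True)
    keep_ids = set(uniq[counts >= 2])
    keep = np.array([i in keep_ids for i in ids])
    x, y, ids = x[keep], y[keep], ids[keep]
    k = len(keep_ids)
    n = len(x)
    df = n - k - 1
    if k == 0 or df < 1:
        return _invalid("insufficient degrees of freedom", n, k)

    xc = x.copy()
    yc = y.copy()
    for pid in keep_ids:
        m = ids == pid
        xc[m] -= xc[m].mean()
        yc[m] -= yc[m].mean()
    ssx = float((xc ** 2).sum())
    ssy = float((yc ** 2).sum())
    if ssx == 0 or ssy == 0:
        return _invalid("zero within-participant variance", n, k)
    r = float((xc * yc).sum() / np.sqrt(ssx * ssy))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r ** 2))
        p = float(2.0 * spstats.t.sf(abs(t), df))
    return RmcorrResult(r=r, df=df, p=p, n_obs=n, n_participants=k)


def bh_adjust(p_values, family_id: str | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one family."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError(f"empty p-value family {family_id!r}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bh_adjust_families(p_by_family: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Apply BH independently within each named family."""
    return {fam: bh_adjust(p, fam) for fam, p in p_by_family.items()}


def sesoi_screen(results: dict[str, RmcorrResult],
                 tier_spec: SESOITier | None = None) -> pd.DataFrame:
    """Tag each result with the highest SESOI tier it satisfies jointly with
    p < alpha.  Comparisons are strict (|r| > threshold)."""
    spec = tier_spec or SESOITier()
    rows = []
    for key, res in results.items():
        tier = ""
        if res.valid and res.p < spec.alpha:
            for name, thr in spec.thresholds:
                if abs(res.r) > thr:
                    tier = name
        rows.append({"key": key, "r": res.r, "df": res.df, "p": res.p,
                     "tier": tier, "valid": res.valid})
    return pd.DataFrame(rows)


def session_mean_features(features: pd.DataFrame,
                          value_col: str = "value") -> pd.DataFrame:
    """Session-level feature means over non-missing windows.

    Expects a long-form table with (participant, session, feature_id)
    columns; missing-flagged windows are excluded from the mean.
    """
    df = features.copy()
    if "missing" in df.columns:
        df = df[~df["missing"].astype(bool)]
    out = (df.groupby(["participant", "session", "feature_id"])[value_col]
             .mean().reset_index())
    return out


def mixed_anova(data: pd.DataFrame, dv: str, within: str, subject: str,
                between: str | None = None) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA, delegated to an established routine.

    Thin wrapper over :func:`pingouin.mixed_anova` (sphericity handling and
    corrections per that package).  This package does not re-implement the
    ANOVA machinery; its numeric tables on real cohorts are outside the
    pipeline's reproduction scope.
    """
    import pingouin as pg  # deferred: heavy import

    if between is None:
        return pg.rm_anova(data=data, dv=dv, within=within, subject=subject)
    return pg.mixed_anova(data=data, dv=dv, within=within, subject=subject,
                          between=between)
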