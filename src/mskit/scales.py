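"""Questionnaire scoring: SSQ, MSSQ-Short percentile, Film IEQ, susceptibility.

The SSQ has 16 symptom items on a 0-3 scale; subscale raw sums for nausea
(N), oculomotor (O) and disorientation (D) are weighted by 9.54, 7.58 and
13.92 respectively, and the total is 3.74 x the sum of the unweighted raw
subscale scores.  Exposure effects use the post-minus-pre difference
(delta-SSQ).

Motion-sickness susceptibility is scored per era (childhood, adulthood) over
nine transport/ride types:

    score_era = 9 x sum(item scores) / (9 - N_miss)

with ``N_miss`` the number of types never experienced.  The percentile is a
quartic polynomial in the combined score; because the published constants
pair a negative second coefficient with a subtracted second term, the
polynomial is evaluated exactly as printed by default, and a documented
``convention`` switch selects the conventional all-positive-coefficient
reading.  Percentiles are clamped to [0, 100].
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np

# MSSQ-Short percentile quartic, evaluated as A x - B x^2 - C x^3 + D x^4.
MSSQ_A = 5.1160923
MSSQ_B = -0.055169904
MSSQ_C = 0.00067784495
MSSQ_D = 0.000010714752

_N_TYPES = 9  # transport/ride types per era


def _load_data(name: str) -> dict:
    with resources.files("mskit.data").joinpath(name).open() as fh:
        return json.load(fh)


_SSQ = _load_data("ssq_items.json")
_IEQ = _load_data("ieq_items.json")


@dataclass(frozen=True)
class SSQResult:
    raw_N: float
    raw_O: float
    raw_D: float
    N: float
    O: float
    D: float
    T: float

    def __sub__(self, other: "SSQResult") -> "SSQResult":
        return SSQResult(*(a - b for a, b in zip(
            (self.raw_N, self.raw_O, self.raw_D, self.N, self.O, self.D, self.T),
            (other.raw_N, other.raw_O, other.raw_D, other.N, other.O, other.D,
             other.T))))


@dataclass(frozen=True)
class MSSQResult:
    score: float
    percentile: float
    group: str          # low | moderate | high
    merged_group: str   # normal | high


def score_ssq(items) -> SSQResult:
    """Score 16 SSQ items (each in {0, 1, 2, 3})."""
    items = np.asarray(items, dtype=float)
    if items.shape != (16,):
        raise ValueError("SSQ requires exactly 16 items")
    if not np.isin(items, (0, 1, 2, 3)).all():
        raise ValueError("SSQ items must be on the 0-3 scale")
    subs = _SSQ["subscales"]
    w = _SSQ["weights"]
    raw = {k: float(items[np.asarray(subs[k]) - 1].sum()) for k in ("N", "O", "D")}
    return SSQResult(
        raw_N=raw["N"], raw_O=raw["O"], raw_D=raw["D"],
        N=w["N"] * raw["N"], O=w["O"] * raw["O"], D=w["D"] * raw["D"],
        T=w["T"] * (raw["N"] + raw["O"] + raw["D"]),
    )


def delta_ssq(post, pre) -> SSQResult:
    """Component-wise post-minus-pre SSQ difference."""
    return score_ssq(post) - score_ssq(pre)


def _era_score(items) -> float:
    """One era's contribution: 9 x sum(scores) / (9 - N_miss).

    ``items`` is a sequence of nine ``(frequency, experienced)`` pairs;
    frequencies on the 0-4 administered scale are remapped 4 -> 3 (the
    percentile norms use a 0-3 scale), and any vomiting sub-scores are the
    caller's to exclude — only sickness/nausea frequencies enter here.
    """
    if len(items) != _N_TYPES:
        raise ValueError(f"expected {_N_TYPES} transport/ride types")
    total = 0.0
    n_miss = 0
    for freq, experienced in items:
        if not 0 <= freq <= 4:
            raise ValueError("item frequency must be in 0-4")
        if not experienced:
            n_miss += 1
            continue
        total += min(float(freq), 3.0)
    if n_miss >= _N_TYPES:
        return 0.0
    return _N_TYPES * total / (_N_TYPES - n_miss)


def mssq_percentile(score: float, convention: str = "printed") -> float:
    """Map an MSSQ score to a population percentile via the quartic norm.

    ``convention="printed"`` evaluates ``A x - B x^2 - C x^3 + D x^4`` with
    the published constants as printed (B negative, so the quadratic term
    adds); ``convention="all-positive"`` uses the magnitudes of all four
    constants in the same expression.  The result is clamped to [0, 100].
    """
    x = float(score)
    if convention == "printed":
        a, b, c, d = MSSQ_A, MSSQ_B, MSSQ_C, MSSQ_D
    elif convention == "all-positive":
        a, b, c, d = MSSQ_A, abs(MSSQ_B), abs(MSSQ_C), abs(MSSQ_D)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    pct = a * x - b * x ** 2 - c * x ** 3 + d * x ** 4
    return float(np.clip(pct, 0.0, 100.0))


def score_mssq(child_items, adult_items,
               convention: str = "printed") -> MSSQResult:
    """Score the susceptibility questionnaire and derive the percentile group."""
    score = _era_score(child_items) + _era_score(adult_items)
    pct = mssq_percentile(score, convention=convention)
    group, merged = susceptibility_group(pct)
    return MSSQResult(score=score, percentile=pct, group=group,
                      merged_group=merged)


def susceptibility_group(percentile: float) -> tuple[str, str]:
    """Tertile grouping (boundaries go to the lower group) and the merged
    normal/high dichotomy."""
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    if percentile <= 33:
        group = "low"
    elif percentile <= 66:
        group = "moderate"
    else:
        group = "high"
    return group, ("high" if group == "high" else "normal")


def score_ieq(items, scale: tuple[int, int] = (1, 5)) -> dict[str, float]:
    """Film IEQ subscale scores by simple summation of the 24 items."""
    items = np.asarray(items, dtype=float)
    if items.shape != (24,):
        raise ValueError("Film IEQ requires exactly 24 items")
    lo, hi = scale
    if np.any((items < lo) | (items > hi)):
        raise ValueError(f"IEQ items must be on the {lo}-{hi} scale")
    return {k: float(items[np.asarray(idx) - 1].sum())
            for k, idx in _IEQ["subscales"].items()}
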