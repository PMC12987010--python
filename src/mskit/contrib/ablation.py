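"""Domain ablation, single-domain and combination evaluation, participant CV.

All comparisons share the same rows and hyperparameters as the full model;
only the column set changes.  The degradation rate for a metric m is

    delta_m(%) = (m_full - m_ablated) / m_full x 100

so positive values mean the reduced model explains less, negative values
mean it improved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ebm import BoostedGAM, EBMParams, FitMetrics, fit_ebm

#: Lightweight sensor combinations evaluated for vehicular practicality.
DEFAULT_COMBOS: tuple[tuple[str, ...], ...] = (
    ("Head", "PPG"),
    ("Head", "PPG", "EDA"),
    ("Head", "PPG", "Eye"),
    ("Head", "PPG", "EDA", "Eye"),
)

#: Ablation granularity groups the two head sensors into one "Head" domain.
ABLATION_DOMAINS = ("PPG", "EDA", "EEG", "SKT", "Head", "Eye", "Demographic")


def domain_of_feature(feature_id: str) -> str:
    """Map a registry feature id to its ablation domain."""
    dom = feature_id.split(":", 1)[0]
    return "Head" if dom in ("HeadPose", "HeadIMU") else dom


@dataclass(frozen=True)
class DegradationRate:
    metric: str
    delta_pct: float


@dataclass
class ContributionReport:
    full_model: FitMetrics
    importances: pd.Series
    ablations: dict[str, list[DegradationRate]] = field(default_factory=dict)
    single_domain: dict[str, list[DegradationRate]] = field(default_factory=dict)
    combos: dict[tuple[str, ...], list[DegradationRate]] = field(default_factory=dict)


def degradation(m_full: float, m_abl: float, metric: str = "r2") -> DegradationRate:
    """Relative degradation of one fit metric, in percent."""
    if m_full == 0:
        raise ValueError("full-model metric is zero; degradation undefined")
    return DegradationRate(metric=metric,
                           delta_pct=(m_full - m_abl) / m_full * 100.0)


def _triplet(full: FitMetrics, abl: FitMetrics) -> list[DegradationRate]:
    return [degradation(getattr(full, m), getattr(abl, m), m)
            for m in ("r2", "plcc", "srcc")]


def _check_rows(X: pd.DataFrame, expected_hash: int) -> None:
    if hash(tuple(X.index)) != expected_hash:
        raise ValueError("refit used a different row set than the full model")


def _domain_columns(X: pd.DataFrame) -> dict[str, list[str]]:
    cols: dict[str, list[str]] = {}
    for c in X.columns:
        cols.setdefault(domain_of_feature(c), []).append(c)
    return cols


def ablate_domains(X: pd.DataFrame, y: np.ndarray,
                   params: EBMParams | None = None,
                   full_metrics: FitMetrics | None = None,
                   domains: list[str] | None = None,
                   ) -> dict[str, list[DegradationRate]]:
    """Refit once per domain with that domain's columns dropped."""
    if full_metrics is None:
        _, full_metrics = fit_ebm(X, y, params)
    cols = _domain_columns(X)
    out: dict[str, list[DegradationRate]] = {}
    row_hash = hash(tuple(X.index))
    for dom in (domains or sorted(cols)):
        keep = [c for c in X.columns if domain_of_feature(c) != dom]
        Xd = X[keep]
        _check_rows(Xd, row_hash)
        _, m = fit_ebm(Xd, y, params)
        out[dom] = _triplet(full_metrics, m)
    return out


def single_domain_eval(X: pd.DataFrame, y: np.ndarray, domain: str,
                       params: EBMParams | None = None,
                       full_metrics: FitMetrics | None = None,
                       ) -> list[DegradationRate]:
    """Refit keeping only one domain's columns."""
    if full_metrics is None:
        _, full_metrics = fit_ebm(X, y, params)
    keep = [c for c in X.columns if domain_of_feature(c) == domain]
    if not keep:
        raise ValueError(f"no columns for domain {domain!r}")
    _check_rows(X[keep], hash(tuple(X.index)))
    _, m = fit_ebm(X[keep], y, params)
    return _triplet(full_metrics, m)


def combo_eval(X: pd.DataFrame, y: np.ndarray,
               combos: tuple[tuple[str, ...], ...] = DEFAULT_COMBOS,
               params: EBMParams | None = None,
               full_metrics: FitMetrics | None = None,
               ) -> dict[tuple[str, ...], list[DegradationRate]]:
    """Refit once per domain combination (columns restricted to the combo)."""
    if full_metrics is None:
        _, full_metrics = fit_ebm(X, y, params)
    out: dict[tuple[str, ...], list[DegradationRate]] = {}
    for combo in combos:
        keep = [c for c in X.columns if domain_of_feature(c) in combo]
        if not keep:
            raise ValueError(f"no columns for combo {combo!r}")
        _, m = fit_ebm(X[keep], y, params)
        out[tuple(combo)] = _triplet(full_metrics, m)
    return out


def participant_cv(X: pd.DataFrame, y: np.ndarray, participants,
                   k: int = 10, seed: int = 42,
                   params: EBMParams | None = None) -> pd.DataFrame:
    """Participant-wise k-fold importances: mean and SD per feature.

    Folds partition participants (never rows), so no participant spans
    folds; each fit uses the rows of k-1 folds.
    """
    participants = np.asarray(participants)
    uniq = np.unique(participants)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds {len(uniq)} participants")
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(uniq)
    folds = np.array_split(shuffled, k)
    imps = []
    for fold in folds:
        train = ~np.isin(participants, fold)
        model = BoostedGAM(params).fit(X[train], np.asarray(y)[train])
        imps.append(pd.Series(model.term_importances(),
                              index=model.feature_names_))
    mat = pd.DataFrame(imps)
    return pd.DataFrame({"mean_importance": mat.mean(axis=0),
                         "sd_importance": mat.std(axis=0, ddof=1)}
                        ).sort_values("mean_importance", ascending=False)


def contribution_report(X: pd.DataFrame, y: np.ndarray,
                        params: EBMParams | None = None,
                        combos: tuple[tuple[str, ...], ...] = DEFAULT_COMBOS,
                        single_domains: list[str] | None = None,
                        ) -> ContributionReport:
    """Full pipeline: fit, importances, ablations, single-domain, combos."""
    model, full = fit_ebm(X, y, params)
    report = ContributionReport(full_model=full, importances=model.importances())
    report.ablations = ablate_domains(X, y, params, full)
    doms = single_domains or sorted(_domain_columns(X))
    for dom in doms:
        report.single_domain[dom] = single_domain_eval(X, y, dom, params, full)
    avail = set(_domain_columns(X))
    usable = tuple(c for c in combos if set(c) <= avail)
    if usable:
        report.combos = combo_eval(X, y, usable, params, full)
    return report
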