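"""Additive-model contribution analysis: fit, ablation, CV, degradation."""

import numpy as np
import pandas as pd
import pytest

from mskit.contrib import (DEFAULT_COMBOS, BoostedGAM, EBMParams,
                           ablate_domains, combo_eval, degradation,
                           domain_of_feature, fit_ebm, participant_cv,
                           single_domain_eval)


def _toy_data(seed=0, n=600, strong="EDA:eda:whole:ptp"):
    rng = np.random.default_rng(seed)
    cols = {
        "EDA:eda:whole:ptp": rng.standard_normal(n),
        "EDA:eda:whole:var": rng.standard_normal(n),
        "HeadPose:rot_pitch:whole:var": rng.standard_normal(n),
        "SKT:skt:whole:mean": rng.standard_normal(n),
        "Demographic:participant:whole:gender": rng.integers(0, 2, n).astype(float),
    }
    X = pd.DataFrame(cols)
    y = 3.0 * X[strong].to_numpy() + 0.3 * rng.standard_normal(n)
    return X, y


class TestDegradation:
    def test_equal_metrics_zero(self):
        assert degradation(0.9, 0.9).delta_pct == 0.0

    def test_total_loss_hundred(self):
        assert degradation(0.8, 0.0).delta_pct == pytest.approx(100.0)

    def test_improvement_negative(self):
        assert degradation(0.8, 0.9).delta_pct < 0.0

    def test_zero_full_rejected(self):
        with pytest.raises(ValueError):
            degradation(0.0, 0.5)


class TestBoostedGAM:
    def test_deterministic_given_seed(self):
        X, y = _toy_data()
        p = EBMParams(seed=42, max_rounds=50)
        m1, f1 = fit_ebm(X, y, p)
        m2, f2 = fit_ebm(X, y, p)
        assert np.array_equal(m1.term_importances(), m2.term_importances())
        assert f1 == f2

    def test_planted_feature_ranks_first(self):
        for seed in range(3):
            X, y = _toy_data(seed=seed)
            model, metrics = fit_ebm(X, y, EBMParams(max_rounds=100))
            imp = model.importances()
            main = imp[[i for i in imp.index if "&" not in i]]
            assert main.index[0] == "EDA:eda:whole:ptp"
            assert metrics.r2 > 0.8

    def test_constant_target_flagged(self):
        X, _ = _toy_data()
        _, metrics = fit_ebm(X, np.full(len(X), 3.0))
        assert metrics.degenerate

    def test_non_finite_target_rejected(self):
        X, y = _toy_data()
        y = y.copy()
        y[0] = np.nan
        with pytest.raises(ValueError):
            fit_ebm(X, y)

    def test_missing_features_imputed(self):
        X, y = _toy_data()
        X = X.copy()
        X.iloc[:20, 1] = np.nan
        model, metrics = fit_ebm(X, y, EBMParams(max_rounds=50))
        assert np.isfinite(model.predict(X)).all()


class TestAblation:
    def test_domains_partition_columns(self):
        X, y = _toy_data()
        doms = [domain_of_feature(c) for c in X.columns]
        assert sorted(set(doms)) == ["Demographic", "EDA", "Head", "SKT"]
        assert len(doms) == len(X.columns)

    def test_dropping_planted_domain_degrades_most(self):
        X, y = _toy_data(seed=1)
        p = EBMParams(max_rounds=80)
        _, full = fit_ebm(X, y, p)
        out = ablate_domains(X, y, p, full)
        r2_deltas = {d: [x for x in trip if x.metric == "r2"][0].delta_pct
                     for d, trip in out.items()}
        assert max(r2_deltas, key=r2_deltas.get) == "EDA"
        assert r2_deltas["EDA"] > 10.0

    def test_single_plus_ablated_cover_all_columns(self):
        X, _ = _toy_data()
        dom = "EDA"
        kept = [c for c in X.columns if domain_of_feature(c) == dom]
        dropped = [c for c in X.columns if domain_of_feature(c) != dom]
        assert sorted(kept + dropped) == sorted(X.columns)

    def test_single_planted_domain_small_delta(self):
        X, y = _toy_data(seed=2)
        p = EBMParams(max_rounds=80)
        _, full = fit_ebm(X, y, p)
        planted = single_domain_eval(X, y, "EDA", p, full)
        noise = single_domain_eval(X, y, "SKT", p, full)
        d_planted = [x for x in planted if x.metric == "r2"][0].delta_pct
        d_noise = [x for x in noise if x.metric == "r2"][0].delta_pct
        assert d_planted < 10.0
        assert d_noise > 50.0


class TestCombos:
    def test_default_list_has_four(self):
        assert len(DEFAULT_COMBOS) == 4
        assert DEFAULT_COMBOS[0] == ("Head", "PPG")

    def test_all_domains_combo_zero_delta(self):
        X, y = _toy_data()
        p = EBMParams(max_rounds=60)
        _, full = fit_ebm(X, y, p)
        out = combo_eval(X, y, (("EDA", "Head", "SKT", "Demographic"),), p, full)
        trip = next(iter(out.values()))
        for d in trip:
            assert d.delta_pct == pytest.approx(0.0, abs=1e-9)

    def test_nested_combo_monotone(self):
        X, y = _toy_data(seed=3)
        p = EBMParams(max_rounds=60)
        _, full = fit_ebm(X, y, p)
        out = combo_eval(X, y, (("Head",), ("Head", "EDA")), p, full)
        small = [x for x in out[("Head",)] if x.metric == "r2"][0].delta_pct
        big = [x for x in out[("Head", "EDA")] if x.metric == "r2"][0].delta_pct
        assert big <= small + 1.0  # adding the signal domain cannot hurt


class TestParticipantCV:
    def _data(self):
        X, y = _toy_data(seed=4, n=200)
        participants = np.repeat([f"p{i}" for i in range(10)], 20)
        return X, y, participants

    def test_every_participant_held_out_once(self):
        X, y, parts = self._data()
        out = participant_cv(X, y, parts, k=5, seed=1,
                             params=EBMParams(max_rounds=20))
        assert set(out.index) == set(X.columns)
        assert (out["mean_importance"] >= 0).all()

    def test_leave_one_participant_out_boundary(self):
        X, y, parts = self._data()
        out = participant_cv(X, y, parts, k=10, seed=1,
                             params=EBMParams(max_rounds=10))
        assert len(out) == X.shape[1]

    def test_k_exceeding_participants_rejected(self):
        X, y, parts = self._data()
        with pytest.raises(ValueError):
            participant_cv(X, y, parts, k=11)

    def test_fold_assignment_deterministic(self):
        X, y, parts = self._data()
        a = participant_cv(X, y, parts, k=5, seed=3,
                           params=EBMParams(max_rounds=10))
        b = participant_cv(X, y, parts, k=5, seed=3,
                           params=EBMParams(max_rounds=10))
        assert np.allclose(a["mean_importance"], b["mean_importance"])
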