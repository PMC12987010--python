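"""rmcorr (vs design-matrix ANCOVA and pingouin), BH adjustment, SESOI tiers."""

import numpy as np
import pandas as pd
import pytest

from mskit.stats import (RmcorrResult, SESOITier, bh_adjust, rmcorr,
                         session_mean_features, sesoi_screen)


from _oracles import ancova_oracle


class TestRmcorr:
    def test_perfect_within_subject_linearity(self):
        rngs = np.random.default_rng(0)
        ids = np.repeat(["a", "b", "c"], 5)
        x = rngs.standard_normal(15)
        offsets = {"a": 10.0, "b": -3.0, "c": 0.5}
        y = 2 * x + np.array([offsets[i] for i in ids])
        res = rmcorr(x, y, ids)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-12

    def test_location_shift_invariance(self):
        rng = np.random.default_rng(1)
        ids = np.repeat(np.arange(4), 6)
        x = rng.standard_normal(24)
        y = rng.standard_normal(24)
        base = rmcorr(x, y, ids)
        shift_x = x + np.array([100.0 * i for i in ids])
        shift_y = y - np.array([7.0 * i for i in ids])
        shifted = rmcorr(shift_x, shift_y, ids)
        assert shifted.r == pytest.approx(base.r, abs=1e-12)
        assert shifted.p == pytest.approx(base.p, abs=1e-12)

    def test_sign_flips_under_negation(self):
        rng = np.random.default_rng(2)
        ids = np.repeat(np.arange(4), 6)
        x = rng.standard_normal(24)
        y = rng.standard_normal(24)
        assert rmcorr(-x, y, ids).r == pytest.approx(-rmcorr(x, y, ids).r)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_design_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ids = np.repeat(np.arange(4), 6)
        x = rng.standard_normal(24)
        y = 0.4 * x + rng.standard_normal(24)
        res = rmcorr(x, y, ids)
        r0, df0, p0 = ancova_oracle(x, y, ids)
        assert res.r == pytest.approx(r0, abs=1e-9)
        assert res.df == df0
        assert res.p == pytest.approx(p0, abs=1e-9)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        ids = np.repeat([f"s{i}" for i in range(6)], 8)
        x = rng.standard_normal(48)
        y = 0.3 * x + rng.standard_normal(48)
        df = pd.DataFrame({"x": x, "y": y, "subject": ids})
        ref = pg.rm_corr(data=df, x="x", y="y", subject="subject")
        res = rmcorr(x, y, ids)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-4)
        assert res.df == int(ref["dof"].iloc[0])

    def test_pairwise_deletion_and_min_two_obs(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 2.0, 3.0, np.nan, 5.0, 6.0, 7.0])
        ids = np.array(["a", "a", "a", "b", "b", "c", "c"])
        res = rmcorr(x, y, ids)
        # participant b drops to 1 complete case and is excluded
        assert res.n_participants == 2
        assert res.n_obs == 4

    def test_insufficient_df_flagged(self):
        res = rmcorr([1.0, 2.0], [1.0, 2.0], ["a", "a"])
        assert not res.valid

    def test_zero_within_variance_flagged(self):
        res = rmcorr([1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
                     [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                     ["a", "a", "a", "b", "b", "b"])
        assert not res.valid or not np.isnan(res.r)


from _oracles import bh_oracle


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 5)
        assert np.allclose(out, 0.2)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_textbook_oracle(self, seed):
        p = np.random.default_rng(seed).uniform(0, 1, 20)
        assert np.allclose(bh_adjust(p), bh_oracle(p), atol=1e-12)

    def test_monotone_in_raw_order(self, rng):
        p = rng.uniform(0, 1, 30)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def _res(r, p):
    return RmcorrResult(r=r, df=100, p=p, n_obs=100, n_participants=10)


class TestSesoiScreen:
    def test_boundary_quarter_is_medium_not_conservative(self):
        out = sesoi_screen({"f": _res(0.25, 0.01)})
        assert out.loc[0, "tier"] == "medium"

    def test_p_gate_blocks_large_r(self):
        out = sesoi_screen({"f": _res(0.40, 0.20)})
        assert out.loc[0, "tier"] == ""

    def test_negative_large(self):
        out = sesoi_screen({"f": _res(-0.31, 0.001)})
        assert out.loc[0, "tier"] == "large"

    def test_tiers_nested(self):
        spec = SESOITier()
        thrs = [t for _, t in spec.thresholds]
        assert thrs == sorted(thrs)


class TestMixedAnovaDelegation:
    def test_within_subject_effect_detected(self):
        pytest.importorskip("pingouin")
        from mskit.stats import mixed_anova
        rng = np.random.default_rng(7)
        rows = []
        for pid in range(12):
            base = rng.normal(0, 1)
            group = "A" if pid < 6 else "B"
            for ci, cond in enumerate(["CMS", "VIMS", "CoMS"]):
                rows.append({"subject": pid, "cond": cond, "group": group,
                             "y": base + ci * 2.0 + rng.normal(0, 0.3)})
        df = pd.DataFrame(rows)
        out = mixed_anova(df, dv="y", within="cond", subject="subject",
                          between="group")
        cond_p = float(out.loc[out["Source"] == "cond", "p_unc"].iloc[0])
        assert cond_p < 1e-6


class TestSessionMeans:
    def test_all_windows_equal(self):
        df = pd.DataFrame({"participant": ["p"] * 3, "session": ["CMS"] * 3,
                           "feature_id": ["f"] * 3, "value": [2.0] * 3,
                           "missing": [False] * 3})
        out = session_mean_features(df)
        assert out["value"].iloc[0] == 2.0

    def test_missing_window_excluded(self):
        df = pd.DataFrame({"participant": ["p"] * 3, "session": ["CMS"] * 3,
                           "feature_id": ["f"] * 3,
                           "value": [1.0, 3.0, 99.0],
                           "missing": [False, False, True]})
        out = session_mean_features(df)
        assert out["value"].iloc[0] == 2.0

    def test_matches_groupby_oracle(self, rng):
        df = pd.DataFrame({
            "participant": rng.choice(["a", "b"], 40),
            "session": rng.choice(["CMS", "VIMS"], 40),
            "feature_id": rng.choice(["f1", "f2"], 40),
            "value": rng.standard_normal(40),
            "missing": [False] * 40,
        })
        out = session_mean_features(df)
        want = df.groupby(["participant", "session", "feature_id"])["value"].mean()
        for _, row in out.iterrows():
            assert row["value"] == pytest.approx(
                want.loc[(row["participant"], row["session"],
                          row["feature_id"])])
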