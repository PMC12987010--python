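"""Eye features: closure, denoising, vergence, gaze angles and kinematics."""

from itertools import groupby, product

import numpy as np
import pytest
from scipy.optimize import minimize

from mskit.features.eye import (blink_rate, closure_combination,
                                convergence_distance, denoise_closure,
                                eye_closure, gaze_angles, gaze_velocity,
                                heatmap_entropy)


class TestEyeClosure:
    def test_null_position_is_closed(self):
        pos = np.array([[np.nan, np.nan, np.nan], [0.1, 0.0, 0.0]])
        center = np.zeros((2, 3))
        assert eye_closure(pos, center).tolist() == [1, 0]

    def test_exact_center_is_closed(self):
        pos = np.zeros((1, 3))
        assert eye_closure(pos, np.zeros((1, 3))).tolist() == [1]

    def test_2mm_offset_is_open(self):
        pos = np.array([[0.002, 0.0, 0.0]])
        assert eye_closure(pos, np.zeros((1, 3))).tolist() == [0]


from _oracles import has_interior_isolated as _has_interior_isolated


class TestDenoiseClosure:
    def test_isolated_one_suppressed(self):
        assert denoise_closure(np.array([0, 1, 0])).tolist() == [0, 0, 0]

    def test_isolated_zero_suppressed(self):
        assert denoise_closure(np.array([1, 0, 1])).tolist() == [1, 1, 1]

    def test_constant_unchanged(self):
        assert denoise_closure(np.ones(6, dtype=int)).tolist() == [1] * 6

    def test_exhaustive_fixed_point_up_to_length_12(self):
        # every binary string converges to a state with no interior isolated
        # singleton, and the result is a fixed point (idempotent)
        for n in range(1, 13):
            for bits in product((0, 1), repeat=n):
                out = denoise_closure(np.array(bits, dtype=np.int8))
                assert not _has_interior_isolated(out.tolist())
                again = denoise_closure(out)
                assert np.array_equal(out, again)


class TestClosureCombination:
    def test_identical_inputs(self):
        s = np.array([0, 1, 1, 0])
        a, o = closure_combination(s, s)
        assert np.array_equal(a, s) and np.array_equal(o, s)

    def test_complementary_inputs(self):
        s = np.array([0, 1, 0, 1])
        a, o = closure_combination(s, 1 - s)
        assert not a.any() and o.all()

    def test_and_never_exceeds_or(self, rng):
        l = rng.integers(0, 2, 50)
        r = rng.integers(0, 2, 50)
        a, o = closure_combination(l, r)
        assert np.all(a <= o)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            closure_combination(np.zeros(3), np.zeros(4))


def _rle_blinks(s):
    runs = [k for k, _ in groupby(s)]
    first_run_is_blink = 1 if s[0] == 1 else 0
    return runs.count(1) - first_run_is_blink


class TestBlinkRate:
    def test_no_closures(self):
        z = np.zeros(900, dtype=int)
        assert blink_rate(z, z, 30.0) == 0.0

    def test_arithmetic_example(self):
        # 5 left and 3 right blinks in 30 s -> (10 + 6) / 2 = 8 per minute
        def pulses(k):
            s = np.zeros(900, dtype=int)
            for i in range(k):
                s[50 + i * 100: 55 + i * 100] = 1
            return s
        assert blink_rate(pulses(5), pulses(3), 30.0) == pytest.approx(8.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_run_length_oracle(self, seed):
        rng = np.random.default_rng(seed)
        l = rng.integers(0, 2, 200)
        r = rng.integers(0, 2, 200)
        got = blink_rate(l, r, 60.0)
        want = (_rle_blinks(l.tolist()) + _rle_blinks(r.tolist())) / 2
        assert got == pytest.approx(want)


class TestConvergenceDistance:
    def test_parallel_gazes_nan(self):
        d = np.array([[0.0, 0.0, 1.0]])
        out = convergence_distance([[-0.03, 0, 0]], [[0.03, 0, 0]], d, d)
        assert np.isnan(out[0])

    def test_intersecting_lines_zero(self):
        # coplanar, intersecting at (0, 0, 1)
        p_l = np.array([[-0.03, 0.0, 0.0]])
        p_r = np.array([[0.03, 0.0, 0.0]])
        d_l = np.array([[0.03, 0.0, 1.0]])
        d_r = np.array([[-0.03, 0.0, 1.0]])
        d_l /= np.linalg.norm(d_l)
        d_r /= np.linalg.norm(d_r)
        out = convergence_distance(p_l, p_r, d_l, d_r)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_skew_lines_match_minimization_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p_l = rng.uniform(-0.1, 0.1, 3)
        p_r = rng.uniform(-0.1, 0.1, 3)
        d_l = rng.standard_normal(3)
        d_r = rng.standard_normal(3)
        d_l /= np.linalg.norm(d_l)
        d_r /= np.linalg.norm(d_r)

        def dist2(st):
            s, t = st
            return float(np.sum((p_l + s * d_l - (p_r + t * d_r)) ** 2))

        res = minimize(dist2, [0.0, 0.0], method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-24,
                                "maxiter": 20000})
        want = np.sqrt(res.fun)
        got = convergence_distance(p_l[None], p_r[None], d_l[None], d_r[None])[0]
        assert got == pytest.approx(want, abs=1e-9)


class TestGazeAngles:
    @pytest.mark.parametrize("g,yaw,pitch", [
        ((0, 0, 1), 0.0, 0.0),
        ((1, 0, 0), 90.0, 0.0),
        ((0, 1, 0), 0.0, 90.0),
    ])
    def test_cardinal_directions(self, g, yaw, pitch):
        y, p = gaze_angles(np.array([g], dtype=float))
        assert y[0] == pytest.approx(yaw)
        assert p[0] == pytest.approx(pitch)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            gaze_angles(np.zeros((1, 3)))


class TestHeatmapEntropy:
    def test_single_bin_zero_bits(self):
        assert heatmap_entropy(np.zeros(100), np.zeros(100)) == 0.0

    def test_uniform_occupancy_twelve_bits(self):
        centers = (np.arange(64) + 0.5) * (180 / 64) - 90
        yaw, pitch = np.meshgrid(centers, centers)
        assert heatmap_entropy(yaw.ravel(), pitch.ravel()) == \
            pytest.approx(12.0, abs=1e-9)

    def test_random_matches_histogram_oracle(self, rng):
        yaw = rng.uniform(-80, 80, 2000)
        pitch = rng.uniform(-80, 80, 2000)
        h, _, _ = np.histogram2d(yaw, pitch, bins=64,
                                 range=[[-90, 90], [-90, 90]])
        p = h.ravel() / h.sum()
        p = p[p > 0]
        want = -(p * np.log2(p)).sum()
        assert heatmap_entropy(yaw, pitch) == pytest.approx(want, abs=1e-12)


class TestGazeVelocity:
    def test_constant_direction(self):
        d = np.tile([0.0, 0.0, 1.0], (50, 1))
        v, wdfs = gaze_velocity(d, 30.0)
        assert np.allclose(v, 0.0)
        assert wdfs["saccade_ratio"] == 0.0
        assert wdfs["fixation_ratio"] == 1.0
        assert wdfs["path_length"] == 0.0

    def test_one_degree_per_frame_is_fixation(self):
        angles = np.radians(np.arange(30))
        d = np.column_stack([np.sin(angles), np.zeros(30), np.cos(angles)])
        v, wdfs = gaze_velocity(d, 30.0)
        assert np.allclose(v, 30.0, atol=1e-6)
        assert wdfs["saccade_ratio"] == 0.0

    def test_four_degrees_per_frame_is_saccade(self):
        angles = np.radians(np.arange(0, 120, 4))
        d = np.column_stack([np.sin(angles), np.zeros(len(angles)),
                             np.cos(angles)])
        v, wdfs = gaze_velocity(d, 30.0)
        assert np.allclose(v, 120.0, atol=1e-6)
        assert wdfs["saccade_ratio"] == 1.0
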