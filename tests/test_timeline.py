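"""Timeline reconstruction: merging, trimming, expected-grid alignment."""

import numpy as np
import pytest

from mskit.timeline import (ReconstructionError, align_to_grid,
                            build_expected_grid, merge_fragments, trim_edges)
from mskit.types import SensorStream


def _stream(rate, t0, t1, fn=np.sin, name="s"):
    t = np.arange(t0, t1, 1.0 / rate)
    return SensorStream(name=name, rate=rate, values=fn(t), timestamps=t)


class TestMergeFragments:
    def test_single_fragment_unchanged(self):
        s = _stream(4.0, 0, 100)
        out = merge_fragments([s])
        assert np.array_equal(out.values, s.values)

    def test_restart_overlap_seam_at_midpoint(self):
        # interruption at t=500, restart at 490: seam lands at 495
        rate = 4.0
        full = _stream(rate, 0, 1200)
        t = full.times
        f1 = SensorStream("s", rate, full.values[t < 500], timestamps=t[t < 500])
        m2 = t >= 490
        f2 = SensorStream("s", rate, full.values[m2], timestamps=t[m2])
        out = merge_fragments([f2, f1])  # order-insensitive
        ot = out.times
        assert ot[0] == 0.0
        assert ot[-1] == pytest.approx(1200 - 1 / rate)
        assert len(ot) == len(np.unique(ot))
        # seam: left part ends just below 495, right part starts at 495
        assert np.max(ot[ot < 495]) < 495
        assert 495.0 in ot

    @pytest.mark.parametrize("seed", range(5))
    def test_random_fragmentations_cover_union(self, seed):
        rng = np.random.default_rng(seed)
        rate = 8.0
        full = _stream(rate, 0, 600)
        t = full.times
        cuts = np.sort(rng.uniform(60, 540, size=2))
        frags = []
        start = 0.0
        for c in list(cuts) + [600.0]:
            m = (t >= start) & (t < c)
            frags.append(SensorStream("s", rate, full.values[m], timestamps=t[m]))
            start = c - 12.0
        out = merge_fragments(frags)
        assert len(frags) == 3
        assert len(out.times) == len(np.unique(out.times))
        assert out.times[0] == 0.0
        assert out.times[-1] == t[-1]

    def test_gap_raises_with_span(self):
        f1 = _stream(4.0, 0, 100)
        f2 = _stream(4.0, 110, 200)
        with pytest.raises(ReconstructionError, match="gap"):
            merge_fragments([f1, f2])


class TestTrimEdges:
    def test_1200s_to_1140s(self):
        s = _stream(2.0, 0, 1200)
        out = trim_edges(s, 30.0)
        assert out.n_samples == 1140 * 2
        assert out.times[0] == 0.0

    def test_zero_trim_is_identity(self):
        s = _stream(2.0, 0, 100)
        assert trim_edges(s, 0.0) is s

    def test_too_short_rejected(self):
        s = _stream(2.0, 0, 59)
        with pytest.raises(ValueError):
            trim_edges(s, 30.0)


class TestExpectedGrid:
    @pytest.mark.parametrize("rate,duration,n", [
        (128.0, 1140.0, 145_920),
        (1.0, 1140.0, 1140),
        (500.0, 1140.0, 570_000),
    ])
    def test_counts(self, rate, duration, n):
        assert build_expected_grid(rate, duration).n_expected == n

    def test_non_integer_product_flagged(self):
        with pytest.raises(ValueError, match="integer"):
            build_expected_grid(0.3, 1001.0)

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            build_expected_grid(-1.0, 10.0)


class TestAlignToGrid:
    def test_on_grid_identity(self):
        grid = build_expected_grid(10.0, 10.0)
        t = grid.timestamps
        v = np.sin(t)
        out = align_to_grid(t, v, grid)
        assert not out.filled_mask.any()
        assert np.allclose(out.values, v)

    def test_missing_interior_of_linear_ramp_filled_linearly(self):
        grid = build_expected_grid(10.0, 2.0)
        t = grid.timestamps
        v = 3.0 * t + 1.0
        keep = np.ones(len(t), dtype=bool)
        keep[7] = False
        out = align_to_grid(t[keep], v[keep], grid)
        assert out.filled_mask[7]
        assert out.values[7] == pytest.approx(v[7], abs=1e-12)

    def test_duplicate_index_takes_temporally_closest(self):
        grid = build_expected_grid(1.0, 5.0)
        # two samples near index 2: 2.3 s loses to 1.9 s
        t = np.array([0.0, 1.0, 1.9, 2.3, 3.0, 4.0])
        v = np.array([0.0, 1.0, 20.0, 30.0, 3.0, 4.0])
        out = align_to_grid(t, v, grid)
        assert out.values[2] == 20.0

    @pytest.mark.parametrize("nyq_div,tol", [(8, 0.01), (16, 0.01), (4, 0.03)])
    def test_jittered_sinusoid_round_trip(self, nyq_div, tol):
        # sinusoid through chunk-count jitter recovers on the grid; below an
        # eighth of Nyquist the RMSE stays under 1% of amplitude, and at a
        # quarter of Nyquist the shape-preserving limiter (which flattens
        # extrema of a coarsely sampled tone) caps accuracy at a few percent
        from mskit.synthgen import perturb_chunk_timing
        rate = 64.0
        grid = build_expected_grid(rate, 30.0)
        f = rate / 2.0 / nyq_div
        clean = np.sin(2 * np.pi * f * grid.timestamps)
        s = SensorStream("s", rate, clean, timestamps=grid.timestamps)
        jittered = perturb_chunk_timing(s, chunk_rate_hz=16.0,
                                        max_dev_chunks=1, seed=7)
        out = align_to_grid(jittered.times, jittered.values, grid)
        rmse = np.sqrt(np.mean((out.values - clean) ** 2))
        assert rmse < tol

    def test_output_length_equals_grid(self):
        grid = build_expected_grid(5.0, 8.0)
        out = align_to_grid(np.array([1.0, 2.0, 5.0]), np.array([1., 2., 3.]),
                            grid)
        assert len(out.values) == grid.n_expected
        assert out.filled_mask.sum() + out.n_observed == grid.n_expected

    def test_monotone_data_stays_monotone(self):
        grid = build_expected_grid(4.0, 10.0)
        t = np.sort(np.random.default_rng(3).uniform(0, 10, 15))
        v = np.cumsum(np.random.default_rng(4).uniform(0, 1, 15))
        out = align_to_grid(t, v, grid)
        assert np.all(np.diff(out.values) >= -1e-12)

    def test_interpolation_is_local(self):
        # perturbing one observed sample changes fills only between its
        # neighbouring anchors
        grid = build_expected_grid(1.0, 20.0)
        t = np.arange(0.0, 20.0, 2.0)  # observed every other index
        v = np.sin(t)
        base = align_to_grid(t, v, grid).values
        v2 = v.copy()
        v2[5] += 1.0  # anchor at t=10 (grid index 10)
        pert = align_to_grid(t, v2, grid).values
        changed = np.flatnonzero(~np.isclose(base, pert))
        # PCHIP support: the perturbed anchor influences its own intervals
        # plus one interval on each side (via the derivative estimates)
        assert changed.min() >= 6 and changed.max() <= 14

    def test_empty_and_degenerate_inputs_rejected(self):
        grid = build_expected_grid(1.0, 5.0)
        with pytest.raises(ValueError):
            align_to_grid(np.array([]), np.array([]), grid)
        with pytest.raises(ValueError):
            align_to_grid(np.array([1.0, 1.0]), np.array([1.0, 2.0]), grid)
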