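"""Synthetic cohort generation: determinism, design, degradations, round trips."""

import numpy as np
import pytest

from mskit.synthgen import (SyntheticConfig, counterbalancing_cells,
                            generate_cohort, generate_msl_trajectory,
                            inject_fragmentation, perturb_chunk_timing,
                            read_session, write_session)
from mskit.synthgen.config import SensorSpec
from mskit.timeline import build_expected_grid, align_to_grid, merge_fragments
from mskit.types import SensorStream

_SMALL = dict(
    n_participants=2, ms_types=("CMS",), session_length_s=120,
    sensor_specs=(SensorSpec("eda", 32.0, ("resistance_kohm",)),
                  SensorSpec("skt", 1.0, ("temp_c",))),
)


class TestTrajectory:
    def test_zero_susceptibility_identically_zero(self):
        assert not generate_msl_trajectory(600, 0.0, "CMS", seed=3).any()

    def test_deterministic(self):
        a = generate_msl_trajectory(600, 1.0, "VIMS", seed=42)
        b = generate_msl_trajectory(600, 1.0, "VIMS", seed=42)
        assert np.array_equal(a, b)

    def test_non_negative_and_rising_on_average(self):
        m = generate_msl_trajectory(1200, 1.5, "CMS", seed=5)
        assert (m >= 0).all()
        assert m[-100:].mean() > m[:100].mean()

    def test_terminal_value_increases_with_susceptibility(self):
        # Monte Carlo over 200 seeds per susceptibility level
        means = []
        for s in (0.5, 1.0, 2.0):
            terms = [generate_msl_trajectory(600, s, "CMS", seed=k)[-1]
                     for k in range(200)]
            means.append(np.mean(terms))
        assert means[0] < means[1] < means[2]

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_msl_trajectory(0, 1.0)


class TestFragmentation:
    def _stream(self, rate=32.0, dur=600.0):
        t = np.arange(0, dur, 1 / rate)
        return SensorStream("s", rate, np.sin(0.1 * t), timestamps=t)

    def test_zero_events_identity(self):
        s = self._stream()
        out = inject_fragmentation(s, [], overlap_s=10)
        assert len(out) == 1 and out[0] is s

    def test_restart_example(self):
        s = self._stream(rate=4.0, dur=1200.0)
        frags = inject_fragmentation(s, [500.0], overlap_s=10)
        assert len(frags) == 2
        assert frags[0].times[0] == 0.0
        assert frags[0].times[-1] < 500.0
        assert frags[1].times[0] == pytest.approx(490.0)
        assert frags[1].times[-1] == s.times[-1]

    def test_two_events_round_trip_through_timeline(self):
        s = self._stream(rate=32.0, dur=600.0)
        frags = inject_fragmentation(s, [200.0, 400.0], overlap_s=10)
        assert len(frags) == 3
        merged = merge_fragments(frags)
        assert np.allclose(merged.times, s.times)
        assert np.allclose(merged.values, s.values)

    def test_event_outside_span_rejected(self):
        with pytest.raises(ValueError):
            inject_fragmentation(self._stream(), [9999.0])

    def test_small_overlap_rejected(self):
        with pytest.raises(ValueError):
            inject_fragmentation(self._stream(), [300.0], overlap_s=2)


class TestChunkJitter:
    def _bandlimited(self, rate=128.0, dur=60.0, f=10.0):
        t = np.arange(0, dur, 1 / rate)
        return SensorStream("s", rate, np.sin(2 * np.pi * f * t), timestamps=t)

    def test_zero_deviation_identity(self):
        s = self._bandlimited()
        assert perturb_chunk_timing(s, max_dev_chunks=0) is s

    def test_deterministic(self):
        s = self._bandlimited()
        a = perturb_chunk_timing(s, seed=9)
        b = perturb_chunk_timing(s, seed=9)
        assert np.array_equal(a.values, b.values)
        assert np.array_equal(a.timestamps, b.timestamps)

    def test_per_second_counts_within_one_chunk(self):
        s = self._bandlimited()
        out = perturb_chunk_timing(s, chunk_rate_hz=16.0, max_dev_chunks=1,
                                   seed=1)
        counts = np.bincount(out.times.astype(int))
        chunk = 8  # 128 / 16
        assert np.all(np.abs(counts[:-1] - 128) <= chunk)

    def test_round_trip_after_grid_correction(self):
        # a 10-Hz bandlimited signal at 128 Hz survives jitter + alignment
        s = self._bandlimited(rate=128.0, dur=60.0, f=10.0)
        out = perturb_chunk_timing(s, seed=2)
        grid = build_expected_grid(128.0, 60.0)
        rec = align_to_grid(out.times, out.values, grid)
        rmse = np.sqrt(np.mean((rec.values - s.values) ** 2))
        assert rmse < 0.02


class TestCohort:
    def test_counterbalancing_16_cells_used_once(self):
        cfg = SyntheticConfig(seed=0, **_SMALL | {"n_participants": 16})
        _, truth = generate_cohort(cfg)
        cells = list(truth.assignment.values())
        assert len(cells) == 16
        assert sorted(cells) == sorted(counterbalancing_cells())

    def test_sample_count_before_degradation(self):
        # 1200-s PPG at 128 Hz carries 153,600 samples pre-trim
        cfg = SyntheticConfig(
            n_participants=1, ms_types=("CMS",), session_length_s=1200,
            sensor_specs=(SensorSpec("ppg", 128.0, ("ppg",)),),
            jitter_chunks=0, fragmentation_rate=0.0, seed=3)
        sessions, _ = generate_cohort(cfg)
        frags = sessions[0].streams["ppg"]
        assert sum(f.n_samples for f in frags) == 153_600

    def test_deterministic_given_seed(self):
        cfg = SyntheticConfig(seed=7, **_SMALL)
        s1, t1 = generate_cohort(cfg)
        s2, t2 = generate_cohort(cfg)
        for a, b in zip(s1, s2):
            for name in a.streams:
                for fa, fb in zip(a.streams[name], b.streams[name]):
                    assert np.array_equal(fa.values, fb.values)
                    assert np.array_equal(fa.times, fb.times)
            assert a.fms_reports == b.fms_reports
            assert a.questionnaires == b.questionnaires
        for key in t1.latent_msl:
            assert np.array_equal(t1.latent_msl[key], t2.latent_msl[key])

    def test_one_record_per_participant_session(self):
        cfg = SyntheticConfig(seed=1, **_SMALL | {"ms_types": ("CMS", "VIMS")})
        sessions, _ = generate_cohort(cfg)
        keys = {(s.participant, s.ms_type) for s in sessions}
        assert len(keys) == 4

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_participants=0)
        with pytest.raises(ValueError):
            SyntheticConfig(session_length_s=50)
        with pytest.raises(ValueError):
            SyntheticConfig(sensor_specs=(SensorSpec("x", -1.0, ("a",)),))

    def test_fms_reports_on_scale(self):
        cfg = SyntheticConfig(seed=2, **_SMALL)
        sessions, _ = generate_cohort(cfg)
        for rec in sessions:
            vals = [v for _, v in rec.fms_reports]
            assert all(1 <= v <= 5 for v in vals)


class TestSessionIO:
    def test_round_trip(self, tmp_path):
        cfg = SyntheticConfig(seed=4, **_SMALL)
        sessions, _ = generate_cohort(cfg)
        rec = sessions[0]
        sdir = write_session(tmp_path, rec)
        back = read_session(sdir)
        assert back.participant == rec.participant
        assert back.ms_type == rec.ms_type
        assert back.fms_reports == rec.fms_reports
        for name in rec.streams:
            orig = rec.streams[name]
            got = back.streams[name]
            assert len(got) == len(orig)
            assert np.allclose(got[0].values, orig[0].values, atol=1e-5)
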