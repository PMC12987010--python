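"""Cohort assembly: counterbalancing, sessions, questionnaires, ground truth.

Participants are assigned cyclically, in enrollment order, to the 16-cell
counterbalancing design crossing 2 visual-induction types (flat display vs
see-through HMD), 4 driving-scenario versions, and 2 movie orders.  Each
participant contributes one session per MS type (classical, visually
induced, composite).

Seed policy: one master seed; per-(participant, session, sensor) child
generators derive from ``numpy.random.SeedSequence`` spawn keys, so any
subset of sensors regenerates identically.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from ..types import SensorStream, SessionRecord
from .config import GroundTruth, SyntheticConfig
from .degrade import inject_fragmentation, perturb_chunk_timing
from .signals import GENERATORS, msl_at_rate
from .trajectory import fms_reports, generate_msl_trajectory

VIMS_TYPES = ("F-VIMS", "S-VIMS")
SCENARIO_VERSIONS = (1, 2, 3, 4)
MOVIE_ORDERS = (1, 2)


def counterbalancing_cells() -> list[tuple[str, int, int]]:
    """The 16 design cells: 2 VIMS types x 4 scenario versions x 2 orders."""
    return list(product(VIMS_TYPES, SCENARIO_VERSIONS, MOVIE_ORDERS))


def _child_rng(master: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(master, spawn_key=key))


def _questionnaires(rng: np.random.Generator, susceptibility: float,
                    terminal_msl: float) -> dict:
    """Item-level questionnaire records from a susceptibility scalar."""
    def mssq_era(gain: float) -> list[tuple[int, bool]]:
        items = []
        for _ in range(9):
            experienced = bool(rng.random() < 0.85)
            freq = int(np.clip(round(gain * susceptibility
                                     + rng.normal(0, 0.7)), 0, 4))
            items.append((freq, experienced))
        return items

    ssq_pre = rng.binomial(1, 0.08, size=16).astype(int)
    bump = np.clip(np.round(terminal_msl * rng.uniform(0.4, 1.0, size=16)
                            + rng.normal(0, 0.4, size=16)), 0, 3)
    ssq_post = np.clip(ssq_pre + bump, 0, 3).astype(int)
    ieq = np.clip(np.round(rng.normal(3.0, 1.0, size=24)), 1, 5).astype(int)
    return {
        "mssq_child": mssq_era(1.8),
        "mssq_adult": mssq_era(1.5),
        "ssq_pre": ssq_pre.tolist(),
        "ssq_post": ssq_post.tolist(),
        "ieq": ieq.tolist(),
    }


def generate_cohort(config: SyntheticConfig,
                    ) -> tuple[list[SessionRecord], GroundTruth]:
    """Generate one session per participant x MS type, plus ground truth."""
    cells = counterbalancing_cells()
    truth = GroundTruth(planted_loadings=dict(config.effect_sizes))
    sessions: list[SessionRecord] = []
    n_seconds = config.session_length_s

    for p_idx in range(config.n_participants):
        pid = f"P{p_idx + 1:03d}"
        p_rng = _child_rng(config.seed, p_idx, 999, 0)
        susceptibility = float(p_rng.lognormal(0.0, 0.45))
        gender = "female" if p_rng.random() < 0.3 else "male"
        truth.assignment[pid] = cells[p_idx % len(cells)]
        truth.susceptibility[pid] = susceptibility

        terminal = 0.0
        for s_idx, ms_type in enumerate(config.ms_types):
            traj_seed = np.random.SeedSequence(config.seed,
                                               spawn_key=(p_idx, s_idx, 900))
            msl = generate_msl_trajectory(n_seconds, susceptibility, ms_type,
                                          seed=traj_seed)
            truth.latent_msl[(pid, ms_type)] = msl
            terminal = max(terminal, float(msl[-1]) if len(msl) else 0.0)

            rec = SessionRecord(participant=pid, ms_type=ms_type,
                                session_length_s=n_seconds)
            fms_rng = _child_rng(config.seed, p_idx, s_idx, 901)
            rec.fms_reports = fms_reports(msl, fms_rng)

            frag_rng = _child_rng(config.seed, p_idx, s_idx, 902)
            n_events = frag_rng.poisson(config.fragmentation_rate)
            events: list[float] = []
            for _ in range(n_events):
                e = float(frag_rng.uniform(60.0, n_seconds - 60.0))
                if all(abs(e - prev) > 30.0 for prev in events):
                    events.append(e)
            events.sort()

            for sensor_idx, spec in enumerate(config.sensor_specs):
                rng = _child_rng(config.seed, p_idx, s_idx, sensor_idx)
                n = int(round(spec.rate * n_seconds))
                msl_norm = msl_at_rate(msl, spec.rate, n)
                values = GENERATORS[spec.name](n, spec.rate, msl_norm,
                                               config.effect_sizes, rng)
                stream = SensorStream(name=spec.name, rate=spec.rate,
                                      values=values, channels=spec.channels)
                if config.jitter_chunks > 0 and spec.rate > 1:
                    jseed = np.random.SeedSequence(
                        config.seed, spawn_key=(p_idx, s_idx, sensor_idx, 1))
                    stream = perturb_chunk_timing(
                        stream, chunk_rate_hz=config.chunk_rate_hz,
                        max_dev_chunks=config.jitter_chunks, seed=jseed)
                fragments = inject_fragmentation(
                    stream, events, overlap_s=config.fragment_overlap_s)
                rec.streams[spec.name] = fragments
            sessions.append(rec)

        q_rng = _child_rng(config.seed, p_idx, 999, 1)
        quest = _questionnaires(q_rng, susceptibility, terminal)
        demographics = {"gender": gender, "susceptibility": susceptibility}
        for rec in sessions[-len(config.ms_types):]:
            rec.questionnaires = quest
            rec.demographics = demographics
    return sessions, truth
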