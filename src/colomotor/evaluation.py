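"""Benchmarking detection output against simulator ground truth.

Alongside the scoring helpers this module defines the reference benchmark
scenarios: fixed event menus with seed-controlled timing that exercise all
five event classes under realistic amplitudes and velocities, the
sphincter/artifact discrimination setting, and the alternating
intrahaustral schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import ClassifiedEvent
from .haustral import HaustralStateSegment
from .recording_io import PhaseWindow
from .synthetic import (
    ArtifactSpec,
    GroundTruthEvent,
    IntrahaustralSpec,
    IsolatedTransientSpec,
    PropagatingWaveSpec,
    ScenarioConfig,
    SphincterSpec,
    SPWTrainSpec,
)

__all__ = [
    "ClassScores",
    "match_events",
    "precision_recall",
    "state_block_accuracy",
    "benchmark_scenario",
    "artifact_benchmark_scenario",
    "intrahaustral_benchmark_scenario",
]


def benchmark_scenario(seed: int, noise_sd: float = 1.0) -> ScenarioConfig:
    """Mixed-event benchmark session (7 min) exercising all five classes.

    Four SPWs (~20 mmHg, full array), three APWs (5 cm/s, 30 mmHg), three
    RPWs (2 cm/s, 25 mmHg), one HAPW (130 mmHg) and 3-4 isolated transients
    (log-normal amplitudes within 8-230 mmHg) are placed on a shuffled
    26-s slot grid so events never overlap; the shuffle is seed-derived.
    """
    rng = np.random.default_rng(seed + 1000)
    duration = 420.0
    slots = list(np.arange(30.0, duration - 30.0, 26.0))
    rng.shuffle(slots)
    iso_events = [
        (
            float(t),
            int(rng.integers(1, 37)),
            float(np.clip(30 * np.exp(0.8 * rng.standard_normal()), 8, 230)),
        )
        for t in sorted(slots[11:15])
    ]
    return ScenarioConfig(
        duration_s=duration,
        seed=seed,
        noise_sd=noise_sd,
        pattern_specs=[
            SPWTrainSpec(times=sorted(slots[0:4]), gas_fraction=0),
            PropagatingWaveSpec(velocity=5.0, times=sorted(slots[4:7]), span=(10, 24), amplitude=30),
            PropagatingWaveSpec(velocity=-2.0, times=sorted(slots[7:10]), span=(12, 26), amplitude=25),
            PropagatingWaveSpec(velocity=1.5, times=[slots[10]], span=(6, 15), amplitude=130, amplitude_cv=0.05),
            IsolatedTransientSpec(events=iso_events),
        ],
    )


def artifact_benchmark_scenario(
    seed: int, n_spws: int = 20, n_coughs: int = 20
) -> ScenarioConfig:
    """SPWs interleaved with coughs under a sphincter pull-back phase.

    SPWs relax the sphincter ahead of arrival; coughs pressurize it — the
    setting for the colonic-vs-abdominal discrimination check.
    """
    duration = 40.0 + 60.0 * max(n_spws, n_coughs) + 40.0
    return ScenarioConfig(
        duration_s=duration,
        seed=seed,
        noise_sd=1.0,
        phases=[PhaseWindow("sphincter_pullback", 0.0, duration)],
        sphincter=SphincterSpec(),
        pattern_specs=[
            SPWTrainSpec(times=[40.0 + 60.0 * k for k in range(n_spws)], gas_fraction=0),
            ArtifactSpec(subtype="cough", times=[70.0 + 60.0 * k for k in range(n_coughs)]),
        ],
    )


def intrahaustral_benchmark_scenario(
    seed: int,
    frequency_cpm: float = 3.0,
    velocity: float = 2.0,
    direction: str = "mixed",
) -> ScenarioConfig:
    """Alternating segmentation / synchronized schedule on a 5-sensor haustrum.

    Episode durations are multiples of the 60-s labelling block so episode
    switches fall on block boundaries.
    """
    return ScenarioConfig(
        duration_s=720.0,
        seed=seed,
        noise_sd=1.0,
        pattern_specs=[
            IntrahaustralSpec(
                sensor_window=(28, 32),
                schedule=[
                    ("segmentation", 180.0),
                    ("synchronized", 180.0),
                    ("segmentation", 120.0),
                    ("synchronized", 240.0),
                ],
                frequency_cpm=frequency_cpm,
                velocity=velocity,
                direction=direction,
            )
        ],
    )

EVENT_CLASSES = ("SPW", "APW", "RPW", "HAPW", "isolated_transient")


@dataclass
class ClassScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")


def _overlaps(truth: GroundTruthEvent, event: ClassifiedEvent) -> bool:
    lo, hi = truth.span_sensors
    return not (event.last_sensor < lo or event.first_sensor > hi)


def match_events(
    truth: list[GroundTruthEvent],
    detected: list[ClassifiedEvent],
    tol_s: float = 5.0,
) -> dict[str, ClassScores]:
    """Greedy one-to-one matching of detections to ground-truth events.

    A detection matches a truth event of the same class when their onsets
    are within ``tol_s`` and their sensor ranges overlap.  Ground-truth
    entries outside the five event classes (episodes, artifacts) are
    ignored.
    """
    scores = {k: ClassScores() for k in EVENT_CLASSES}
    truth = [t for t in truth if t.kind in EVENT_CLASSES]
    used: set[int] = set()
    for t in truth:
        best, best_d = None, np.inf
        for i, e in enumerate(detected):
            if i in used or e.kind != t.kind:
                continue
            d = abs(e.onset_s - t.onset_s)
            if d <= tol_s and d < best_d and _overlaps(t, e):
                best, best_d = i, d
        if best is None:
            scores[t.kind].fn += 1
        else:
            used.add(best)
            scores[t.kind].tp += 1
    for i, e in enumerate(detected):
        if i not in used and e.kind in EVENT_CLASSES:
            scores[e.kind].fp += 1
    return scores


def precision_recall(
    scores_list: list[dict[str, ClassScores]],
) -> dict[str, tuple[float, float]]:
    """Pool per-seed score dicts; returns class -> (precision, recall)."""
    pooled = {k: ClassScores() for k in EVENT_CLASSES}
    for scores in scores_list:
        for k, s in scores.items():
            pooled[k].tp += s.tp
            pooled[k].fp += s.fp
            pooled[k].fn += s.fn
    return {k: (s.precision, s.recall) for k, s in pooled.items()}


def state_block_accuracy(
    truth_episodes: list[GroundTruthEvent],
    segments: list[HaustralStateSegment],
) -> float:
    """Fraction of labelled blocks matching the generator's episode schedule.

    Each block is compared against the ground-truth state at its midpoint;
    blocks whose midpoint falls outside any scheduled episode are skipped.
    """
    state_of = {
        "segmentation_episode": "segmentation",
        "synchronized_episode": "synchronized",
        "quiescent_episode": "quiescent",
    }
    hits = total = 0
    for seg in segments:
        mid = 0.5 * (seg.start_s + seg.end_s)
        gt_state = None
        for ep in truth_episodes:
            if ep.kind in state_of and ep.onset_s <= mid < ep.onset_s + ep.duration_s:
                gt_state = state_of[ep.kind]
                break
        if gt_state is None:
            continue
        total += 1
        hits += seg.state == gt_state
    return hits / total if total else float("nan")
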