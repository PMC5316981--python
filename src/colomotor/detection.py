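"""Detection and classification of colonic motor events.

The pipeline follows the clinical reading of spatiotemporal pressure maps:

1. per-sensor baseline estimation (rolling low percentile) and transient
   detection (threshold crossings of pressure above baseline, with onset and
   offset placed at the 25%-of-peak crossings);
2. assembly of multi-sensor candidates by chaining transients on adjacent
   sensors whose onsets fall within a short window;
3. propagation-velocity estimation by a robust fit of onset time against
   sensor position — velocities that exceed the ~7 cm/s resolution bound of
   a 1-cm array, or statistically flat onset profiles, are reported as
   "simultaneous";
4. classification into the taxonomy: simultaneous pressure wave (SPW,
   >= 2.5 s, >= 5 mmHg, simultaneous over most of the array), antegrade /
   retrograde propagating wave (APW/RPW, 5-100 mmHg over >= 3 adjacent
   sensors with a measurable velocity), high-amplitude propagating wave
   (HAPW, >= 100 mmHg in >= 3 sensors), or isolated single-sensor transient.

Antegrade means toward the anus, i.e. decreasing sensor index (P1 is
distal), and is reported with positive velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .recording_io import AnnotationLog, Recording, sphincter_channels

__all__ = [
    "ClassificationThresholds",
    "Transient",
    "EventCandidate",
    "ClassifiedEvent",
    "DetectionResult",
    "estimate_baseline",
    "detrend_matrix",
    "detect_transients",
    "group_transients",
    "estimate_velocity",
    "classify_candidate",
    "event_parameters",
    "sphincter_association",
    "gas_association",
    "detect_events",
]

EVENT_KINDS = ("SPW", "APW", "RPW", "HAPW", "isolated_transient")


@dataclass
class ClassificationThresholds:
    """Operating constants of the event classifier.

    The clinically established values: transients must reach 5 mmHg above
    baseline; an SPW lasts at least 2.5 s; velocity can be resolved only up
    to ~7 cm/s on a 1-cm array, beyond which a wave is "simultaneous"; a
    propagating wave of >= 100 mmHg in at least 3 sensors is an HAPW.
    ``min_spw_span_cm`` = 14 cm is the smallest simultaneous-wave extent
    observed (range 14-35 cm) and operationalises "most or all sensors".
    """

    min_amplitude: float = 5.0
    min_spw_duration_s: float = 2.5
    simultaneity_velocity: float = 7.0
    hapw_amplitude: float = 100.0
    hapw_min_sensors: int = 3
    apw_min_sensors: int = 3
    min_spw_span_cm: float = 14.0
    onset_group_window_s: float = 2.0
    merge_gap_s: float = 2.0
    baseline_window_s: float = 60.0
    smoothing_s: float = 0.5
    onset_fraction: float = 0.25
    flat_fit_p: float = 0.05
    sphincter_relaxation_frac: float = 0.2
    sphincter_rise_mmhg: float = 5.0
    sphincter_tone_window_s: float = 60.0
    gas_window_s: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "min_amplitude",
            "min_spw_duration_s",
            "simultaneity_velocity",
            "hapw_amplitude",
            "hapw_min_sensors",
            "apw_min_sensors",
            "min_spw_span_cm",
            "onset_group_window_s",
            "merge_gap_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.hapw_amplitude <= self.min_amplitude:
            raise ValueError("hapw_amplitude must exceed min_amplitude")


@dataclass
class Transient:
    """A single-sensor pressure transient above baseline."""

    sensor_index: int  # 1-based, distal -> proximal
    onset_s: float
    offset_s: float
    peak_s: float
    amplitude: float  # mmHg above local baseline

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class EventCandidate:
    """Transients chained across adjacent sensors, pre-classification."""

    members: list[Transient]

    @property
    def sensors(self) -> list[int]:
        return sorted({t.sensor_index for t in self.members})

    @property
    def onset_s(self) -> float:
        return min(t.onset_s for t in self.members)

    @property
    def offset_s(self) -> float:
        return max(t.offset_s for t in self.members)

    def earliest_onsets(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for t in self.members:
            out[t.sensor_index] = min(out.get(t.sensor_index, np.inf), t.onset_s)
        return out


@dataclass
class ClassifiedEvent:
    """A classified colonic motor event."""

    kind: str
    members: list[Transient]
    onset_s: float
    duration_s: float
    span_cm: float
    velocity: float | str  # signed cm/s, or "simultaneous"
    amplitude_mean: float
    amplitude_max: float
    sphincter_relaxation: str = "undetermined"  # yes | no | undetermined
    gas_associated: bool = False

    @property
    def first_sensor(self) -> int:
        return min(t.sensor_index for t in self.members)

    @property
    def last_sensor(self) -> int:
        return max(t.sensor_index for t in self.members)

    @property
    def offset_s(self) -> float:
        return max(t.offset_s for t in self.members)


@dataclass
class DetectionResult:
    """Full output of :func:`detect_events`."""

    events: list[ClassifiedEvent]
    transients: list[list[Transient]]  # index 0 <-> sensor 1
    mask: np.ndarray
    artifacts: list = field(default_factory=list)
    gas_summary: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Baseline and transients
# ---------------------------------------------------------------------------


def estimate_baseline(
    trace: np.ndarray, sampling_rate: float, window_s: float = 60.0
) -> np.ndarray:
    """Rolling 10th-percentile baseline of a single-sensor trace.

    Insensitive to transients much shorter than the window; tracks slow
    drift with at most a window of lag.
    """
    trace = np.asarray(trace, dtype=float)
    if np.all(np.isnan(trace)):
        raise ValueError("cannot estimate a baseline from an all-NaN trace")
    window = max(3, round(window_s * sampling_rate))
    s = pd.Series(trace)
    return (
        s.rolling(window, center=True, min_periods=max(1, window // 4))
        .quantile(0.10)
        .to_numpy()
    )


def _smooth(trace: np.ndarray, sampling_rate: float, smoothing_s: float) -> np.ndarray:
    n = max(1, round(smoothing_s * sampling_rate))
    if n <= 1:
        return trace
    kernel = np.ones(n) / n
    # reflect-pad so the edges are not biased toward zero
    padded = np.concatenate([trace[n - 1 :: -1], trace, trace[: -n - 1 : -1]])
    return np.convolve(padded, kernel, mode="same")[n : n + len(trace)]


def detrend_matrix(
    recording: Recording, thresholds: ClassificationThresholds
) -> np.ndarray:
    """Smoothed pressure minus rolling baseline, per sensor (zeros if broken)."""
    out = np.zeros_like(recording.pressures)
    for s in recording.functional_sensors():
        trace = recording.pressures[s - 1]
        if np.all(np.isnan(trace)):
            continue
        x = _smooth(np.nan_to_num(trace), recording.sampling_rate, thresholds.smoothing_s)
        out[s - 1] = x - estimate_baseline(
            x, recording.sampling_rate, thresholds.baseline_window_s
        )
    return out


def _runs(above: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.astype(np.int8), [0]))))
    return list(zip(edges[0::2], edges[1::2]))  # half-open [start, stop)


def _merge_runs(runs: list[tuple[int, int]], gap: int) -> list[tuple[int, int]]:
    merged = [runs[0]]
    for a, b in runs[1:]:
        if a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    return merged


def _crossing(d: np.ndarray, i: int, j: int, level: float) -> float:
    """Linear-interpolated index where d crosses ``level`` between i and j."""
    if d[j] == d[i]:
        return float(j)
    frac = (level - d[i]) / (d[j] - d[i])
    return i + frac * (j - i)


def detect_transients(
    recording: Recording,
    thresholds: ClassificationThresholds | None = None,
    mask: np.ndarray | None = None,
    detrended: np.ndarray | None = None,
    sensors: list[int] | None = None,
) -> list[list[Transient]]:
    """Per-sensor transient detection.

    Returns one list per sensor (index 0 corresponds to P1); non-functional
    sensors yield empty lists.  Events whose onset lies inside the artifact
    ``mask`` are dropped; events separated by less than the merge gap are
    merged.
    """
    thr = thresholds or ClassificationThresholds()
    fs = recording.sampling_rate
    if detrended is None:
        detrended = detrend_matrix(recording, thr)
    gap = max(1, round(thr.merge_gap_s * fs))
    out: list[list[Transient]] = [[] for _ in range(recording.n_sensors)]
    wanted = sensors if sensors is not None else recording.functional_sensors()
    for s in wanted:
        if not recording.functional_mask[s - 1]:
            continue
        d = detrended[s - 1]
        above = d >= thr.min_amplitude
        if not above.any():
            continue
        runs = _merge_runs(_runs(above), gap)

        def bounds(a: int, b: int) -> tuple[float, int, float, float]:
            """Peak and interpolated 25%-of-peak crossings, walking outward
            from the peak (the level may sit above or below the detection
            threshold depending on the peak amplitude)."""
            pk = a + int(np.argmax(d[a:b]))
            amp = float(d[pk])
            level = thr.onset_fraction * amp
            i = pk
            while i > 0 and d[i - 1] > level:
                i -= 1
            onset_idx = _crossing(d, i - 1, i, level) if i > 0 else float(i)
            j = pk
            while j < len(d) - 1 and d[j + 1] > level:
                j += 1
            off_idx = _crossing(d, j + 1, j, level) if j < len(d) - 1 else float(j)
            return onset_idx, pk, amp, off_idx

        # low-amplitude events have their 25% crossings outside the threshold
        # run; if the widened extents overlap, the runs are one event
        for _ in range(10):
            spans = [bounds(a, b) for a, b in runs]
            merged_runs: list[tuple[int, int]] = []
            prev_off = -np.inf
            changed = False
            for (a, b), (on, _, _, off) in zip(runs, spans):
                if merged_runs and on <= prev_off:
                    merged_runs[-1] = (merged_runs[-1][0], b)
                    changed = True
                else:
                    merged_runs.append((a, b))
                prev_off = max(prev_off, off)
            if not changed:
                break
            runs = merged_runs
        for onset_idx, pk, amp, off_idx in (bounds(a, b) for a, b in runs):
            if mask is not None and mask[min(int(onset_idx), len(d) - 1)]:
                continue
            out[s - 1].append(
                Transient(s, onset_idx / fs, off_idx / fs, pk / fs, amp)
            )
    return out


# ---------------------------------------------------------------------------
# Grouping and velocity
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def group_transients(
    per_sensor: list[list[Transient]],
    thresholds: ClassificationThresholds | None = None,
) -> list[EventCandidate]:
    """Chain transients on adjacent sensors into multi-sensor candidates.

    Two transients on neighbouring sensors belong to the same candidate when
    their onsets differ by at most the grouping window; matching across each
    sensor boundary is one-to-one (nearest onset first) so that rhythmic
    trains on the same sensors are not fused into one event.  Every
    transient ends up in exactly one candidate.
    """
    thr = thresholds or ClassificationThresholds()
    flat: list[Transient] = [t for lst in per_sensor for t in lst]
    index = {id(t): i for i, t in enumerate(flat)}
    uf = _UnionFind(len(flat))
    n_sensors = len(per_sensor)
    for s in range(n_sensors - 1):
        a_list, b_list = per_sensor[s], per_sensor[s + 1]
        if not a_list or not b_list:
            continue
        pairs = []
        for a in a_list:
            for b in b_list:
                diff = abs(a.onset_s - b.onset_s)
                if diff <= thr.onset_group_window_s:
                    pairs.append((diff, index[id(a)], index[id(b)]))
        pairs.sort()
        used_a: set[int] = set()
        used_b: set[int] = set()
        for _, ia, ib in pairs:
            if ia in used_a or ib in used_b:
                continue
            uf.union(ia, ib)
            used_a.add(ia)
            used_b.add(ib)
    groups: dict[int, list[Transient]] = {}
    for i, t in enumerate(flat):
        groups.setdefault(uf.find(i), []).append(t)
    candidates = [
        EventCandidate(sorted(g, key=lambda t: (t.sensor_index, t.onset_s)))
        for g in groups.values()
    ]
    candidates.sort(key=lambda c: c.onset_s)
    return candidates


def estimate_velocity(
    candidate: EventCandidate,
    sensor_spacing: float,
    thresholds: ClassificationThresholds | None = None,
) -> float | str | None:
    """Signed propagation velocity (cm/s) of a candidate, or "simultaneous".

    A Theil-Sen fit of onset time against sensor position gives the slope;
    positive velocity is antegrade (toward the anus).  The wave is reported
    as simultaneous when the fitted speed exceeds the resolution bound or
    the onset-position relation is statistically flat.  Candidates covering
    fewer than 3 sensors have no defined velocity (``None``).
    """
    thr = thresholds or ClassificationThresholds()
    onsets = candidate.earliest_onsets()
    if len(onsets) < 3:
        return None
    x = np.array(sorted(onsets)) * sensor_spacing
    y = np.array([onsets[s] for s in sorted(onsets)])
    if np.ptp(y) == 0:
        return "simultaneous"
    lr = stats.linregress(x, y)
    p = lr.pvalue
    if not np.isfinite(p) or p >= thr.flat_fit_p:
        return "simultaneous"
    slope = stats.theilslopes(y, x).slope
    if slope == 0:
        return "simultaneous"
    velocity = -1.0 / slope  # positive = toward P1 = antegrade
    if abs(velocity) > thr.simultaneity_velocity:
        return "simultaneous"
    return float(velocity)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _median_duration(members: list[Transient]) -> float:
    return float(np.median([t.duration_s for t in members]))


def _build_event(
    kind: str, members: list[Transient], velocity, sensor_spacing: float
) -> ClassifiedEvent:
    sensors = sorted({t.sensor_index for t in members})
    return ClassifiedEvent(
        kind=kind,
        members=members,
        onset_s=min(t.onset_s for t in members),
        duration_s=_median_duration(members),
        span_cm=(sensors[-1] - sensors[0]) * sensor_spacing,
        velocity=velocity,
        amplitude_mean=float(np.mean([t.amplitude for t in members])),
        amplitude_max=float(max(t.amplitude for t in members)),
    )


def classify_candidate(
    candidate: EventCandidate,
    velocity: float | str | None,
    thresholds: ClassificationThresholds | None = None,
    sensor_spacing: float = 1.0,
) -> list[ClassifiedEvent]:
    """Apply the classification decision order to one candidate.

    (1) a single-sensor candidate is an isolated transient; (2) >= 3 sensors
    at HAPW amplitude with a measurable velocity -> HAPW; (3) simultaneous,
    long and wide enough -> SPW; (4) measurable velocity over >= 3 adjacent
    sensors -> APW (antegrade) or RPW (retrograde); (5) anything else falls
    back to per-sensor isolated transients.  The order makes the classes
    mutually exclusive and exhaustive.
    """
    thr = thresholds or ClassificationThresholds()
    members = candidate.members
    sensors = candidate.sensors
    if len(sensors) == 1:
        return [_build_event("isolated_transient", [t], None, sensor_spacing) for t in members]

    peak_by_sensor: dict[int, float] = {}
    for t in members:
        peak_by_sensor[t.sensor_index] = max(
            peak_by_sensor.get(t.sensor_index, 0.0), t.amplitude
        )
    n_high = sum(1 for a in peak_by_sensor.values() if a >= thr.hapw_amplitude)
    if n_high >= thr.hapw_min_sensors and isinstance(velocity, float):
        return [_build_event("HAPW", members, velocity, sensor_spacing)]

    duration = _median_duration(members)
    span_cm = (sensors[-1] - sensors[0]) * sensor_spacing
    if (
        velocity == "simultaneous"
        and duration >= thr.min_spw_duration_s
        and span_cm >= thr.min_spw_span_cm
    ):
        return [_build_event("SPW", members, "simultaneous", sensor_spacing)]

    if isinstance(velocity, float) and len(sensors) >= thr.apw_min_sensors:
        kind = "APW" if velocity > 0 else "RPW"
        return [_build_event(kind, members, velocity, sensor_spacing)]

    return [_build_event("isolated_transient", [t], None, sensor_spacing) for t in members]


def event_parameters(
    event: ClassifiedEvent,
    recording: Recording,
    thresholds: ClassificationThresholds | None = None,
    detrended: np.ndarray | None = None,
) -> ClassifiedEvent:
    """Fill the amplitude fields measured at the event's temporal centre.

    The mean amplitude is the pressure above baseline at the centre of the
    event, averaged over member sensors — the automated version of placing a
    cursor at the wave's centre and averaging across sensors.
    """
    thr = thresholds or ClassificationThresholds()
    if detrended is None:
        detrended = detrend_matrix(recording, thr)
    centre = 0.5 * (event.onset_s + event.offset_s)
    idx = min(recording.n_samples - 1, max(0, round(centre * recording.sampling_rate)))
    sensors = sorted({t.sensor_index for t in event.members})
    event.amplitude_mean = float(np.mean([detrended[s - 1, idx] for s in sensors]))
    event.amplitude_max = float(max(t.amplitude for t in event.members))
    event.duration_s = _median_duration(event.members)
    event.span_cm = (sensors[-1] - sensors[0]) * recording.sensor_spacing
    return event


# ---------------------------------------------------------------------------
# Physiological associations
# ---------------------------------------------------------------------------


def _local_tone(trace: np.ndarray, fs: float, onset_s: float, window_s: float) -> float:
    """Resting tone just before an event: a high percentile of the preceding
    window, robust to relaxation dips that can occupy much of the window
    when waves arrive rhythmically."""
    i1 = max(0, round((onset_s - 5.0) * fs))
    i0 = max(0, round((onset_s - window_s) * fs))
    if i1 <= i0:
        return float(trace[0])
    return float(np.nanpercentile(trace[i0:i1], 75))


def sphincter_association(
    events: list[ClassifiedEvent],
    recording: Recording,
    thresholds: ClassificationThresholds | None = None,
) -> list[ClassifiedEvent]:
    """Mark SPWs whose arrival coincides with internal-anal-sphincter relaxation.

    ``yes`` when sphincter pressure falls at least 20% below its local
    resting tone inside ``[onset - 5 s, offset]``; ``undetermined`` when no
    pull-back phase or tonically active channel exists.
    """
    thr = thresholds or ClassificationThresholds()
    channels, phase = sphincter_channels(recording)
    fs = recording.sampling_rate
    for ev in events:
        if ev.kind != "SPW":
            continue
        if not channels or phase is None or not phase.contains(ev.onset_s):
            ev.sphincter_relaxation = "undetermined"
            continue
        relaxed = False
        for s in channels:
            trace = recording.pressures[s - 1]
            tone = _local_tone(trace, fs, ev.onset_s, thr.sphincter_tone_window_s)
            sl = recording.sample_slice(ev.onset_s - 5.0, ev.offset_s)
            seg = trace[sl]
            if len(seg) and np.nanmin(seg) <= (1 - thr.sphincter_relaxation_frac) * tone:
                relaxed = True
                break
        ev.sphincter_relaxation = "yes" if relaxed else "no"
    return events


def gas_association(
    events: list[ClassifiedEvent],
    log: AnnotationLog | None,
    window_s: float = 10.0,
) -> dict:
    """Flag SPWs near gas-expulsion annotations, and the converse check.

    Returns fractions: (a) SPWs that were gas-associated, (b) gas
    annotations that coincided with an SPW — in the characterised sessions
    every reported gas expulsion had a matching SPW.
    """
    spws = [e for e in events if e.kind == "SPW"]
    gas_times = [a.time_s for a in log.of_kind("gas_expulsion")] if log else []
    matched_gas = 0
    for ev in spws:
        ev.gas_associated = any(
            ev.onset_s - window_s <= t <= ev.offset_s + window_s for t in gas_times
        )
    for t in gas_times:
        if any(e.onset_s - window_s <= t <= e.offset_s + window_s for e in spws):
            matched_gas += 1
    return {
        "n_spw": len(spws),
        "n_gas_annotations": len(gas_times),
        "frac_spws_gas_associated": (
            sum(e.gas_associated for e in spws) / len(spws) if spws else float("nan")
        ),
        "frac_gas_with_spw": matched_gas / len(gas_times) if gas_times else float("nan"),
    }


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def detect_events(
    recording: Recording,
    thresholds: ClassificationThresholds | None = None,
    annotations: AnnotationLog | None = None,
    artifact_mode: str = "both",
) -> DetectionResult:
    """Run the full detection pipeline on one recording.

    ``artifact_mode`` selects the artifact defence: ``annotations`` masks
    time around logged coughs/talking/body shifts, ``signal`` screens
    global simultaneous pressurizations with the sphincter/morphology rule,
    ``both`` (default) applies the two, ``none`` disables screening.
    """
    from .artifacts import (
        classify_global_pressurization,
        exclusion_mask,
        screen_annotations,
    )

    thr = thresholds or ClassificationThresholds()
    intervals = []
    if annotations is not None and artifact_mode in ("annotations", "both"):
        intervals = screen_annotations(annotations)
    mask = exclusion_mask(recording, intervals)
    detrended = detrend_matrix(recording, thr)
    per_sensor = detect_transients(recording, thr, mask=mask, detrended=detrended)
    candidates = group_transients(per_sensor, thr)

    n_functional = len(recording.functional_sensors())
    events: list[ClassifiedEvent] = []
    artifacts = list(intervals)
    for cand in candidates:
        velocity = estimate_velocity(cand, recording.sensor_spacing, thr)
        if (
            artifact_mode in ("signal", "both")
            and velocity == "simultaneous"
            and len(cand.sensors) >= 0.5 * n_functional
        ):
            verdict = classify_global_pressurization(cand, recording, thr)
            if verdict == "abdominal":
                from .artifacts import ArtifactInterval

                artifacts.append(
                    ArtifactInterval(
                        cand.onset_s, cand.offset_s, "body_shift", source="signal",
                        confidence=0.5,
                    )
                )
                continue
        for ev in classify_candidate(cand, velocity, thr, recording.sensor_spacing):
            events.append(event_parameters(ev, recording, thr, detrended=detrended))

    events.sort(key=lambda e: e.onset_s)
    sphincter_association(events, recording, thr)
    gas_summary = gas_association(events, annotations, thr.gas_window_s)
    return DetectionResult(
        events=events,
        transients=per_sensor,
        mask=mask,
        artifacts=artifacts,
        gas_summary=gas_summary,
    )


def events_to_frame(events: list[ClassifiedEvent]) -> pd.DataFrame:
    """Tabulate classified events (one row per event)."""
    rows = []
    for e in events:
        rows.append(
            {
                "kind": e.kind,
                "onset_s": round(e.onset_s, 3),
                "duration_s": round(e.duration_s, 3),
                "span_cm": e.span_cm,
                "velocity": e.velocity if isinstance(e.velocity, str) else (
                    round(e.velocity, 3) if e.velocity is not None else ""
                ),
                "amplitude_mean": round(e.amplitude_mean, 2),
                "amplitude_max": round(e.amplitude_max, 2),
                "first_sensor": e.first_sensor,
                "last_sensor": e.last_sensor,
                "sphincter_relaxation": e.sphincter_relaxation,
                "gas_associated": e.gas_associated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "kind",
            "onset_s",
            "duration_s",
            "span_cm",
            "velocity",
            "amplitude_mean",
            "amplitude_max",
            "first_sensor",
            "last_sensor",
            "sphincter_relaxation",
            "gas_associated",
        ],
    )
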