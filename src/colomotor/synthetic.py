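"""Ground-truthed synthetic high-resolution colonic manometry recordings.

The generator emulates the repertoire of colonic intraluminal pressure
patterns seen on a 36-sensor, 1-cm probe: rhythmic simultaneous pressure
waves (SPWs) with a fast ~8 s rise to ~20 mmHg and a slower ~12 s irregular
return with superimposed peaks; antegrade/retrograde propagating waves;
high-amplitude propagating waves; isolated single-sensor transients
(5-230 mmHg); rhythmic haustral-boundary transients at sensors 3-8 cm apart
(~3 cycles/min); intrahaustral activity alternating between erratic
segmentation and synchronized haustral pressure waves (~3 cycles/min,
~2 cm/s); abdominal-pressure artifacts (cough, body shift, talk, drink);
and an internal-anal-sphincter channel whose resting tone relaxes ahead of
arriving SPWs but pressurizes during artifacts.

Every injected event is recorded in a ground-truth list so detection and
classification can be benchmarked without patient data.  Output is
bit-exact reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import ClassVar

import numpy as np
import yaml

from .recording_io import Annotation, AnnotationLog, PhaseWindow, Recording

__all__ = [
    "SphincterSpec",
    "SPWTrainSpec",
    "PropagatingWaveSpec",
    "IsolatedTransientSpec",
    "HaustralBoundarySpec",
    "IntrahaustralSpec",
    "ArtifactSpec",
    "ScenarioConfig",
    "GroundTruthEvent",
    "spw_waveform",
    "pressure_pulse",
    "generate_recording",
    "scenario_from_yaml",
    "scenario_to_yaml",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SphincterSpec:
    """Internal anal sphincter behaviour during a pull-back phase.

    The sphincter occupies the most distal channel(s), holds ``resting_tone``
    mmHg, relaxes by ``relaxation_depth`` x tone starting ``relaxation_lead_s``
    seconds before an arriving SPW, and pressurizes by
    ``artifact_pressurization`` mmHg during coughs and body shifts.
    """

    resting_tone: float = 40.0
    relaxation_depth: float = 0.6
    relaxation_lead_s: float = 2.0
    artifact_pressurization: float = 15.0
    n_channels: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.relaxation_depth <= 1:
            raise ValueError("relaxation_depth must lie in (0, 1]")
        if self.relaxation_lead_s < 0:
            raise ValueError("relaxation_lead_s must be non-negative")


@dataclass
class SPWTrainSpec:
    """Rhythmic train of simultaneous pressure waves.

    Defaults follow the typical appearance: ~20 mmHg rise over ~8 s, ~12 s
    irregular decay with superimposed transients, spanning the full array,
    rhythmic at ~1 cycle/min.  ``gas_fraction`` of the waves are followed by
    a gas-expulsion annotation (9 of 32 in the characterised sessions).
    """

    kind: ClassVar[str] = "spw_train"
    rate_per_min: float = 1.0
    jitter_cv: float = 0.15
    amplitude: float = 20.0
    amplitude_cv: float = 0.15
    rise_s: float = 8.0
    decay_s: float = 12.0
    span: tuple[int, int] = (1, 36)
    with_superimposed: bool = True
    gas_fraction: float = 9 / 32
    times: list[float] | None = None

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class PropagatingWaveSpec:
    """Propagating pressure waves of fixed signed velocity.

    ``velocity`` is in cm/s, positive antegrade (toward the anus, decreasing
    sensor index), negative retrograde.  Amplitudes >= 100 mmHg over >= 3
    sensors produce high-amplitude propagating waves.
    """

    kind: ClassVar[str] = "propagating_wave"
    velocity: float = 5.0
    rate_per_min: float = 0.5
    jitter_cv: float = 1.0
    amplitude: float = 30.0
    amplitude_cv: float = 0.1
    span: tuple[int, int] = (10, 24)
    rise_s: float = 2.0
    decay_s: float = 5.0
    amplitude_profile: list[float] | None = None
    times: list[float] | None = None

    def __post_init__(self) -> None:
        if self.velocity == 0:
            raise ValueError("propagating waves need a non-zero velocity")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


@dataclass
class IsolatedTransientSpec:
    """Isolated single-sensor pressure transients.

    Amplitudes are log-normal (median ``amplitude_median``, shape
    ``amplitude_sigma``) clipped to ``amplitude_range``; the range observed
    clinically is 5-230 mmHg but no distribution is reported, so the
    log-normal is a documented modelling choice.
    """

    kind: ClassVar[str] = "isolated_transients"
    rate_per_min: float = 2.0
    sensors: list[int] | None = None
    amplitude_range: tuple[float, float] = (8.0, 230.0)
    amplitude_median: float = 30.0
    amplitude_sigma: float = 0.8
    duration_range: tuple[float, float] = (2.0, 6.0)
    events: list[tuple[float, int, float]] | None = None  # (time, sensor, amp)


@dataclass
class HaustralBoundarySpec:
    """Rhythmic isolated transients at haustral-boundary sensors.

    Boundary sensors are 3-8 cm apart with quiet sensors in between and a
    strikingly constant rhythm of ~3 cycles/min.
    """

    kind: ClassVar[str] = "haustral_boundaries"
    boundary_sensors: list[int] = field(default_factory=lambda: [11, 19, 27, 35])
    frequency_cpm: float = 3.0
    amplitude: float = 15.0
    amplitude_cv: float = 0.2
    jitter_cv: float = 0.1
    duration_s: float = 4.0

    def __post_init__(self) -> None:
        s = sorted(self.boundary_sensors)
        if any(b - a < 2 for a, b in zip(s, s[1:])):
            raise ValueError("haustral boundary sensors must be non-adjacent")


@dataclass
class IntrahaustralSpec:
    """Alternating segmentation / synchronized activity within one haustrum.

    ``schedule`` is a list of ``(state, duration_s)`` with state in
    {"segmentation", "synchronized", "quiescent"}.  Synchronized episodes are
    coherent cycles at ``frequency_cpm`` propagating at ``velocity`` cm/s
    (direction per cycle when ``direction='mixed'``); segmentation episodes
    carry independent per-sensor transients of erratic timing and amplitude.
    """

    kind: ClassVar[str] = "intrahaustral"
    sensor_window: tuple[int, int] = (28, 32)
    schedule: list[tuple[str, float]] = field(
        default_factory=lambda: [("segmentation", 300.0), ("synchronized", 240.0)]
    )
    frequency_cpm: float = 3.0
    velocity: float = 2.0
    direction: str = "mixed"  # antegrade | retrograde | mixed
    amplitude: float = 12.0
    start_s: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.sensor_window
        if not 2 <= hi - lo + 1 <= 5:
            raise ValueError("intrahaustral window must cover 2-5 adjacent sensors")


@dataclass
class ArtifactSpec:
    """Abdominal-pressure artifacts at explicit times."""

    kind: ClassVar[str] = "artifact"
    subtype: str = "cough"
    times: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.subtype not in ("cough", "body_shift", "talk", "drink"):
            raise ValueError(f"unknown artifact subtype {self.subtype!r}")


@dataclass
class ScenarioConfig:
    """Complete description of one synthetic session."""

    duration_s: float
    seed: int = 0
    sampling_rate: float = 10.0
    n_sensors: int = 36
    sensor_spacing: float = 1.0
    tip_position: float = 85.0
    noise_sd: float = 1.0
    baseline_tone: float = 5.0
    pattern_specs: list = field(default_factory=list)
    sphincter: SphincterSpec | None = None
    phases: list[PhaseWindow] = field(default_factory=list)
    rate_multipliers: dict[str, float] = field(default_factory=dict)
    subject_id: str = "synthetic"
    broken_sensors: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if any(m < 0 for m in self.rate_multipliers.values()):
            raise ValueError("rate multipliers must be non-negative")


@dataclass
class GroundTruthEvent:
    """One injected event, recorded exactly once, sorted by onset."""

    kind: str
    onset_s: float
    duration_s: float
    sensor_onsets: dict[int, float]
    amplitude: float
    span_sensors: tuple[int, int]
    velocity: float | str | None = None
    source: str | None = None
    frequency_cpm: float | None = None
    direction: str | None = None


# ---------------------------------------------------------------------------
# Waveform primitives
# ---------------------------------------------------------------------------


def spw_waveform(
    amplitude: float,
    rise_s: float,
    decay_s: float,
    sampling_rate: float = 10.0,
    with_superimposed: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Single-sensor SPW trace: smooth monotone rise, slower irregular decay.

    The rise is a raised cosine reaching ``amplitude`` exactly at ``rise_s``;
    the decay is a shifted exponential reaching zero at ``decay_s`` (below 5%
    of peak over its final stretch).  With ``with_superimposed``, 1-3 short
    transients ride on the early decay limb, capped below the peak.
    """
    if rise_s < 0 or decay_s < 0:
        raise ValueError("durations must be non-negative")
    fs = sampling_rate
    n_r = max(1, round(rise_s * fs))
    n_d = max(1, round(decay_s * fs))
    if amplitude == 0:
        return np.zeros(n_r + n_d + 1)
    t_r = np.arange(n_r + 1) / n_r
    rise = amplitude * 0.5 * (1 - np.cos(np.pi * t_r))
    t_d = np.arange(1, n_d + 1) / n_d
    k = 3.0
    decay = amplitude * (np.exp(-k * t_d) - np.exp(-k)) / (1 - np.exp(-k))
    if with_superimposed and rng is not None and decay_s > 2:
        n_bumps = int(rng.integers(1, 4))
        t_axis = t_d * decay_s
        for _ in range(n_bumps):
            centre = rng.uniform(0.1, 0.6) * decay_s  # early decay limb
            width = rng.uniform(0.4, 0.9)
            ci = int(round(centre * fs)) - 1
            ci = min(max(ci, 0), n_d - 1)
            headroom = amplitude - decay[ci]
            height = rng.uniform(0.2, 0.8) * headroom
            bump = height * np.exp(-0.5 * ((t_axis - centre) / width) ** 2)
            decay = np.minimum(decay + bump, 0.97 * amplitude)
    return np.concatenate([rise, decay])


def pressure_pulse(
    amplitude: float, rise_s: float, decay_s: float, sampling_rate: float
) -> np.ndarray:
    """Smooth asymmetric pulse (raised-cosine rise and fall), exact peak."""
    if rise_s < 0 or decay_s < 0:
        raise ValueError("durations must be non-negative")
    fs = sampling_rate
    n_r = max(1, round(rise_s * fs))
    n_d = max(1, round(decay_s * fs))
    rise = amplitude * 0.5 * (1 - np.cos(np.pi * np.arange(n_r + 1) / n_r))
    fall = amplitude * 0.5 * (1 + np.cos(np.pi * np.arange(1, n_d + 1) / n_d))
    return np.concatenate([rise, fall])


def _add_at(buffer: np.ndarray, sensor: int, start_sample: int, wave: np.ndarray) -> None:
    """Add ``wave`` to row ``sensor`` (1-based) starting at ``start_sample``."""
    n = buffer.shape[1]
    a = max(0, start_sample)
    b = min(n, start_sample + len(wave))
    if b <= a:
        return
    buffer[sensor - 1, a:b] += wave[a - start_sample : b - start_sample]


# ---------------------------------------------------------------------------
# Injectors
# ---------------------------------------------------------------------------


def inject_propagating_wave(
    buffer: np.ndarray,
    sampling_rate: float,
    sensor_spacing: float,
    onset_s: float,
    velocity: float | None,
    amplitudes: np.ndarray,
    span: tuple[int, int],
    ground_truth: list[GroundTruthEvent],
    rise_s: float = 2.0,
    decay_s: float = 5.0,
    kind: str = "APW",
    source: str | None = None,
) -> GroundTruthEvent:
    """Inject a (possibly simultaneous) multi-sensor wave.

    ``velocity`` in signed cm/s; positive = antegrade (the wave enters at the
    proximal end of the span and travels toward P1), negative = retrograde;
    ``None`` = simultaneous onsets on every sensor.  ``onset_s`` is the onset
    at the entry sensor.
    """
    lo, hi = span
    if lo < 1 or hi > buffer.shape[0] or lo > hi:
        raise ValueError(f"span {span} outside the sensor array")
    sensors = list(range(lo, hi + 1))
    amplitudes = np.broadcast_to(np.asarray(amplitudes, dtype=float), (len(sensors),))
    onsets: dict[int, float] = {}
    for i, s in enumerate(sensors):
        if velocity is None:
            t = onset_s
        elif velocity > 0:
            t = onset_s + (hi - s) * sensor_spacing / velocity
        else:
            t = onset_s + (s - lo) * sensor_spacing / abs(velocity)
        onsets[s] = t
        wave = pressure_pulse(amplitudes[i], rise_s, decay_s, sampling_rate)
        _add_at(buffer, s, round(t * sampling_rate), wave)
    gt = GroundTruthEvent(
        kind=kind,
        onset_s=min(onsets.values()),
        duration_s=rise_s + decay_s,
        sensor_onsets=onsets,
        amplitude=float(np.max(amplitudes)),
        span_sensors=(lo, hi),
        velocity="simultaneous" if velocity is None else float(velocity),
        source=source,
    )
    ground_truth.append(gt)
    return gt


def inject_spw(
    buffer: np.ndarray,
    sampling_rate: float,
    onset_s: float,
    amplitude: float,
    span: tuple[int, int],
    ground_truth: list[GroundTruthEvent],
    rng: np.random.Generator,
    rise_s: float = 8.0,
    decay_s: float = 12.0,
    amplitude_cv: float = 0.15,
    with_superimposed: bool = True,
    source: str = "spw_train",
) -> GroundTruthEvent:
    """Inject one simultaneous pressure wave across ``span``."""
    lo, hi = span
    if lo < 1 or hi > buffer.shape[0] or lo > hi:
        raise ValueError(f"span {span} outside the sensor array")
    onsets = {}
    start = round(onset_s * sampling_rate)
    for s in range(lo, hi + 1):
        amp = amplitude * max(0.3, 1 + amplitude_cv * rng.standard_normal())
        wave = spw_waveform(
            amp, rise_s, decay_s, sampling_rate, with_superimposed=with_superimposed, rng=rng
        )
        _add_at(buffer, s, start, wave)
        onsets[s] = onset_s
    gt = GroundTruthEvent(
        kind="SPW",
        onset_s=onset_s,
        duration_s=rise_s + decay_s,
        sensor_onsets=onsets,
        amplitude=amplitude,
        span_sensors=(lo, hi),
        velocity="simultaneous",
        source=source,
    )
    ground_truth.append(gt)
    return gt


def _jittered_times(
    rng: np.random.Generator,
    start: float,
    end: float,
    rate_per_min: float,
    jitter_cv: float,
    edge_pad: float = 10.0,
) -> list[float]:
    """Event times in [start+pad, end-pad) at the given mean rate.

    ``jitter_cv`` is the coefficient of variation of inter-event intervals:
    0 gives a strictly periodic train, 1 a Poisson-like train (gamma
    intervals are used throughout).
    """
    if rate_per_min <= 0:
        return []
    mean = 60.0 / rate_per_min
    times = []
    t = start + edge_pad + rng.uniform(0, mean)
    while t < end - edge_pad:
        times.append(t)
        if jitter_cv <= 0:
            t += mean
        else:
            shape = 1.0 / jitter_cv**2
            t += rng.gamma(shape, mean / shape)
    return times


def inject_haustral_rhythm(
    buffer: np.ndarray,
    sampling_rate: float,
    boundary_sensors: list[int],
    frequency_cpm: float,
    amplitude: float,
    jitter_cv: float,
    t_range: tuple[float, float],
    ground_truth: list[GroundTruthEvent],
    rng: np.random.Generator,
    amplitude_cv: float = 0.2,
    duration_s: float = 4.0,
) -> None:
    """Rhythmic isolated transients at boundary sensors, quiet in between."""
    s_sorted = sorted(boundary_sensors)
    if any(b - a < 2 for a, b in zip(s_sorted, s_sorted[1:])):
        raise ValueError("boundary sensors must be non-adjacent")
    if frequency_cpm <= 0:
        return
    start, end = t_range
    for s in boundary_sensors:
        for t in _jittered_times(rng, start, end, frequency_cpm, jitter_cv, edge_pad=5.0):
            amp = amplitude * max(0.3, 1 + amplitude_cv * rng.standard_normal())
            wave = pressure_pulse(amp, duration_s / 3, 2 * duration_s / 3, sampling_rate)
            _add_at(buffer, s, round(t * sampling_rate), wave)
            ground_truth.append(
                GroundTruthEvent(
                    kind="isolated_transient",
                    onset_s=t,
                    duration_s=duration_s,
                    sensor_onsets={s: t},
                    amplitude=amp,
                    span_sensors=(s, s),
                    source="haustral_boundary",
                    frequency_cpm=frequency_cpm,
                )
            )


def inject_intrahaustral(
    buffer: np.ndarray,
    sampling_rate: float,
    sensor_spacing: float,
    spec: IntrahaustralSpec,
    ground_truth: list[GroundTruthEvent],
    rng: np.random.Generator,
) -> None:
    """Alternating segmentation / synchronized episodes in one haustrum."""
    lo, hi = spec.sensor_window
    if hi > buffer.shape[0]:
        raise ValueError("intrahaustral window outside the sensor array")
    sensors = list(range(lo, hi + 1))
    t = spec.start_s
    period = 60.0 / spec.frequency_cpm if spec.frequency_cpm > 0 else np.inf
    for state, dur in spec.schedule:
        if state == "synchronized":
            lag = sensor_spacing / spec.velocity if spec.velocity else 0.0
            cycle = t + period / 2
            dirs = []
            while cycle + period / 2 <= t + dur:
                if spec.direction == "mixed":
                    sign = 1 if rng.random() < 0.5 else -1
                else:
                    sign = 1 if spec.direction == "antegrade" else -1
                dirs.append(sign)
                pulse_dur = min(10.0, 0.6 * period)
                for s in sensors:
                    # antegrade: wave arrives first proximally, travels to P1
                    order = (hi - s) if sign > 0 else (s - lo)
                    t_s = cycle + order * lag
                    amp = spec.amplitude * max(0.4, 1 + 0.15 * rng.standard_normal())
                    wave = pressure_pulse(
                        amp, pulse_dur / 2, pulse_dur / 2, sampling_rate
                    )
                    _add_at(buffer, s, round(t_s * sampling_rate), wave)
                cycle += period
            agree = np.mean([d > 0 for d in dirs]) if dirs else 0.5
            direction = (
                "antegrade" if agree >= 0.7 else "retrograde" if agree <= 0.3 else "mixed"
            )
            ground_truth.append(
                GroundTruthEvent(
                    kind="synchronized_episode",
                    onset_s=t,
                    duration_s=dur,
                    sensor_onsets={s: t for s in sensors},
                    amplitude=spec.amplitude,
                    span_sensors=(lo, hi),
                    velocity=abs(spec.velocity),
                    source="intrahaustral",
                    frequency_cpm=spec.frequency_cpm,
                    direction=direction,
                )
            )
        elif state == "segmentation":
            for s in sensors:
                rate = rng.uniform(2.0, 5.0)  # erratic, sensor-specific rate
                for ts in _jittered_times(rng, t, t + dur, rate, 1.0, edge_pad=2.0):
                    amp = spec.amplitude * rng.uniform(0.5, 2.5)
                    d = rng.uniform(2.0, 5.0)
                    wave = pressure_pulse(amp, d / 2, d / 2, sampling_rate)
                    _add_at(buffer, s, round(ts * sampling_rate), wave)
            ground_truth.append(
                GroundTruthEvent(
                    kind="segmentation_episode",
                    onset_s=t,
                    duration_s=dur,
                    sensor_onsets={s: t for s in sensors},
                    amplitude=spec.amplitude,
                    span_sensors=(lo, hi),
                    source="intrahaustral",
                )
            )
        elif state == "quiescent":
            ground_truth.append(
                GroundTruthEvent(
                    kind="quiescent_episode",
                    onset_s=t,
                    duration_s=dur,
                    sensor_onsets={},
                    amplitude=0.0,
                    span_sensors=(lo, hi),
                    source="intrahaustral",
                )
            )
        else:
            raise ValueError(f"unknown intrahaustral state {state!r}")
        t += dur


_ARTIFACT_PARAMS = {
    # (duration range s, amplitude range mmHg)
    "cough": ((0.6, 1.2), (25.0, 60.0)),
    "body_shift": ((5.0, 10.0), (3.0, 5.0)),
    "talk": ((2.0, 4.0), (5.0, 5.0)),
    "drink": ((1.5, 3.0), (10.0, 10.0)),
}


def inject_artifact(
    buffer: np.ndarray,
    sampling_rate: float,
    subtype: str,
    time_s: float,
    ground_truth: list[GroundTruthEvent],
    annotations: list[Annotation],
    rng: np.random.Generator,
    sphincter_channels: list[int] = (),
    sphincter: SphincterSpec | None = None,
) -> None:
    """Inject one abdominal-pressure artifact plus its annotation.

    Coughs are short sharp all-sensor spikes; body shifts broad low-amplitude
    elevations with sustained single-sensor offsets; talking ~5 mmHg;
    drinking ~10 mmHg.  Cough and body shift pressurize the sphincter
    channel rather than relaxing it.
    """
    if subtype not in _ARTIFACT_PARAMS:
        raise ValueError(f"unknown artifact kind {subtype!r}")
    (d_lo, d_hi), (a_lo, a_hi) = _ARTIFACT_PARAMS[subtype]
    dur = rng.uniform(d_lo, d_hi)
    amp = rng.uniform(a_lo, a_hi)
    n_sensors = buffer.shape[0]
    start = round(time_s * sampling_rate)
    rise = 0.15 if subtype == "cough" else dur / 3
    for s in range(1, n_sensors + 1):
        a_s = amp * (1 + 0.05 * rng.standard_normal())
        wave = pressure_pulse(max(a_s, 0.5), rise, dur - rise, sampling_rate)
        _add_at(buffer, s, start, wave)
    onsets = {s: time_s for s in range(1, n_sensors + 1)}
    if subtype == "body_shift":
        # sustained non-rhythmic offsets at a few single sensors
        for s in rng.choice(np.arange(1, n_sensors + 1), rng.integers(1, 4), replace=False):
            hold = rng.uniform(20.0, 40.0)
            off = rng.uniform(8.0, 15.0)
            wave = pressure_pulse(off, 2.0, hold - 2.0, sampling_rate)
            _add_at(buffer, int(s), start, wave)
    if sphincter is not None and subtype in ("cough", "body_shift"):
        for s in sphincter_channels:
            wave = pressure_pulse(
                sphincter.artifact_pressurization, rise, dur - rise, sampling_rate
            )
            _add_at(buffer, s, start, wave)
    ground_truth.append(
        GroundTruthEvent(
            kind=f"artifact_{subtype}",
            onset_s=time_s,
            duration_s=dur,
            sensor_onsets=onsets,
            amplitude=amp,
            span_sensors=(1, n_sensors),
            velocity="simultaneous",
            source="artifact",
        )
    )
    annotations.append(Annotation(time_s, subtype, "synthetic artifact"))


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def _phase_blocks(config: ScenarioConfig) -> list[tuple[float, float, float]]:
    """(start, end, rate multiplier) blocks covering the recording."""
    if not config.phases:
        return [(0.0, config.duration_s, 1.0)]
    return [
        (p.start_s, p.end_s, config.rate_multipliers.get(p.label, 1.0))
        for p in config.phases
        if p.label != "sphincter_pullback" or len(config.phases) == 1
    ] or [(0.0, config.duration_s, 1.0)]


def _scheduled(rng, config, rate_per_min, jitter_cv) -> list[float]:
    times = []
    for start, end, mult in _phase_blocks(config):
        times.extend(_jittered_times(rng, start, end, rate_per_min * mult, jitter_cv))
    return sorted(times)


def generate_recording(
    config: ScenarioConfig,
) -> tuple[Recording, list[GroundTruthEvent], AnnotationLog]:
    """Build one synthetic session from a scenario.

    Returns the recording, the ground-truth event list (sorted by onset) and
    the annotation log.  Deterministic and bit-exact for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate
    n_samples = round(config.duration_s * fs)
    if config.noise_sd > 0:
        buffer = rng.normal(0.0, config.noise_sd, size=(config.n_sensors, n_samples))
    else:
        buffer = np.zeros((config.n_sensors, n_samples))
    buffer += config.baseline_tone

    phases = list(config.phases) or [PhaseWindow("baseline", 0.0, config.duration_s)]
    pullback = next((p for p in phases if p.label == "sphincter_pullback"), None)
    sph = config.sphincter
    sph_channels: list[int] = []
    if sph is not None and pullback is not None:
        sph_channels = list(range(1, sph.n_channels + 1))
        sl = slice(
            round(pullback.start_s * fs), min(n_samples, round(pullback.end_s * fs))
        )
        ramp = np.ones(sl.stop - sl.start)
        n_ramp = min(len(ramp) // 2, round(2 * fs))
        if n_ramp > 0:
            edge = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
            ramp[:n_ramp] = edge
            ramp[-n_ramp:] = edge[::-1]
        for s in sph_channels:
            buffer[s - 1, sl] += sph.resting_tone * ramp

    ground_truth: list[GroundTruthEvent] = []
    annotations: list[Annotation] = []

    for spec in config.pattern_specs:
        if isinstance(spec, SPWTrainSpec):
            times = spec.times or _scheduled(rng, config, spec.rate_per_min, spec.jitter_cv)
            gas_idx: set[int] = set()
            if times and spec.gas_fraction > 0:
                n_gas = round(spec.gas_fraction * len(times))
                gas_idx = set(
                    rng.choice(len(times), size=min(n_gas, len(times)), replace=False)
                )
            for i, t in enumerate(times):
                span = spec.span
                in_pullback = pullback is not None and pullback.contains(t)
                if sph_channels and in_pullback:
                    # the colonic wave stops short of the sphincter channels
                    span = (max(span[0], sph_channels[-1] + 1), span[1])
                amp = spec.amplitude * max(0.3, 1 + spec.amplitude_cv * rng.standard_normal())
                inject_spw(
                    buffer,
                    fs,
                    t,
                    amp,
                    span,
                    ground_truth,
                    rng,
                    rise_s=spec.rise_s,
                    decay_s=spec.decay_s,
                    amplitude_cv=0.1,
                    with_superimposed=spec.with_superimposed,
                )
                if sph is not None and sph_channels and in_pullback:
                    # relaxation precedes the arriving wave
                    t0 = t - sph.relaxation_lead_s
                    d = sph.relaxation_lead_s + spec.rise_s + spec.decay_s
                    dip = pressure_pulse(
                        sph.relaxation_depth * sph.resting_tone, d / 3, 2 * d / 3, fs
                    )
                    for s in sph_channels:
                        _add_at(buffer, s, round(t0 * fs), -dip)
                if i in gas_idx:
                    annotations.append(
                        Annotation(t + spec.rise_s, "gas_expulsion", "synthetic")
                    )
        elif isinstance(spec, PropagatingWaveSpec):
            times = spec.times or _scheduled(rng, config, spec.rate_per_min, spec.jitter_cv)
            lo, hi = spec.span
            for t in times:
                if spec.amplitude_profile is not None:
                    amps = np.asarray(spec.amplitude_profile, dtype=float)
                else:
                    amps = spec.amplitude * np.clip(
                        1 + spec.amplitude_cv * rng.standard_normal(hi - lo + 1), 0.3, None
                    )
                kind = (
                    "HAPW"
                    if int(np.sum(amps >= 100.0)) >= 3
                    else ("APW" if spec.velocity > 0 else "RPW")
                )
                inject_propagating_wave(
                    buffer,
                    fs,
                    config.sensor_spacing,
                    t,
                    spec.velocity,
                    amps,
                    spec.span,
                    ground_truth,
                    rise_s=spec.rise_s,
                    decay_s=spec.decay_s,
                    kind=kind,
                )
        elif isinstance(spec, IsolatedTransientSpec):
            if spec.events is not None:
                events = spec.events
            else:
                sensors = spec.sensors or list(range(1, config.n_sensors + 1))
                events = []
                for t in _scheduled(rng, config, spec.rate_per_min, 1.0):
                    s = int(rng.choice(sensors))
                    amp = float(
                        np.clip(
                            spec.amplitude_median
                            * np.exp(spec.amplitude_sigma * rng.standard_normal()),
                            *spec.amplitude_range,
                        )
                    )
                    events.append((t, s, amp))
            for t, s, amp in events:
                d = rng.uniform(*spec.duration_range)
                wave = pressure_pulse(amp, d / 3, 2 * d / 3, fs)
                _add_at(buffer, s, round(t * fs), wave)
                ground_truth.append(
                    GroundTruthEvent(
                        kind="isolated_transient",
                        onset_s=t,
                        duration_s=d,
                        sensor_onsets={s: t},
                        amplitude=amp,
                        span_sensors=(s, s),
                        source="isolated",
                    )
                )
        elif isinstance(spec, HaustralBoundarySpec):
            inject_haustral_rhythm(
                buffer,
                fs,
                spec.boundary_sensors,
                spec.frequency_cpm,
                spec.amplitude,
                spec.jitter_cv,
                (0.0, config.duration_s),
                ground_truth,
                rng,
                amplitude_cv=spec.amplitude_cv,
                duration_s=spec.duration_s,
            )
        elif isinstance(spec, IntrahaustralSpec):
            inject_intrahaustral(
                buffer, fs, config.sensor_spacing, spec, ground_truth, rng
            )
        elif isinstance(spec, ArtifactSpec):
            for t in spec.times:
                inject_artifact(
                    buffer,
                    fs,
                    spec.subtype,
                    t,
                    ground_truth,
                    annotations,
                    rng,
                    sphincter_channels=sph_channels,
                    sphincter=sph,
                )
        else:
            raise TypeError(f"unknown pattern spec {type(spec).__name__}")

    mask = np.ones(config.n_sensors, dtype=bool)
    for s in config.broken_sensors:
        mask[s - 1] = False
        buffer[s - 1, :] = np.nan

    recording = Recording(
        pressures=buffer,
        sampling_rate=fs,
        sensor_spacing=config.sensor_spacing,
        tip_position=config.tip_position,
        functional_mask=mask,
        phases=phases,
        subject_id=config.subject_id,
        group="synthetic",
    )
    ground_truth.sort(key=lambda e: e.onset_s)
    return recording, ground_truth, AnnotationLog(annotations)


# ---------------------------------------------------------------------------
# Scenario serialisation
# ---------------------------------------------------------------------------

_SPEC_REGISTRY = {
    "spw_train": SPWTrainSpec,
    "propagating_wave": PropagatingWaveSpec,
    "isolated_transients": IsolatedTransientSpec,
    "haustral_boundaries": HaustralBoundarySpec,
    "intrahaustral": IntrahaustralSpec,
    "artifact": ArtifactSpec,
}


def _despan(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        out[k] = v
    return out


def scenario_to_yaml(config: ScenarioConfig, path) -> None:
    data = asdict(config)
    data["pattern_specs"] = [
        {"kind": type(s).kind, **_despan(asdict(s))} for s in config.pattern_specs
    ]
    data["phases"] = [
        {"label": p.label, "start_s": p.start_s, "end_s": p.end_s} for p in config.phases
    ]
    if config.sphincter is not None:
        data["sphincter"] = asdict(config.sphincter)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def _retuple(cls, kwargs: dict) -> dict:
    tuple_fields = {"span", "sensor_window", "amplitude_range", "duration_range"}
    out = {}
    for k, v in kwargs.items():
        if k in tuple_fields and isinstance(v, list):
            v = tuple(v)
        if k == "schedule" and isinstance(v, list):
            v = [tuple(item) for item in v]
        out[k] = v
    return out


def scenario_from_yaml(path) -> ScenarioConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    specs = []
    for entry in data.get("pattern_specs", []):
        entry = dict(entry)
        kind = entry.pop("kind")
        cls = _SPEC_REGISTRY[kind]
        specs.append(cls(**_retuple(cls, entry)))
    data["pattern_specs"] = specs
    data["phases"] = [PhaseWindow(**p) for p in data.get("phases", [])]
    if data.get("sphincter"):
        data["sphincter"] = SphincterSpec(**data["sphincter"])
    return ScenarioConfig(**data)


def write_ground_truth(events: list[GroundTruthEvent], path) -> None:
    """Write ground-truth events as a TSV (onset-sorted, one row each)."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append(
            {
                "kind": e.kind,
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "amplitude": e.amplitude,
                "first_sensor": e.span_sensors[0],
                "last_sensor": e.span_sensors[1],
                "velocity": e.velocity,
                "source": e.source,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
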