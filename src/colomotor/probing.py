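"""Black-box recovery of the classifier's operating constants.

These helpers verify an analysis configuration by probing the detection
pipeline from the outside: controlled noise-free waveforms are synthesised
(independently of the scenario generator), pushed through
:func:`colomotor.detection.detect_events`, and the decision boundaries are
located by bisection.  A correctly configured pipeline recovers the
clinical constants — 5 mmHg minimum amplitude, 2.5 s minimum simultaneous-
wave duration, the 7 cm/s velocity resolution bound, the 100 mmHg
high-amplitude boundary and the 3-sensor high-amplitude minimum.
"""

from __future__ import annotations

import numpy as np

from .detection import ClassificationThresholds, detect_events
from .recording_io import Recording

__all__ = [
    "recover_min_amplitude",
    "recover_min_spw_duration",
    "recover_velocity_boundary",
    "recover_hapw_amplitude",
    "recover_hapw_min_sensors",
    "full_array_span_cm",
]


def _flat_recording(
    n_sensors: int = 36, duration_s: float = 120.0, sampling_rate: float = 10.0
) -> Recording:
    n = round(duration_s * sampling_rate)
    return Recording(
        pressures=np.zeros((n_sensors, n)),
        sampling_rate=sampling_rate,
        subject_id="probe",
    )


def _trapezoid(
    amplitude: float, measured_s: float, sampling_rate: float, ramp_s: float = 1.2
) -> np.ndarray:
    """Flat-top pulse whose 25%-of-peak width equals ``measured_s`` exactly.

    The linear ramps are long relative to the detector's smoothing kernel,
    whose moving average leaves the interior of a linear ramp unchanged, so
    the 25% crossings stay where they are constructed.
    """
    plateau = max(0.0, measured_s - 1.5 * ramp_s)
    n_r = max(1, round(ramp_s * sampling_rate))
    n_p = round(plateau * sampling_rate)
    ramp = amplitude * np.arange(1, n_r + 1) / n_r
    # the ramp ends at the peak; start the descent one step below it so the
    # peak sample is not duplicated (which would widen the pulse by 1/fs)
    return np.concatenate([ramp, np.full(n_p, amplitude), ramp[-2::-1]])


def _add(rec: Recording, sensor: int, t: float, wave: np.ndarray) -> None:
    i = round(t * rec.sampling_rate)
    j = min(rec.n_samples, i + len(wave))
    rec.pressures[sensor - 1, i:j] += wave[: j - i]


def _event_kinds(rec: Recording) -> list[str]:
    return [e.kind for e in detect_events(rec, artifact_mode="none").events]


def _bisect(predicate, lo: float, hi: float, tol: float) -> float:
    """Smallest x in [lo, hi] with predicate(x) true (predicate monotone)."""
    if not predicate(hi) or predicate(lo):
        raise RuntimeError("bisection bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def recover_min_amplitude(tol: float = 0.02) -> float:
    """Smallest amplitude (mmHg) at which a transient is detected at all."""

    def detected(amp: float) -> bool:
        rec = _flat_recording()
        wave = _trapezoid(amp, 10.0, rec.sampling_rate)
        for s in range(1, rec.n_sensors + 1):
            _add(rec, s, 50.0, wave)
        return len(_event_kinds(rec)) > 0

    return _bisect(detected, 2.0, 10.0, tol)


def recover_min_spw_duration(tol: float = 0.02) -> float:
    """Shortest simultaneous full-array wave still classified as an SPW."""

    def is_spw(duration: float) -> bool:
        rec = _flat_recording(sampling_rate=20.0)
        wave = _trapezoid(20.0, duration, rec.sampling_rate)
        for s in range(1, rec.n_sensors + 1):
            _add(rec, s, 50.0, wave)
        return "SPW" in _event_kinds(rec)

    return _bisect(is_spw, 1.0, 5.0, tol)


def recover_velocity_boundary(tol: float = 0.02) -> float:
    """Velocity above which a full-array propagating wave becomes an SPW."""

    def is_spw(velocity: float) -> bool:
        rec = _flat_recording(duration_s=180.0, sampling_rate=20.0)
        wave = _trapezoid(30.0, 6.0, rec.sampling_rate)
        for s in range(1, rec.n_sensors + 1):
            # antegrade: the wave enters proximally and travels toward P1
            _add(rec, s, 60.0 + (rec.n_sensors - s) * rec.sensor_spacing / velocity, wave)
        kinds = _event_kinds(rec)
        return "SPW" in kinds and "APW" not in kinds

    return _bisect(is_spw, 4.0, 10.0, tol)


def recover_hapw_amplitude(tol: float = 0.1) -> float:
    """Amplitude at which a propagating wave becomes high-amplitude (HAPW)."""

    def is_hapw(amplitude: float) -> bool:
        rec = _flat_recording(duration_s=180.0)
        wave = _trapezoid(amplitude, 8.0, rec.sampling_rate)
        for s in range(10, 22):
            _add(rec, s, 60.0 + (21 - s) / 2.0, wave)  # 2 cm/s antegrade
        return "HAPW" in _event_kinds(rec)

    return _bisect(is_hapw, 60.0, 140.0, tol)


def recover_hapw_min_sensors(max_k: int = 6) -> int:
    """Minimum number of >= 100 mmHg sensors that makes a wave an HAPW."""
    for k in range(1, max_k + 1):
        rec = _flat_recording(duration_s=180.0)
        for i, s in enumerate(range(10, 22)):
            amp = 120.0 if i < k else 60.0
            wave = _trapezoid(amp, 8.0, rec.sampling_rate)
            _add(rec, s, 60.0 + (21 - s) / 2.0, wave)
        if "HAPW" in _event_kinds(rec):
            return k
    raise RuntimeError("no sensor count produced an HAPW")


def full_array_span_cm() -> float:
    """Propagation distance reported for a wave covering all 36 sensors."""
    rec = _flat_recording()
    wave = _trapezoid(20.0, 15.0, rec.sampling_rate)
    for s in range(1, rec.n_sensors + 1):
        _add(rec, s, 50.0, wave)
    events = detect_events(rec, artifact_mode="none").events
    spws = [e for e in events if e.kind == "SPW"]
    if not spws:
        raise RuntimeError("full-array probe produced no SPW")
    return spws[0].span_cm
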