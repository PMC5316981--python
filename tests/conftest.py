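import numpy as np
import pytest

from colomotor.detection import ClassificationThresholds
from colomotor.recording_io import Recording


@pytest.fixture
def thresholds():
    return ClassificationThresholds()


def make_recording(n_sensors=36, duration_s=120.0, fs=10.0, tone=0.0, **kwargs) -> Recording:
    """Flat noise-free recording to draw test waveforms on."""
    n = round(duration_s * fs)
    return Recording(
        pressures=np.full((n_sensors, n), float(tone)),
        sampling_rate=fs,
        **kwargs,
    )


def add_pulse(rec: Recording, sensor: int, t: float, amplitude: float, duration_s: float):
    """Add a flat-top pulse (0.4 s ramps) at ``t`` on a 1-based sensor."""
    fs = rec.sampling_rate
    n_r = max(1, round(0.4 * fs))
    n_p = max(0, round(duration_s * fs) - 2 * n_r)
    ramp = amplitude * np.arange(1, n_r + 1) / n_r
    wave = np.concatenate([ramp, np.full(n_p, amplitude), ramp[-2::-1]])
    i = round(t * fs)
    j = min(rec.n_samples, i + len(wave))
    rec.pressures[sensor - 1, i:j] += wave[: j - i]


@pytest.fixture
def recording_factory():
    return make_recording
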