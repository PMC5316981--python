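"""Screening of abdominal-pressure artifacts.

Rises in intraluminal pressure caused by abdominal pressure (coughing, body
shifts, talking, drinking) must never be classified as colonic motor
patterns.  Two complementary defences are provided:

* **annotation screening** — contemporaneous observer annotations are
  expanded into exclusion intervals (the clinical practice); gas expulsion
  is *not* an artifact, it accompanies simultaneous pressure waves;
* **signal screening** — a global simultaneous pressurization is abdominal
  when the internal anal sphincter pressurizes with it, and colonic when
  the sphincter relaxes at or before the wave's arrival; without a
  sphincter channel a cough-morphology rule (very short, very sharp) is
  applied.  The signal rule extends the annotation-based practice to
  unannotated data.

Talking (~5 mmHg) and drinking (~10 mmHg) signatures are too weakly
characterised for automatic detection and are handled via annotations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording_io import AnnotationLog, Recording, sphincter_channels

__all__ = [
    "ArtifactInterval",
    "screen_annotations",
    "classify_global_pressurization",
    "exclusion_mask",
]

# pad (s) applied either side of an annotated artifact
DEFAULT_PADS = {
    "cough": 3.0,
    "talk": 3.0,
    "drink": 3.0,
    "body_shift": 10.0,
    "reposition": 10.0,
}


@dataclass
class ArtifactInterval:
    """One excluded time interval."""

    start_s: float
    end_s: float
    kind: str
    source: str = "annotation"  # annotation | signal
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ValueError("artifact interval must have start < end")


def screen_annotations(
    log: AnnotationLog, pad_s: dict[str, float] | float | None = None
) -> list[ArtifactInterval]:
    """Turn artifact annotations into exclusion intervals.

    Each cough/talk/drink annotation becomes ``[t - pad, t + pad)`` with a
    3 s default pad; body shifts and repositioning use 10 s.  Gas expulsion
    and the other physiological annotations produce no interval.
    """
    pads = dict(DEFAULT_PADS)
    if isinstance(pad_s, dict):
        pads.update(pad_s)
    elif pad_s is not None:
        pads = {k: float(pad_s) for k in pads}
    intervals = []
    for ann in log:
        if ann.kind in pads:
            pad = pads[ann.kind]
            intervals.append(
                ArtifactInterval(ann.time_s - pad, ann.time_s + pad, ann.kind)
            )
    return intervals


def classify_global_pressurization(
    event,
    recording: Recording,
    thresholds=None,
) -> str:
    """Decide whether a global simultaneous pressurization is colonic or abdominal.

    Requires a candidate/event spanning most sensors with (near-)simultaneous
    onsets.  With a sphincter channel: a pressure rise of >= 5 mmHg above the
    local resting tone during the event marks it abdominal, a dip of >= 20%
    of tone starting at or before arrival marks it colonic, anything else is
    undetermined.  Without a sphincter channel, a cough-morphology test
    (duration < 2.5 s and rise time < 1 s) marks it abdominal.
    """
    from .detection import ClassificationThresholds, _local_tone

    thr = thresholds or ClassificationThresholds()
    members = event.members
    sensors = sorted({t.sensor_index for t in members})
    n_functional = len(recording.functional_sensors())
    onsets = [t.onset_s for t in members]
    if len(sensors) < 0.5 * n_functional or (
        np.ptp(onsets) > 2 * thr.onset_group_window_s
    ):
        raise ValueError(
            "global-pressurization screening requires a near-simultaneous event "
            "spanning most sensors"
        )
    onset = min(onsets)
    offset = max(t.offset_s for t in members)

    channels, phase = sphincter_channels(recording)
    fs = recording.sampling_rate
    if channels and phase is not None and phase.contains(onset):
        rose = dipped = False
        for s in channels:
            trace = recording.pressures[s - 1]
            tone = _local_tone(trace, fs, onset, thr.sphincter_tone_window_s)
            sl = recording.sample_slice(onset - 5.0, offset)
            seg = trace[sl]
            if not len(seg):
                continue
            if np.nanmax(seg) - tone >= thr.sphincter_rise_mmhg:
                rose = True
            if np.nanmin(seg) <= (1 - thr.sphincter_relaxation_frac) * tone:
                dipped = True
        if rose:
            return "abdominal"
        if dipped:
            return "colonic"
        return "undetermined"

    duration = offset - onset
    rise = float(np.median([t.peak_s - t.onset_s for t in members]))
    if duration < thr.min_spw_duration_s and rise < 1.0:
        return "abdominal"
    return "colonic"


def exclusion_mask(
    recording: Recording, intervals: list[ArtifactInterval]
) -> np.ndarray:
    """Boolean per-sample mask, true inside any artifact interval.

    Downstream detectors drop events whose onset is masked, and masked time
    is subtracted from the denominators of per-time metrics.  The mask is a
    union, hence idempotent and order-independent.
    """
    mask = np.zeros(recording.n_samples, dtype=bool)
    for iv in intervals:
        sl = recording.sample_slice(max(0.0, iv.start_s), iv.end_s)
        mask[sl] = True
    return mask
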