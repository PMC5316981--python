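"""Data model and file I/O for high-resolution colonic manometry recordings.

A recording is a sensors x samples matrix of intraluminal pressures (mmHg)
acquired from a linear catheter with evenly spaced solid-state sensors.
Sensors are indexed 1..n_sensors from distal (P1, closest to the anal verge)
to proximal (P36 at the catheter tip).  Time is expressed in seconds from
the start of the recording and all windows are half-open ``[start, end)``.

On-disk dialect: a plain CSV matrix (one row per sensor, labelled P1..Pn),
a YAML metadata sidecar next to it, and a tab-separated annotation log.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError",
    "ConfigurationError",
    "PhaseWindow",
    "Annotation",
    "AnnotationLog",
    "Recording",
    "sensor_position",
    "sphincter_channels",
    "read_recording",
    "write_recording",
    "read_annotations",
    "write_annotations",
    "render_map",
]

PHASE_LABELS = ("baseline", "meal_intake", "postprandial", "sphincter_pullback")
GROUPS = ("constipation", "healthy_control", "patient_control", "synthetic")
ANNOTATION_KINDS = (
    "cough",
    "talk",
    "body_shift",
    "drink",
    "gas_expulsion",
    "bowel_urge",
    "meal_start",
    "meal_end",
    "reposition",
    "other",
)


class FormatError(ValueError):
    """A data file does not conform to the expected on-disk layout."""


class ConfigurationError(ValueError):
    """Required metadata (sidecar, field, value) is missing or invalid."""


@dataclass
class PhaseWindow:
    """A labelled study phase, e.g. the 90-min baseline or the meal response."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.label not in PHASE_LABELS:
            raise ConfigurationError(f"unknown phase label {self.label!r}")
        if not self.start_s < self.end_s:
            raise ConfigurationError(
                f"phase {self.label!r}: start {self.start_s} must precede end {self.end_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass
class Annotation:
    """A timestamped subject/observer event noted during acquisition."""

    time_s: float
    kind: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ANNOTATION_KINDS:
            raise FormatError(f"unknown annotation kind {self.kind!r}")


class AnnotationLog:
    """Chronologically ordered collection of :class:`Annotation`."""

    def __init__(self, annotations=()):
        self.annotations = sorted(annotations, key=lambda a: a.time_s)

    def __iter__(self):
        return iter(self.annotations)

    def __len__(self):
        return len(self.annotations)

    def of_kind(self, *kinds: str) -> list[Annotation]:
        return [a for a in self.annotations if a.kind in kinds]

    def append(self, annotation: Annotation) -> None:
        self.annotations.append(annotation)
        self.annotations.sort(key=lambda a: a.time_s)


@dataclass
class Recording:
    """A multichannel pressure recording plus acquisition metadata.

    Parameters
    ----------
    pressures
        Array of shape ``(n_sensors, n_samples)`` in mmHg; row 0 is P1
        (distal), the last row the catheter tip.
    sampling_rate
        Samples per second (Hz).
    sensor_spacing
        Inter-sensor distance in cm (1 cm for the 36-sensor probe).
    tip_position
        Position of the most proximal sensor in cm from the anal verge.
    functional_mask
        Per-sensor boolean; ``False`` marks a malfunctioning sensor whose
        trace is ignored by all analyses.
    """

    pressures: np.ndarray
    sampling_rate: float
    sensor_spacing: float = 1.0
    tip_position: float = 85.0
    functional_mask: np.ndarray | None = None
    phases: list[PhaseWindow] = field(default_factory=list)
    subject_id: str = "anonymous"
    group: str = "synthetic"

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        if self.pressures.ndim != 2:
            raise FormatError("pressures must be a 2-D sensors x samples matrix")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be positive")
        if self.sensor_spacing <= 0:
            raise ConfigurationError("sensor_spacing must be positive")
        if self.group not in GROUPS:
            raise ConfigurationError(f"unknown subject group {self.group!r}")
        if self.functional_mask is None:
            self.functional_mask = np.ones(self.n_sensors, dtype=bool)
        else:
            self.functional_mask = np.asarray(self.functional_mask, dtype=bool)
            if self.functional_mask.shape != (self.n_sensors,):
                raise ConfigurationError(
                    "functional_mask length must equal the number of sensors"
                )
        for ph in self.phases:
            if ph.start_s < 0 or ph.end_s > self.duration_s + 1e-9:
                raise ConfigurationError(
                    f"phase {ph.label!r} [{ph.start_s}, {ph.end_s}) lies outside the recording"
                )
        labels = [p.label for p in self.phases if p.label != "sphincter_pullback"]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("phase labels must be unique (except sphincter_pullback)")

    @property
    def n_sensors(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_samples(self) -> int:
        return self.pressures.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def phase(self, label: str) -> PhaseWindow | None:
        for ph in self.phases:
            if ph.label == label:
                return ph
        return None

    def sample_slice(self, start_s: float, end_s: float) -> slice:
        """Half-open sample slice covering ``[start_s, end_s)``, clipped."""
        i0 = max(0, int(np.floor(start_s * self.sampling_rate)))
        i1 = min(self.n_samples, int(np.ceil(end_s * self.sampling_rate)))
        return slice(i0, max(i0, i1))

    def functional_sensors(self) -> list[int]:
        """1-based indices of functional sensors, distal to proximal."""
        return [i + 1 for i in range(self.n_sensors) if self.functional_mask[i]]


def sensor_position(recording: Recording, sensor_index: int) -> float:
    """Position of a sensor in cm from the anal verge.

    The catheter tip (highest index) sits at ``tip_position``; positions are
    affine in the index with slope ``sensor_spacing``.
    """
    if not 1 <= sensor_index <= recording.n_sensors:
        raise IndexError(
            f"sensor index {sensor_index} outside 1..{recording.n_sensors}"
        )
    return recording.tip_position - (recording.n_sensors - sensor_index) * recording.sensor_spacing


def sphincter_channels(
    recording: Recording, min_tone: float = 20.0, n_channels: int = 2
) -> tuple[list[int], PhaseWindow | None]:
    """Identify internal-anal-sphincter channels during a pull-back phase.

    When the catheter is partially withdrawn the one or two most distal
    functional sensors sit in the sphincter and carry a sustained resting
    tone.  Returns the 1-based channel indices whose median pressure during
    the ``sphincter_pullback`` phase exceeds ``min_tone`` mmHg, along with
    the phase window, or ``([], None)`` when no pull-back phase exists.
    """
    phase = recording.phase("sphincter_pullback")
    if phase is None:
        return [], None
    sl = recording.sample_slice(phase.start_s, phase.end_s)
    candidates = recording.functional_sensors()[:n_channels]
    channels = []
    for s in candidates:
        tone = float(np.nanmedian(recording.pressures[s - 1, sl]))
        if tone > min_tone:
            channels.append(s)
    return channels, (phase if channels else phase)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SENSOR_RE = re.compile(r"^P(\d+)$")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_recording(recording: Recording, path) -> None:
    """Write the pressure matrix (CSV) and metadata sidecar (YAML).

    Pressures are serialised with 17 significant digits so that
    ``read_recording(write_recording(r))`` reproduces them bit-exactly;
    NaN samples are written as the sentinel ``NaN``.
    """
    path = Path(path)
    labels = [f"P{i + 1}" for i in range(recording.n_sensors)]
    frame = pd.DataFrame(recording.pressures, index=pd.Index(labels, name="sensor"))
    frame.to_csv(path, float_format="%.17g", na_rep="NaN")
    meta = {
        "sampling_rate": float(recording.sampling_rate),
        "sensor_spacing": float(recording.sensor_spacing),
        "n_sensors": int(recording.n_sensors),
        "tip_position": float(recording.tip_position),
        "functional_mask": [bool(b) for b in recording.functional_mask],
        "phases": [
            {"label": p.label, "start_s": float(p.start_s), "end_s": float(p.end_s)}
            for p in recording.phases
        ],
        "subject_id": recording.subject_id,
        "group": recording.group,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_recording(path) -> Recording:
    """Read a recording written by :func:`write_recording`.

    Rows are re-ordered to P1..Pn regardless of file order.  A missing
    sidecar raises :class:`ConfigurationError`; a row-count mismatch or a
    non-numeric pressure raises :class:`FormatError` naming the offender.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ConfigurationError(f"metadata sidecar {sidecar} not found")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh) or {}
    for key in ("sampling_rate", "n_sensors"):
        if key not in meta:
            raise ConfigurationError(f"sidecar missing required field {key!r}")

    frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
    n_expected = int(meta["n_sensors"])
    if frame.shape[0] != n_expected:
        raise FormatError(
            f"expected {n_expected} sensor rows, found {frame.shape[0]} in {path}"
        )
    order = {}
    for label in frame.index:
        m = _SENSOR_RE.match(str(label))
        if not m:
            raise FormatError(f"unparseable sensor label {label!r}")
        order[label] = int(m.group(1))
    frame = frame.loc[sorted(frame.index, key=order.get)]

    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        raw = frame[col]
        bad = numeric.isna() & ~raw.astype(str).str.strip().str.lower().isin(
            {"nan", ""}
        ) & ~raw.isna()
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"non-numeric pressure {raw[row]!r} at sensor {row}, sample column {col}"
            )
        values[:, j] = numeric.to_numpy()

    return Recording(
        pressures=values,
        sampling_rate=float(meta["sampling_rate"]),
        sensor_spacing=float(meta.get("sensor_spacing", 1.0)),
        tip_position=float(meta.get("tip_position", 85.0)),
        functional_mask=meta.get("functional_mask"),
        phases=[PhaseWindow(**p) for p in meta.get("phases", [])],
        subject_id=str(meta.get("subject_id", "anonymous")),
        group=str(meta.get("group", "synthetic")),
    )


def write_annotations(log: AnnotationLog, path) -> None:
    """Write a tab-separated annotation log (time_s, kind, note)."""
    frame = pd.DataFrame(
        [(a.time_s, a.kind, a.note) for a in log], columns=["time_s", "kind", "note"]
    )
    frame.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> AnnotationLog:
    """Read a tab-separated annotation log; chronological order is enforced."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    required = {"time_s", "kind", "note"}
    if not required.issubset(frame.columns):
        raise FormatError(f"annotation log must have columns {sorted(required)}")
    annotations = []
    for _, row in frame.iterrows():
        try:
            t = float(row["time_s"])
        except ValueError as exc:
            raise FormatError(f"non-numeric annotation time {row['time_s']!r}") from exc
        annotations.append(Annotation(t, row["kind"], row["note"]))
    return AnnotationLog(annotations)


def render_map(recording: Recording, window, out, cmap: str = "magma", vmax=None) -> None:
    """Render a spatiotemporal pressure map to an image file.

    Distal sensors (P1) are drawn at the bottom, time runs along x, and the
    colour encodes pressure.  Malfunctioning sensors are shown as a neutral
    grey band, mirroring the grey squares on clinical maps.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(window, PhaseWindow):
        start_s, end_s = window.start_s, window.end_s
    else:
        start_s, end_s = window
    sl = recording.sample_slice(start_s, end_s)
    if sl.stop - sl.start == 0:
        raise ValueError("empty rendering window")
    data = np.ma.masked_invalid(recording.pressures[:, sl])
    data[~recording.functional_mask, :] = np.ma.masked

    fig, ax = plt.subplots(figsize=(8, 4.5))
    colormap = matplotlib.colormaps[cmap].copy()
    colormap.set_bad("0.6")
    im = ax.imshow(
        data,
        origin="lower",
        aspect="auto",
        cmap=colormap,
        vmax=vmax,
        extent=(start_s, start_s + (sl.stop - sl.start) / recording.sampling_rate, 0.5, recording.n_sensors + 0.5),
        interpolation="nearest",
    )
    ax.set_xlabel("time (s)")
    ax.set_ylabel("sensor (P1 distal → tip)")
    fig.colorbar(im, ax=ax, label="pressure (mmHg)")
    fig.tight_layout()
    fig.savefig(out, dpi=110)
    plt.close(fig)
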