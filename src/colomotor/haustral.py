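"""Haustral activity: boundary rhythms, segmentation and synchronized waves.

Haustra are sac-like colonic compartments bounded by circumferential
contractions 3-5 cm apart.  On a 1-cm sensor array they appear as rhythmic
isolated pressure transients (~3 cycles/min) confined to regularly spaced
sensors with little activity in between; within a haustrum, erratic
segmentation-like activity alternates abruptly with "synchronized haustral
pressure waves" — cycles coherent across the 3-5 sensors of the haustrum,
propagating at ~2 cm/s in antegrade, retrograde or mixed direction, in
episodes of 2-10 min.

The analyses here are automated versions of the by-eye reading of
spatiotemporal maps: per-sensor transient-rate profiles with a
shuffle-calibrated rhythmicity test, boundary detection from the spatial
rate profile, and a cross-correlation synchrony classifier over 60-s
blocks (1-6 cycles/min band, mean pairwise peak correlation over lags up
to 10 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .detection import ClassificationThresholds, Transient, detect_transients
from .recording_io import Recording

__all__ = [
    "HaustralThresholds",
    "ActivityProfile",
    "HaustralBoundarySet",
    "HaustralStateSegment",
    "ShpwEpisode",
    "activity_profile",
    "detect_boundaries",
    "classify_window_state",
    "label_state_timeline",
    "shpw_episodes",
]


@dataclass
class HaustralThresholds:
    """Constants of the haustral state classifier.

    The synchrony threshold (mean pairwise peak correlation 0.6, lags up to
    10 s) and the 60-s labelling block (>= 3 cycles of a 3 cycles/min
    rhythm) are simulator-calibrated; the 1-6 cycles/min band brackets the
    characteristic intrahaustral frequency.
    """

    band_cpm: tuple[float, float] = (1.0, 6.0)
    sync_r: float = 0.6
    max_lag_s: float = 10.0
    block_s: float = 60.0
    quiescent_rate_per_min: float = 0.5
    direction_agreement: float = 0.7
    min_episode_s: float = 120.0
    simultaneity_velocity: float = 7.0


@dataclass
class ActivityProfile:
    """Per-sensor transient rates and dominant rhythm over a window."""

    sensors: list[int]
    rates_per_min: np.ndarray
    dominant_freq_cpm: np.ndarray  # NaN where no significant rhythm
    prominence: np.ndarray
    window: tuple[float, float]


@dataclass
class HaustralBoundarySet:
    """Sensors behaving as haustral boundaries, with spacing statistics."""

    sensors: list[int]
    mean_spacing_cm: float
    spacing_cv: float
    mean_frequency_cpm: float
    persistence_s: float


@dataclass
class HaustralStateSegment:
    """State of one haustral window over one time block."""

    sensor_window: tuple[int, int]
    start_s: float
    end_s: float
    state: str  # segmentation | synchronized | quiescent
    frequency_cpm: float = float("nan")
    velocity: float | str | None = None  # signed cm/s or "simultaneous"
    mean_pairwise_r: float = float("nan")


@dataclass
class ShpwEpisode:
    """A sustained run of synchronized haustral pressure waves."""

    start_s: float
    end_s: float
    mean_frequency_cpm: float
    direction: str  # antegrade | retrograde | mixed
    blocks: list[HaustralStateSegment] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


# ---------------------------------------------------------------------------
# Activity profile and boundaries
# ---------------------------------------------------------------------------


def _band_peak(
    train: np.ndarray, fs: float, band_cpm: tuple[float, float], pad: int = 8
) -> tuple[float, float]:
    """(peak frequency cpm, peak power) in the band, zero-padded periodogram."""
    if len(train) < 8 or np.allclose(train, train[0]):
        return float("nan"), 0.0
    x = train - train.mean()
    freqs, power = signal.periodogram(x, fs=fs, nfft=pad * len(x))
    lo, hi = band_cpm[0] / 60.0, band_cpm[1] / 60.0
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any() or not power[sel].any():
        return float("nan"), 0.0
    f_band, p_band = freqs[sel], power[sel]
    i = int(np.argmax(p_band))
    f_peak, p_peak = float(f_band[i]), float(p_band[i])
    # harmonic guard: spike trains carry strong harmonics of the event rate;
    # if the subharmonic of the argmax is nearly as strong, it is the rhythm
    half = f_peak / 2.0
    if half >= lo:
        near = np.abs(f_band - half) <= 0.05 * half + 2.0 * (freqs[1] - freqs[0])
        if near.any():
            j = int(np.argmax(np.where(near, p_band, 0.0)))
            if p_band[j] >= 0.5 * p_peak:
                return float(f_band[j] * 60.0), float(p_band[j])
    return f_peak * 60.0, p_peak


def activity_profile(
    per_sensor_transients: list[list[Transient]],
    window: tuple[float, float],
    band_cpm: tuple[float, float] = (1.0, 6.0),
    n_shuffles: int = 200,
    seed: int = 0,
    min_window_s: float = 300.0,
) -> ActivityProfile:
    """Per-sensor transient rate and dominant rhythm in the 1-6 cpm band.

    Each sensor's transient onsets are binarised into 1-s bins; the dominant
    frequency is the periodogram peak in the band, reported only when its
    power exceeds the 95th percentile of peak powers from shuffled trains
    (a rate-preserving null, fixed seed).  Windows shorter than 5 min leave
    rhythmicity undetermined (all NaN).
    """
    start, end = window
    span = end - start
    if span <= 0:
        raise ValueError("empty analysis window")
    n_sensors = len(per_sensor_transients)
    rates = np.zeros(n_sensors)
    dominant = np.full(n_sensors, np.nan)
    prominence = np.zeros(n_sensors)
    rng = np.random.default_rng(seed)
    n_bins = max(1, int(span))
    for i, transients in enumerate(per_sensor_transients):
        onsets = [t.onset_s for t in transients if start <= t.onset_s < end]
        rates[i] = len(onsets) / (span / 60.0)
        if span < min_window_s or len(onsets) < 3:
            continue
        train = np.zeros(n_bins)
        idx = np.clip(((np.array(onsets) - start)).astype(int), 0, n_bins - 1)
        train[idx] = 1.0
        freq, peak = _band_peak(train, 1.0, band_cpm)
        null_peaks = np.empty(n_shuffles)
        for k in range(n_shuffles):
            null_peaks[k] = _band_peak(rng.permutation(train), 1.0, band_cpm)[1]
        threshold = np.percentile(null_peaks, 95)
        prominence[i] = peak / threshold if threshold > 0 else np.inf
        if peak > threshold:
            dominant[i] = freq
    return ActivityProfile(
        sensors=list(range(1, n_sensors + 1)),
        rates_per_min=rates,
        dominant_freq_cpm=dominant,
        prominence=prominence,
        window=(start, end),
    )


def detect_boundaries(
    profile: ActivityProfile,
    sensor_spacing: float = 1.0,
    max_spacing_cm: float = 8.0,
    min_boundaries: int = 3,
    spacing_cv_max: float = 0.35,
    rate_ratio: float = 3.0,
    min_rate_per_min: float = 0.5,
) -> HaustralBoundarySet:
    """Find haustral-boundary sensors from the spatial rate profile.

    Boundary sensors are local rate maxima whose rate is at least
    ``rate_ratio`` times the mean rate of the sensors between them; the set
    is accepted when >= 3 boundaries show regular spacing (CV <= 0.35, up to
    8 cm apart).  Returns an empty set otherwise.
    """
    rates = profile.rates_per_min
    n = len(rates)
    candidates = []
    for i in range(n):
        left = rates[i - 1] if i > 0 else -np.inf
        right = rates[i + 1] if i < n - 1 else -np.inf
        if rates[i] >= min_rate_per_min and rates[i] >= left and rates[i] >= right and (
            rates[i] > left or rates[i] > right
        ):
            candidates.append(i)
    # enforce dominance over intervening sensors
    kept = []
    for j, i in enumerate(candidates):
        neighbours = []
        if j > 0:
            neighbours.extend(rates[candidates[j - 1] + 1 : i])
        if j < len(candidates) - 1:
            neighbours.extend(rates[i + 1 : candidates[j + 1]])
        between = float(np.mean(neighbours)) if neighbours else 0.0
        if between == 0.0 or rates[i] >= rate_ratio * between:
            kept.append(i)
    empty = HaustralBoundarySet([], float("nan"), float("nan"), float("nan"), 0.0)
    if len(kept) < min_boundaries:
        return empty
    spacings = np.diff(kept) * sensor_spacing
    if np.any(spacings < 2.0) or np.any(spacings > max_spacing_cm):
        return empty
    cv = float(spacings.std() / spacings.mean()) if spacings.mean() > 0 else np.inf
    if cv > spacing_cv_max:
        return empty
    sensors = [i + 1 for i in kept]
    freqs = profile.dominant_freq_cpm[kept]
    mean_freq = float(np.nanmean(freqs)) if not np.all(np.isnan(freqs)) else float("nan")
    persistence = profile.window[1] - profile.window[0]
    return HaustralBoundarySet(
        sensors=sensors,
        mean_spacing_cm=float(spacings.mean()),
        spacing_cv=cv,
        mean_frequency_cpm=mean_freq,
        persistence_s=persistence,
    )


def boundary_persistence(
    per_sensor_transients: list[list[Transient]],
    window: tuple[float, float],
    sensor_spacing: float = 1.0,
    block_s: float = 1800.0,
    **profile_kwargs,
) -> float:
    """Longest stretch (s) over which the same boundary set dominates,
    re-evaluated in 30-min blocks (boundaries persist 30-180 min clinically)."""
    start, end = window
    blocks = []
    t = start
    while t < end:
        profile = activity_profile(
            per_sensor_transients, (t, min(end, t + block_s)), **profile_kwargs
        )
        blocks.append(tuple(detect_boundaries(profile, sensor_spacing).sensors))
        t += block_s
    best = run = 0
    prev = None
    for b in blocks:
        run = run + 1 if (b and b == prev) else (1 if b else 0)
        prev = b if b else None
        best = max(best, run)
    return best * block_s


# ---------------------------------------------------------------------------
# Window-state classification
# ---------------------------------------------------------------------------


def _bandpass(
    traces: np.ndarray, fs: float, band_cpm: tuple[float, float]
) -> np.ndarray:
    lo, hi = band_cpm[0] / 60.0, band_cpm[1] / 60.0
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, traces, axis=-1)


def _max_corr_lag(
    a: np.ndarray, b: np.ndarray, fs: float, max_lag_s: float
) -> tuple[float, float]:
    """Peak normalised cross-correlation of a and b over |lag| <= max_lag_s.

    Positive lag means activity on ``a`` occurs *later* than on ``b``.
    """
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return 0.0, 0.0
    c = signal.correlate(a, b, mode="full") / denom
    lags = signal.correlation_lags(len(a), len(b), mode="full") / fs
    sel = np.abs(lags) <= max_lag_s
    i = np.argmax(c[sel])
    return float(c[sel][i]), float(lags[sel][i])


def classify_window_state(
    recording: Recording,
    sensor_window: tuple[int, int],
    block: tuple[float, float],
    thresholds: HaustralThresholds | None = None,
    transients: list[list[Transient]] | None = None,
    detection_thresholds: ClassificationThresholds | None = None,
) -> HaustralStateSegment:
    """Label one haustral window x time block as segmentation, synchronized
    or quiescent.

    Band-passed (1-6 cycles/min) traces are compared pairwise; a mean peak
    cross-correlation >= 0.6 within +/-10 s lags marks the block
    synchronized (the lag-position fit yields velocity and direction; speeds
    beyond the resolution bound are reported "simultaneous"), ongoing but
    uncorrelated activity marks it segmentation, and a total transient rate
    below 0.5/min marks it quiescent.  Invariant to per-sensor offsets and
    to global positive rescaling.
    """
    thr = thresholds or HaustralThresholds()
    lo, hi = sensor_window
    if not 2 <= hi - lo + 1 <= 5:
        raise ValueError("haustral window must cover 2-5 adjacent sensors")
    start, end = block
    fs = recording.sampling_rate

    if transients is None:
        transients = detect_transients(
            recording,
            detection_thresholds or ClassificationThresholds(),
            sensors=list(range(lo, hi + 1)),
        )
    n_tr = sum(
        1
        for s in range(lo, hi + 1)
        for t in transients[s - 1]
        if start <= t.onset_s < end
    )
    rate = n_tr / ((end - start) / 60.0)
    if rate < thr.quiescent_rate_per_min:
        return HaustralStateSegment(sensor_window, start, end, "quiescent")

    pad = 60.0
    sl = recording.sample_slice(max(0.0, start - pad), min(recording.duration_s, end + pad))
    seg_traces = np.nan_to_num(recording.pressures[lo - 1 : hi, sl])
    filtered = _bandpass(seg_traces, fs, thr.band_cpm)
    i0 = round((start - max(0.0, start - pad)) * fs)
    filtered = filtered[:, i0 : i0 + round((end - start) * fs)]

    n_ch = filtered.shape[0]
    rs, lag_by_sensor = [], {lo: 0.0}
    for i in range(n_ch):
        for j in range(i + 1, n_ch):
            r, lag = _max_corr_lag(filtered[i], filtered[j], fs, thr.max_lag_s)
            rs.append(r)
            if i == 0:
                lag_by_sensor[lo + j] = -lag  # arrival of sensor j relative to lo
    r_bar = float(np.mean(rs)) if rs else 0.0

    freq, _ = _band_peak(filtered.mean(axis=0), fs, thr.band_cpm)
    if r_bar >= thr.sync_r:
        xs = np.array(sorted(lag_by_sensor)) * recording.sensor_spacing
        ys = np.array([lag_by_sensor[s] for s in sorted(lag_by_sensor)])
        velocity: float | str | None
        if np.ptp(ys) == 0:
            velocity = "simultaneous"
        else:
            slope = stats.theilslopes(ys, xs).slope
            if slope == 0:
                velocity = "simultaneous"
            else:
                velocity = -1.0 / slope
                if abs(velocity) > thr.simultaneity_velocity:
                    velocity = "simultaneous"
        return HaustralStateSegment(
            sensor_window, start, end, "synchronized", freq, velocity, r_bar
        )
    return HaustralStateSegment(
        sensor_window, start, end, "segmentation", freq, None, r_bar
    )


def label_state_timeline(
    recording: Recording,
    sensor_window: tuple[int, int],
    time_range: tuple[float, float] | None = None,
    thresholds: HaustralThresholds | None = None,
    detection_thresholds: ClassificationThresholds | None = None,
) -> list[HaustralStateSegment]:
    """Tile a time range with fixed blocks and label each one."""
    thr = thresholds or HaustralThresholds()
    start, end = time_range or (0.0, recording.duration_s)
    lo, hi = sensor_window
    transients = detect_transients(
        recording,
        detection_thresholds or ClassificationThresholds(),
        sensors=list(range(lo, hi + 1)),
    )
    segments = []
    t = start
    while t + thr.block_s <= end + 1e-9:
        segments.append(
            classify_window_state(
                recording, sensor_window, (t, t + thr.block_s), thr, transients
            )
        )
        t += thr.block_s
    return segments


# ---------------------------------------------------------------------------
# Episodes
# ---------------------------------------------------------------------------


def shpw_episodes(
    segments: list[HaustralStateSegment],
    min_episode_s: float = 120.0,
    direction_agreement: float = 0.7,
) -> tuple[list[ShpwEpisode], list[float]]:
    """Merge synchronized runs into episodes; report alternation switches.

    Runs of contiguous synchronized blocks lasting at least
    ``min_episode_s`` become episodes (clinically 2-10 min, 1-3 per
    session); episode direction is antegrade/retrograde when >= 70% of the
    blocks' velocities agree in sign, otherwise mixed.  Also returns the
    times of segmentation <-> synchronized switches.
    """
    episodes: list[ShpwEpisode] = []
    run: list[HaustralStateSegment] = []

    def close_run() -> None:
        nonlocal run
        if run and (run[-1].end_s - run[0].start_s) >= min_episode_s:
            freqs = [b.frequency_cpm for b in run if np.isfinite(b.frequency_cpm)]
            signs = [
                np.sign(b.velocity)
                for b in run
                if isinstance(b.velocity, float) and b.velocity != 0
            ]
            if signs:
                agree_pos = np.mean([s > 0 for s in signs])
                direction = (
                    "antegrade"
                    if agree_pos >= direction_agreement
                    else "retrograde"
                    if agree_pos <= 1 - direction_agreement
                    else "mixed"
                )
            else:
                direction = "mixed"
            episodes.append(
                ShpwEpisode(
                    run[0].start_s,
                    run[-1].end_s,
                    float(np.mean(freqs)) if freqs else float("nan"),
                    direction,
                    blocks=list(run),
                )
            )
        run = []

    for seg in segments:
        if seg.state == "synchronized":
            run.append(seg)
        else:
            close_run()
    close_run()

    switches = []
    prev = None
    for seg in segments:
        if seg.state in ("segmentation", "synchronized"):
            if prev is not None and seg.state != prev:
                switches.append(seg.start_s)
            prev = seg.state
    return episodes, switches
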