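"""Per-session summaries and cohort comparisons of colonic motor patterns.

For each study phase (baseline / postprandial) a session summary reports,
per pattern class: occurrence per 30 min of unmasked time, the maximum
frequency within any sustained rhythmic run, mean duration, mean
propagation distance and mean amplitude; plus the isolated-transient block
(maximum amplitude, % sensors involved out of 36, % time involved, and the
fraction of active sensors reaching <50, 50-100 and >100 mmHg — a sensor
may fall in several categories, so these can sum to more than 100%), and
the presence of high-amplitude propagating waves and synchronized haustral
pressure waves.

Cohort comparisons mirror standard practice: paired t within subjects
(baseline vs meal), independent t between groups at baseline, exact
McNemar / Fisher tests for pattern presence, and baseline-adjusted
linear/logistic regression for post-meal values.  Comparisons with n < 5
are suppressed (no p reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detection import ClassifiedEvent
from .haustral import ShpwEpisode
from .recording_io import PhaseWindow

__all__ = [
    "PatternStats",
    "TransientMetrics",
    "SessionSummary",
    "GroupComparison",
    "summarize_session",
    "max_sustained_frequency",
    "isolated_transient_metrics",
    "paired_compare",
    "independent_compare",
    "presence_compare",
    "baseline_adjusted_compare",
    "export_table",
]

MIN_N_FOR_TEST = 5
PROPAGATING_CLASSES = ("SPW", "APW", "RPW")


@dataclass
class PatternStats:
    """Summary of one propagating pattern class within one phase."""

    occurrence_per_30min: float
    max_frequency_per_min: float | None
    mean_duration_s: float | None
    mean_distance_cm: float | None
    mean_amplitude_mmhg: float | None
    n_events: int


@dataclass
class TransientMetrics:
    """Isolated pressure transient metrics for one phase."""

    max_amplitude_mmhg: float | None
    pct_sensors_involved: float
    pct_time_involved: float
    pct_amp_lt_50: float
    pct_amp_50_100: float
    pct_amp_gt_100: float
    n_transients: int


@dataclass
class SessionSummary:
    """All per-phase metrics for one subject-phase."""

    phase: str
    analyzed_time_s: float
    patterns: dict[str, PatternStats] = field(default_factory=dict)
    transients: TransientMetrics | None = None
    hapw_present: bool = False
    shpw_present: bool = False


@dataclass
class GroupComparison:
    """One statistical comparison, suppressed when n < 5."""

    metric: str
    groups: tuple[str, str]
    statistic_name: str
    statistic: float | None
    df: float | None
    p: float | None
    n: int
    suppressed: bool = False
    coefficient: float | None = None
    ci: tuple[float, float] | None = None
    flag: str | None = None


# ---------------------------------------------------------------------------
# Session summaries
# ---------------------------------------------------------------------------


def max_sustained_frequency(
    onsets, cv_max: float = 0.25, min_run: int = 3
) -> float | None:
    """Maximum frequency (per min) within any sustained rhythmic run.

    Scans all windows of at least ``min_run`` consecutive inter-onset
    intervals with interval CV <= ``cv_max`` and returns 60/mean-interval of
    the fastest qualifying window; ``None`` when no window qualifies.
    Events outside the rhythmic run do not affect the result.
    """
    onsets = np.sort(np.asarray(list(onsets), dtype=float))
    if len(onsets) < min_run + 1:
        return None
    intervals = np.diff(onsets)
    best = None
    n = len(intervals)
    for i in range(n):
        for j in range(i + min_run, n + 1):
            w = intervals[i:j]
            m = w.mean()
            if m <= 0:
                continue
            if w.std() / m <= cv_max:
                freq = 60.0 / m
                if best is None or freq > best:
                    best = freq
    return best


def _unmasked_seconds(
    phase: PhaseWindow, mask: np.ndarray | None, sampling_rate: float
) -> float:
    if mask is None:
        return phase.duration_s
    i0 = int(np.floor(phase.start_s * sampling_rate))
    i1 = min(len(mask), int(np.ceil(phase.end_s * sampling_rate)))
    return float(np.sum(~mask[i0:i1]) / sampling_rate)


def isolated_transient_metrics(
    isolated_events: list[ClassifiedEvent],
    unmasked_phase_s: float,
    n_sensors: int = 36,
    functional_sensors: list[int] | None = None,
) -> TransientMetrics:
    """Isolated-transient block of the session summary.

    Percent sensors involved is always out of ``n_sensors`` (36 on the
    standard probe, regardless of malfunctioning sensors); percent time is
    the per-sensor summed transient duration over the unmasked phase
    duration, averaged over functional sensors; the amplitude-category
    percentages are computed over sensors showing any activity, and a
    sensor with transients in several categories counts in each.
    """
    functional = functional_sensors or list(range(1, n_sensors + 1))
    by_sensor: dict[int, list[ClassifiedEvent]] = {}
    for ev in isolated_events:
        by_sensor.setdefault(ev.first_sensor, []).append(ev)
    active = sorted(by_sensor)
    n_active = len(active)

    if unmasked_phase_s > 0:
        pct_time = float(
            np.mean(
                [
                    min(
                        100.0,
                        100.0
                        * sum(e.duration_s for e in by_sensor.get(s, []))
                        / unmasked_phase_s,
                    )
                    for s in functional
                ]
            )
        )
    else:
        pct_time = float("nan")

    def category_pct(lo: float, hi: float) -> float:
        if n_active == 0:
            return 0.0
        hits = sum(
            1
            for s in active
            if any(lo <= e.amplitude_max < hi for e in by_sensor[s])
        )
        return 100.0 * hits / n_active

    amps = [e.amplitude_max for e in isolated_events]
    return TransientMetrics(
        max_amplitude_mmhg=float(max(amps)) if amps else None,
        pct_sensors_involved=100.0 * n_active / n_sensors,
        pct_time_involved=pct_time,
        pct_amp_lt_50=category_pct(0.0, 50.0),
        pct_amp_50_100=category_pct(50.0, 100.0),
        pct_amp_gt_100=category_pct(100.0, np.inf),
        n_transients=len(isolated_events),
    )


def summarize_session(
    events: list[ClassifiedEvent],
    episodes: list[ShpwEpisode],
    phases: list[PhaseWindow],
    mask: np.ndarray | None = None,
    sampling_rate: float = 10.0,
    n_sensors: int = 36,
    functional_sensors: list[int] | None = None,
    cv_max: float = 0.25,
    min_run: int = 3,
) -> dict[str, SessionSummary]:
    """Build one :class:`SessionSummary` per phase.

    Occurrence is count x 1800 / unmasked phase seconds; means are over the
    events whose onset falls in the phase; HAPW / SHPW presence are
    booleans per phase.
    """
    out: dict[str, SessionSummary] = {}
    for phase in phases:
        if phase.label == "sphincter_pullback":
            continue
        analyzed = _unmasked_seconds(phase, mask, sampling_rate)
        summary = SessionSummary(phase=phase.label, analyzed_time_s=analyzed)
        in_phase = [e for e in events if phase.contains(e.onset_s)]
        for kind in PROPAGATING_CLASSES:
            evs = [e for e in in_phase if e.kind == kind]
            occurrence = len(evs) * 1800.0 / analyzed if analyzed > 0 else float("nan")
            summary.patterns[kind] = PatternStats(
                occurrence_per_30min=occurrence,
                max_frequency_per_min=max_sustained_frequency(
                    [e.onset_s for e in evs], cv_max, min_run
                ),
                mean_duration_s=float(np.mean([e.duration_s for e in evs])) if evs else None,
                mean_distance_cm=float(np.mean([e.span_cm for e in evs])) if evs else None,
                mean_amplitude_mmhg=float(np.mean([e.amplitude_mean for e in evs]))
                if evs
                else None,
                n_events=len(evs),
            )
        isolated = [e for e in in_phase if e.kind == "isolated_transient"]
        summary.transients = isolated_transient_metrics(
            isolated, analyzed, n_sensors, functional_sensors
        )
        summary.hapw_present = any(e.kind == "HAPW" for e in in_phase)
        summary.shpw_present = any(
            ep.start_s < phase.end_s and ep.end_s > phase.start_s for ep in episodes
        )
        out[phase.label] = summary
    return out


# ---------------------------------------------------------------------------
# Statistical comparisons
# ---------------------------------------------------------------------------


def paired_compare(
    baseline, meal, metric: str = "", min_n: int = MIN_N_FOR_TEST
) -> GroupComparison:
    """Two-sided paired t test (baseline vs meal, same subjects).

    Pairs with a missing value on either side are dropped; comparisons with
    fewer than 5 complete pairs are suppressed.
    """
    baseline = np.asarray(baseline, dtype=float)
    meal = np.asarray(meal, dtype=float)
    if baseline.shape != meal.shape:
        raise ValueError("paired comparison requires equal-length vectors")
    ok = ~(np.isnan(baseline) | np.isnan(meal))
    b, m = baseline[ok], meal[ok]
    n = len(b)
    if n < min_n:
        return GroupComparison(metric, ("baseline", "meal"), "paired_t", None, None, None, n, True)
    if np.allclose(b, m):
        return GroupComparison(metric, ("baseline", "meal"), "paired_t", 0.0, n - 1, 1.0, n)
    t, p = stats.ttest_rel(b, m)
    return GroupComparison(metric, ("baseline", "meal"), "paired_t", float(t), n - 1, float(p), n)


def independent_compare(
    group_a, group_b, metric: str = "", labels=("constipation", "controls"),
    min_n: int = MIN_N_FOR_TEST,
) -> GroupComparison:
    """Two-sided independent-samples t test between subject groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    n = len(a) + len(b)
    if min(len(a), len(b)) < min_n:
        return GroupComparison(metric, tuple(labels), "independent_t", None, None, None, n, True)
    t, p = stats.ttest_ind(a, b)
    return GroupComparison(
        metric, tuple(labels), "independent_t", float(t), len(a) + len(b) - 2, float(p), n
    )


def presence_compare(
    flags_a, flags_b, mode: str = "within", metric: str = "",
    min_n: int = MIN_N_FOR_TEST,
) -> GroupComparison:
    """Compare pattern presence proportions.

    ``within`` (baseline vs meal, paired): exact McNemar — a two-sided
    exact binomial on the discordant pairs.  ``between`` (two groups):
    two-sided Fisher exact on the 2x2 table.
    """
    a = np.asarray(flags_a)
    b = np.asarray(flags_b)
    if not (set(np.unique(a)) <= {0, 1} and set(np.unique(b)) <= {0, 1}):
        raise ValueError("presence comparison requires binary vectors")
    if mode == "within":
        if a.shape != b.shape:
            raise ValueError("within-subject comparison requires paired vectors")
        n = len(a)
        if n < min_n:
            return GroupComparison(metric, ("baseline", "meal"), "mcnemar_exact", None, None, None, n, True)
        d01 = int(np.sum((a == 0) & (b == 1)))
        d10 = int(np.sum((a == 1) & (b == 0)))
        if d01 + d10 == 0:
            p = 1.0
        else:
            p = float(stats.binomtest(d10, d01 + d10, 0.5).pvalue)
        return GroupComparison(
            metric, ("baseline", "meal"), "mcnemar_exact", float(min(d01, d10)), None, p, n
        )
    if mode == "between":
        n = len(a) + len(b)
        if min(len(a), len(b)) < min_n:
            return GroupComparison(metric, ("group_a", "group_b"), "fisher_exact", None, None, None, n, True)
        table = [
            [int(np.sum(a == 1)), int(np.sum(a == 0))],
            [int(np.sum(b == 1)), int(np.sum(b == 0))],
        ]
        odds, p = stats.fisher_exact(table, alternative="two-sided")
        return GroupComparison(
            metric, ("group_a", "group_b"), "fisher_exact", float(odds), None, float(p), n
        )
    raise ValueError(f"unknown mode {mode!r}")


def baseline_adjusted_compare(
    post, baseline, group_labels, binary: bool = False, metric: str = "",
    min_n: int = MIN_N_FOR_TEST,
) -> GroupComparison:
    """Baseline-adjusted group comparison of post-meal values.

    The post-meal value is regressed on subject group (0/1 coded) and the
    baseline value; the group coefficient, its CI and p are reported.
    Linear for continuous outcomes, logistic for binary; logistic models
    with complete separation are flagged and their p suppressed.
    """
    import statsmodels.api as sm

    post = np.asarray(post, dtype=float)
    base = np.asarray(baseline, dtype=float)
    groups = np.asarray(group_labels)
    codes = pd.Categorical(groups).codes.astype(float)
    ok = ~(np.isnan(post) | np.isnan(base))
    post, base, codes = post[ok], base[ok], codes[ok]
    n = len(post)
    name = "baseline_adjusted_logistic" if binary else "baseline_adjusted_linear"
    if n < min_n:
        return GroupComparison(metric, ("group0", "group1"), name, None, None, None, n, True)
    X = sm.add_constant(np.column_stack([codes, base]))
    if binary:
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(post, X).fit(disp=0, maxiter=200)
            coef = float(fit.params[1])
            if not fit.mle_retvals.get("converged", True) or abs(coef) > 30:
                raise np.linalg.LinAlgError("separation")
            ci = tuple(fit.conf_int()[1])
            return GroupComparison(
                metric, ("group0", "group1"), name, float(fit.tvalues[1]), None,
                float(fit.pvalues[1]), n, coefficient=coef, ci=ci,
            )
        except Exception:
            return GroupComparison(
                metric, ("group0", "group1"), name, None, None, None, n,
                suppressed=True, flag="separation",
            )
    fit = sm.OLS(post, X).fit()
    ci = tuple(fit.conf_int()[1])
    return GroupComparison(
        metric, ("group0", "group1"), name, float(fit.tvalues[1]),
        float(fit.df_resid), float(fit.pvalues[1]), n,
        coefficient=float(fit.params[1]), ci=ci,
    )


# ---------------------------------------------------------------------------
# Table export
# ---------------------------------------------------------------------------

_TABLE_ROWS = [
    ("SPW", "occurrence_per_30min", "Occurrence (/30 min)"),
    ("SPW", "max_frequency_per_min", "Maximum frequency (/min)"),
    ("SPW", "mean_duration_s", "Average pressure duration (s)"),
    ("SPW", "mean_distance_cm", "Propagation distance (cm)"),
    ("SPW", "mean_amplitude_mmhg", "Average amplitude (mmHg)"),
    ("APW", "occurrence_per_30min", "Occurrence (/30 min)"),
    ("APW", "max_frequency_per_min", "Maximum frequency (/min)"),
    ("APW", "mean_duration_s", "Average pressure duration (s)"),
    ("APW", "mean_distance_cm", "Propagation distance (cm)"),
    ("APW", "mean_amplitude_mmhg", "Average amplitude (mmHg)"),
    ("RPW", "occurrence_per_30min", "Occurrence (/30 min)"),
    ("RPW", "max_frequency_per_min", "Maximum frequency (/min)"),
    ("RPW", "mean_duration_s", "Average pressure duration (s)"),
    ("RPW", "mean_distance_cm", "Propagation distance (cm)"),
    ("RPW", "mean_amplitude_mmhg", "Average amplitude (mmHg)"),
    ("transients", "max_amplitude_mmhg", "Maximum amplitude (mmHg)"),
    ("transients", "pct_sensors_involved", "Percentage of sensors involved"),
    ("transients", "pct_time_involved", "Percentage of time involved"),
    ("transients", "pct_amp_lt_50", "Percentage with amplitude < 50 mmHg"),
    ("transients", "pct_amp_50_100", "Percentage with amplitude 50-100 mmHg"),
    ("transients", "pct_amp_gt_100", "Percentage with amplitude > 100 mmHg"),
    ("presence", "hapw_present", "HAPW occurrence (%)"),
    ("presence", "shpw_present", "SHPW occurrence (%)"),
]


def _cell(values: list[float]) -> str:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return "- (0)"
    arr = np.asarray(vals, dtype=float)
    sd = arr.std(ddof=1) if len(arr) > 1 else 0.0
    return f"{arr.mean():.1f} ± {sd:.1f} ({len(arr)})"


def _presence_cell(flags: list[bool]) -> str:
    if not flags:
        return "- (0)"
    k = sum(flags)
    return f"{k} ({100.0 * k / len(flags):.1f}%) ({len(flags)})"


def export_table(
    cohort: list[tuple[str, str, dict[str, SessionSummary]]],
    out=None,
) -> pd.DataFrame:
    """Assemble the pattern-by-phase cohort table (mean +/- SD with n).

    ``cohort`` holds (subject_id, group, {phase: SessionSummary}) triples;
    columns are group x phase, deterministically ordered.  Written as TSV
    when ``out`` is given.
    """
    groups = sorted({g for _, g, _ in cohort})
    phases = sorted({ph for _, _, s in cohort for ph in s})
    columns = [(g, ph) for g in groups for ph in phases]
    rows = []
    for section, attr, label in _TABLE_ROWS:
        row: dict = {"pattern": section, "metric": label}
        for g, ph in columns:
            summaries = [s[ph] for _, gg, s in cohort if gg == g and ph in s]
            if section == "presence":
                flags = [getattr(s, attr) for s in summaries]
                row[f"{g}:{ph}"] = _presence_cell(flags)
            elif section == "transients":
                vals = [getattr(s.transients, attr) for s in summaries if s.transients]
                row[f"{g}:{ph}"] = _cell(vals)
            else:
                vals = [getattr(s.patterns[section], attr) for s in summaries]
                row[f"{g}:{ph}"] = _cell(vals)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if out is not None:
        frame.to_csv(out, sep="\t", index=False)
    return frame
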