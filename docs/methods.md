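# Methods

This note documents the models, estimators and design choices behind
`colomotor`, in the spirit of a methods appendix: what is computed, under
which assumptions, and where the genuinely open choices were made.

## Signal model and baseline

A recording is a sensors × samples matrix of intraluminal pressures
(mmHg), sensors indexed 1..36 distal → proximal at 1-cm spacing, sampled
at a configurable rate (default 10 Hz — sufficient to resolve 2.5-s events
and onset staircases up to the 7 cm/s resolution bound at 1-cm spacing;
acquisition hardware rates vary and the true rate is read from the
sidecar). Time is seconds from recording start; all windows are half-open
`[start, end)`.

Amplitudes are read *above baseline*. The baseline is a rolling 10th
percentile (60-s centred window) of the lightly smoothed trace (0.5-s
moving average). The percentile baseline is unaffected by transients much
shorter than half the window and follows slow drift with at most a window
of lag; the smoothing suppresses sampling noise without distorting events
of physiological duration (≥ 2 s). On pure-noise recordings with noise SD
up to 1.5 mmHg this combination leaves the effective detection threshold
more than 6 noise SDs above the baseline, which is why noise-only
scenarios produce zero events (verified in the test suite).

## Transients and events

Per-sensor transients are threshold crossings of (pressure − baseline) at
5 mmHg. Onset and offset are placed at the 25%-of-peak crossings found by
walking outward from the peak with sub-sample linear interpolation; the
25% rule is a robust operationalisation of "initial rise", and the
interpolation is what makes velocity estimates accurate at 0.1-s sampling.
Crossings may lie outside the threshold run (low peaks) or inside it
(high peaks); both are handled by the peak-outward walk. Events separated
by less than 2 s on the same sensor are merged.

Transients on adjacent sensors whose onsets differ by ≤ 2 s are chained
into multi-sensor candidates; matching across each sensor boundary is
one-to-one (nearest onset first) so rhythmic trains on fixed sensors are
not fused. Every transient belongs to exactly one candidate.

**Velocity.** For candidates covering ≥ 3 sensors, onset time is
regressed on sensor position. The slope is the Theil–Sen median slope
(robust to single-sensor onset outliers); the flatness test is the OLS
p-value, because an exact rank test cannot reach significance at n = 3
and would wrongly force every 3-sensor wave to "simultaneous". Antegrade
(toward the anus, decreasing sensor index) is positive. A fitted speed
above 7 cm/s, or a flat fit (p ≥ 0.05), is reported as *simultaneous* —
the physical resolution bound of onset staircases on a 1-cm array.

**Classification order** (mutually exclusive, exhaustive): single sensor
→ isolated transient; ≥ 3 sensors at ≥ 100 mmHg with measurable velocity
→ HAPW; simultaneous ∧ duration ≥ 2.5 s ∧ span ≥ 14 cm → SPW; measurable
velocity over ≥ 3 adjacent sensors → APW/RPW by sign; anything else falls
back to per-sensor isolated transients. The 14-cm SPW span floor
operationalises "most or all sensors": it equals the smallest
simultaneous-wave extent observed clinically (span range 14–35 cm) and is
configurable. Event duration is the median of member-sensor durations
(the reference-sensor convention is not standardised; the median is
robust and a single-sensor read-out remains available through the member
transients). Mean amplitude is pressure-above-baseline at the event's
temporal centre averaged over member sensors — the automated version of
placing a cursor at the wave's centre.

## Sphincter association and artifact screening

During a sphincter pull-back phase the one or two most distal functional
channels with a resting tone > 20 mmHg are treated as the internal anal
sphincter. The local resting tone before an event is the **75th
percentile of the preceding 60 s** rather than a median: with rhythmic
SPWs 30–60 s apart, relaxation dips can occupy more than half of a short
pre-event window and a median would track the dip instead of the tone.
An SPW is relaxation-associated when sphincter pressure falls ≥ 20% below
tone within `[onset − 5 s, offset]`.

Artifact defence is two-layered. Observer annotations become exclusion
intervals (±3 s; ±10 s for body shifts and repositioning); gas expulsion
is *not* an artifact — it accompanies SPWs, and the pipeline reports both
the fraction of SPWs with gas and the converse (fraction of gas reports
with a matching SPW). For unannotated data, any near-simultaneous
candidate spanning at least half the functional sensors is screened: a
sphincter **rise ≥ 5 mmHg** during the event marks it abdominal, a
relaxation dip marks it colonic, otherwise undetermined; without a
sphincter channel a cough-morphology rule applies (duration < 2.5 s and
rise time < 1 s → abdominal). The +5 mmHg rise criterion is a documented
choice — no numeric criterion is established clinically. Talking
(~5 mmHg) and drinking (~10 mmHg) are too weakly characterised for signal
detection and are handled via annotations only.

## Haustral analysis

Per-sensor transient onsets are binarised into 1-s bins; the dominant
rhythm in the 1–6 cycles/min band is the periodogram peak (8× zero-padded
for sub-bin peak location), accepted only when it exceeds the 95th
percentile of peak powers from rate-preserving shuffles (200 shuffles,
fixed seed). Spike trains carry strong harmonics of their event rate, so
a subharmonic guard replaces the argmax by its half-frequency when that
peak holds ≥ 50% of the power. Windows under 5 min leave rhythmicity
undetermined. A memoryless (Poisson) train of the same rate is called
rhythmic in ≤ ~5–10% of runs — the calibration of the shuffle null.

Boundary sensors are local rate maxima at ≥ 3× the mean rate of the
sensors between them; a boundary set is accepted when ≥ 3 such maxima are
regularly spaced (CV ≤ 0.35) at 2–8 cm. Persistence is re-evaluated in
30-min blocks (clinically boundaries persist 30–180 min).

Intrahaustral windows (2–5 adjacent sensors; between detected boundaries,
or sliding 5-sensor windows when none exist) are labelled per 60-s block
— the shortest block holding ≥ 3 cycles of a 3 cycles/min rhythm. Traces
are band-passed to 1–6 cycles/min (2nd-order zero-phase Butterworth,
60-s context padding) and compared pairwise by peak normalised
cross-correlation within ±10-s lags: mean pairwise r̄ ≥ 0.6 →
*synchronized* (velocity and direction from the lag–position fit; speeds
beyond 7 cm/s reported simultaneous-within-haustrum); ongoing but
uncorrelated activity → *segmentation*; total transient rate < 0.5/min →
*quiescent*. The r̄ = 0.6 / 10-s-lag thresholds are simulator-calibrated
(clinically this distinction is made by eye) and exposed in
configuration. Runs of synchronized blocks ≥ 120 s form episodes
(clinically 2–10 min, 1–3 per session); episode direction is
antegrade/retrograde when ≥ 70% of block velocities agree in sign, else
*mixed* — no numeric criterion for "mixed" exists, 70% is the documented
choice. The labelling is invariant to per-sensor offsets and global
positive rescaling (correlations are normalised and the baseline is
subtracted).

## Session summaries and statistics

Occurrence is events × 1800 / unmasked phase seconds; masked (artifact)
time is removed from every per-time denominator. Maximum frequency is
60/mean-interval of the fastest window of ≥ 3 consecutive inter-onset
intervals with CV ≤ 0.25 — "sustained rhythmicity" is not numerically
defined clinically; these constants are the documented choice, and the
result is invariant to events outside the rhythmic run. Isolated-transient
"% sensors involved" always divides by 36 (the convention even when
sensors malfunction); "% time involved" is summed transient duration over
unmasked phase time, averaged over functional sensors (an alternative —
fraction of active 1-min bins — is deliberately not the default since the
summed-duration reading matches per-sensor percentages); the three
amplitude-category percentages are computed over active sensors, and one
sensor may count in several categories, so they may sum to over 100%.

Comparisons: two-sided paired t (within subject, complete pairs),
independent t (between groups at baseline), exact McNemar (two-sided
exact binomial on discordant pairs — exact rather than chi-square because
cohort sizes are ~15), Fisher exact, and baseline-adjusted linear or
logistic regression with the post-meal value as outcome and group +
baseline as covariates (age deliberately not adjusted; logistic
separation is flagged and its p suppressed). Any comparison with n < 5 is
suppressed entirely. McNemar and Fisher are cross-checked in the test
suite against independent enumeration oracles on all tables with margins
≤ 10.

## Synthetic recordings

The generator writes events into a Gaussian-noise buffer (default SD
1 mmHg over a 5-mmHg resting tone — no noise characterisation of the
acquisition chain is published, so a single additive model is used) and
records every event in a ground-truth list. Determinism is bit-exact for
a fixed seed.

* **SPW**: raised-cosine rise to ~20 mmHg in ~8 s, exponential return
  shaped to reach zero at ~12 s (below 5% beforehand); the decay shape is
  a free choice — only the time scales and "irregular" character are
  established. 1–3 Gaussian bumps ride the *early* decay limb (while the
  decaying pressure is still above the detection floor), capped below the
  peak, reproducing superimposed peaks on the downward slope without
  fragmenting into spurious single-sensor events. A configurable fraction
  of SPWs (default 9/32, the characterised proportion, drawn as an exact
  count) emits a gas-expulsion annotation at the wave peak.
* **Propagating waves**: raised-cosine pulses with per-sensor onsets
  staircased at the signed velocity; amplitude profiles per sensor;
  ≥ 100 mmHg on ≥ 3 sensors is ground-truthed as HAPW.
* **Isolated transients**: log-normal amplitudes (median 30 mmHg, σ=0.8)
  clipped to 8–230 mmHg — only the clinical range (5–230) is known, the
  distribution is a documented choice; the lower clip sits 3 noise SDs
  above threshold so ground truth remains detectable by construction.
* **Haustral boundaries**: gamma-interval trains (CV = jitter) at
  non-adjacent sensors, quiet in between.
* **Intrahaustral schedule**: synchronized episodes are coherent cycles
  with lag = spacing/velocity, direction fixed or per-cycle random
  (*mixed*); segmentation episodes draw independent per-sensor Poisson
  trains with sensor-specific rates (2–5/min) and erratic amplitudes —
  the rate heterogeneity is what makes erratic activity decorrelate in
  the 1–6 cycles/min band, as in real segmentation.
* **Artifacts**: cough = sharp all-sensor spike (< 1.5 s); body shift =
  broad low-amplitude elevation plus sustained single-sensor offsets;
  talk ≈ 5 mmHg; drink ≈ 10 mmHg. Cough and body shift *pressurize* the
  sphincter channels.
* **Sphincter**: during a pull-back phase the two most distal channels
  (the convention when the catheter is withdrawn to the anal canal) carry
  a 40-mmHg resting tone, relax by 60% of tone starting 2 s before an
  arriving SPW, and colonic waves stop short of the sphincter channels —
  the sphincter records the relaxation, not the wave itself.
* **Meal response**: per-phase rate multipliers (rate changes are what is
  reported; no mechanism is modelled).

What the generator does **not** emulate: respiration and slow vascular
rhythms, probe-movement baseline wander, content/fecal load, non-Gaussian
sensor noise, and catheter repositioning. Passing tests therefore
demonstrate correctness of the pipeline's logic under the stated signal
model, not robustness to every artifact of real acquisitions.

## Problem sizes and determinism

Test and acceptance scenarios use 6–22-min sessions at 10 Hz, 20 seeds
for stochastic claims, a 50-case noise-free classification grid, 1000
null replicates for the paired-t calibration, and enumeration oracles
over all exact-test tables with margins ≤ 10 — sizes chosen so the whole
suite completes in a few minutes while keeping binomial error bars well
inside the asserted margins. All randomness flows through explicit seeds;
the acceptance script derives every scenario seed from its `--seed`
argument.

## Known limitations

* Velocity is a single straight-line fit per event; waves that accelerate
  or reverse mid-course are summarised by one slope (an HAPW continuing
  as an SPW splits only if the onset chain breaks).
* Haustral windows are fixed over the analysis range; boundaries that
  migrate mid-recording blur the state labels near the move.
* The signal-based artifact screen needs either a sphincter channel or
  cough-like morphology; slow abdominal straining without annotations is
  not caught.
* The exact McNemar mid-p variant is not implemented; the classical
  two-sided exact binomial is used.
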