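# colomotor

Automated detection, classification and quantification of intraluminal
pressure patterns in **high-resolution colonic manometry (HRCM)** — the
36-sensor, 1-cm-spacing solid-state catheter recordings used to assess
colonic motor function in chronic constipation and its controls.

Clinically these recordings are still read by eye on spatiotemporal
pressure maps. `colomotor` turns that reading into a tested pipeline for
researchers and motility-lab analysts:

* **Event taxonomy.** Per-sensor pressure transients (≥ 5 mmHg above a
  rolling-percentile baseline) are chained across adjacent sensors and
  classified as:
  * **SPW** — simultaneous pressure wave: ≥ 2.5 s, ≥ 5 mmHg, occurring at
    once over most or all of the 35-cm array. Velocity cannot be resolved
    beyond ~7 cm/s on a 1-cm array, so a fitted speed above that bound (or
    a statistically flat onset–position fit) is reported as
    *simultaneous*. SPWs are the dominant propulsive pattern, associated
    with gas expulsion and internal-anal-sphincter relaxation.
  * **APW / RPW** — antegrade / retrograde propagating pressure wave:
    5–100 mmHg over ≥ 3 adjacent sensors with measurable velocity
    (onset time regressed on sensor position, Theil–Sen slope; antegrade =
    toward the anus = positive velocity).
  * **HAPW** — high-amplitude propagating wave: ≥ 100 mmHg in ≥ 3 sensors.
  * **Isolated pressure transient** — confined to a single sensor
    (5–230 mmHg).
* **Artifact screening.** Abdominal-pressure events (cough, body shift,
  talking, drinking) are excluded via observer annotations and, for global
  simultaneous pressurizations, via the sphincter rule: artifacts
  *pressurize* the internal anal sphincter whereas colonic waves *relax*
  it ahead of their arrival.
* **Haustral activity.** Rhythmic boundary transients at sensors 3–8 cm
  apart (~3 cycles/min), and intrahaustral windows of 2–5 sensors labelled
  per 60-s block as erratic *segmentation* or *synchronized haustral
  pressure waves* (coherent cycles at ~3 cycles/min propagating at
  ~2 cm/s), merged into 2–10-min episodes with direction statistics.
* **Cohort statistics.** Per-phase session summaries (occurrence /30 min
  of unmasked time, maximum sustained frequency, duration, propagation
  distance, amplitude, isolated-transient metrics, HAPW/SHPW presence) and
  the standard comparisons: paired t, independent t, exact McNemar, Fisher
  exact, and baseline-adjusted linear/logistic regression (suppressed at
  n < 5).
* **Synthetic recordings.** A ground-truthed generator reproduces every
  waveform class, rhythm, artifact and sphincter behaviour so the whole
  pipeline is testable without patient data.

## Worked example

```python
from colomotor import detect_events, summarize_session
from colomotor.detection import events_to_frame
from colomotor.evaluation import benchmark_scenario
from colomotor.synthetic import generate_recording

config = benchmark_scenario(seed=1)          # 7-min session, all five classes
recording, truth, annotations = generate_recording(config)
result = detect_events(recording, annotations=annotations)
print(events_to_frame(result.events).head(6).to_string(index=False))
```

```
              kind  onset_s  duration_s  span_cm     velocity  amplitude_mean  amplitude_max  first_sensor  last_sensor
isolated_transient   30.404       2.685      0.0                        31.14          32.92             4            4
               APW   56.695       4.753     14.0         5.05           26.16          34.17            10           24
              HAPW   82.644       4.709      9.0          1.5           67.12         139.73             6           15
isolated_transient  108.408       2.652      0.0                       152.93         161.31             7            7
               APW  134.582       4.748     14.0        4.915           26.31          35.33            10           24
               SPW  162.339      11.065     35.0 simultaneous           19.81          31.86             1           36
```

Every injected event is recovered with its class: the APW at 56.7 s is
read at 5.05 cm/s (truth 5.0), the HAPW reaches 139.7 mmHg over sensors
6–15, and the SPW at 162.3 s spans the full 35 cm with no resolvable
velocity. Summarising the session:

```python
summaries = summarize_session(result.events, [], recording.phases,
                              result.mask, recording.sampling_rate)
s = summaries["baseline"].patterns["SPW"]
print(f"SPW occurrence: {s.occurrence_per_30min:.1f} /30 min; "
      f"mean span {s.mean_distance_cm:.1f} cm; "
      f"mean amplitude {s.mean_amplitude_mmhg:.1f} mmHg")
```

```
SPW occurrence: 17.1 /30 min; mean span 35.0 cm; mean amplitude 17.1 mmHg
```

i.e. four SPWs in the 7-min session (17.1 per 30 min), all covering the
full array, with a mean centre amplitude of 17.1 mmHg — within the range
reported for patient sessions.

A command-line interface mirrors the library:

```bash
colomotor simulate --scenario scenario.yaml --seed 1 --out session/
colomotor detect session/recording.csv --annotations session/annotations.tsv --out events.tsv
colomotor haustral session/recording.csv --window 28 32 --out states.tsv
colomotor render session/recording.csv --from 0 --to 600 --out map.png
```

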