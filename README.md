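# tpear — gait event detection from ear-worn IMUs

`tpear` detects gait events — initial contact (IC, heel strike) and terminal
contact (TC, foot-off) — from a 6-axis inertial sensor worn at the ear, and
derives per-cycle temporal gait parameters from them.  Ear-worn IMUs are an
attractive platform for clinical gait assessment (hearing aids and earbuds
already house accelerometers, and the head tracks the centre of mass well),
but complex tasks such as walking with head turns or turning on the spot
disrupt the mediolateral (ML) acceleration that classical ear-worn detectors
rely on.  The package is aimed at movement-analysis researchers and
engineers who need event-level timing from earables under such tasks.

## What it implements

Two detectors share a common preprocessing stack (CSV trial I/O with a
dropped-sample quality screen and cubic-spline gap repair, axis remapping to
a superior–inferior / mediolateral / anterior–posterior frame):

* **SSA baseline (Diao, with Seifer's laterality refinement).**  Singular
  spectrum analysis — SVD of the Hankel trajectory matrix with anti-diagonal
  averaging, embedding window 2 s (1 s for trials under 4 s) — splits each
  channel into trend, dominant oscillation and residual.  Peaks of the
  dominant SI oscillation are ICs; the step side comes from the sign of the
  dominant ML slope at the IC (rising = left); the TC is the next extremum of
  the trend-removed ML signal, polarity chosen by the side.
* **TP-EAR (Temporal Parameters from the EAR).**  The SI channel is band-pass
  filtered 0.5–12 Hz; for every dominant-SI peak a trusted window opens at
  the 80 %-of-peak crossing before the peak and closes at the next dominant
  minimum.  Peaks of the windowed filtered signal are counted: two peaks →
  IC/TC; more than two → IC = closest to the dominant peak, TC = latest
  positive peak; one peak → peak sharpening, then a minimum-gradient
  fallback.  Because TCs come from the SI channel, lateral head movement does
  not degrade them.

Around the detectors: an error-state Kalman attitude filter providing the
yaw track ψ(t); turn segmentation by the thresholds |ψ| > 15°, |ψ̇| > 30 °/s
(start) and |ψ| ≥ |ψ|max − 5° (end); temporal parameters

    stride = (IC_end − IC_start)/fs,  stance = (TC − IC_start)/fs,
    swing  = (IC_end − TC)/fs;

an evaluation protocol (one-to-one event matching within 300 ms, sensitivity,
laterality accuracy, absolute/signed error statistics); and a synthetic
trial generator with exact ground truth for all of the above.

## Worked example

```bash
tpear simulate --seed 5 --out-trial trial.csv --out-truth truth.csv
tpear detect --algo tpear --input trial.csv --output events.csv
tpear params --events events.csv --output cycles.csv
tpear evaluate --truth truth.csv --detected events.csv --report report.json
```

which prints

```
wrote 2357 samples, 80 events
84 events written to events.csv
40 cycles written to cycles.csv
{"IC": 100.0, "TC": 100.0}
```

The simulated trial holds 20 strides per foot (80 true events) at 100 Hz.
TP-EAR finds every IC and TC within the 300 ms criterion (sensitivities
100 %), plus a few unmatched extras at the bout edges.  `cycles.csv` starts

```
side,ic_start,tc,ic_end,stride_s,stance_s,swing_s
L,100,166,210,1.1,0.66,0.44
```

— a left gait cycle of 1.10 s stride with 0.66 s stance and 0.44 s swing
(the generator's programmed 60 % stance fraction), and `report.json` shows
stride errors of 0 ms and stance/swing mean errors below 1 ms.

The same pipeline is available as a library:

```python
from tpear import (GaitSimConfig, simulate_trial, detect_events_tpear,
                   match_events, sensitivity)

trial, truth = simulate_trial(GaitSimConfig(seed=5))
events = detect_events_tpear(trial)
match = match_events(truth.events, events, fs=trial.fs)
print(sensitivity(match, "IC"), sensitivity(match, "TC"))  # 100.0 100.0
```

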