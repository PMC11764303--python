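# edastress

Electrodermal-activity (EDA / galvanic skin response, GSR) stress
analysis for short wearable-sensor recordings.

Skin conductance, measured in microsiemens (µS) between two finger
electrodes, rises transiently when the sympathetic nervous system fires
— each transient is a *skin-conductance response* (SCR). `edastress`
implements the full chain from a microcontroller's raw ADC counts to a
per-subject stress verdict:

1. **Device model** — a 10-bit ADC reading `au` becomes a voltage
   `Vx = au·λ` with `λ = V/1024 = 0.0048828125 V` (5 V supply). The
   sensor is a voltage divider with a fixed `R = 500 kΩ` in series with
   the skin resistance `X`, so `I = (V − Vx)/R`, `X = Vx/I` and the
   conductance `Y = 1/X`.
2. **Preprocessing** — validity screening against the physiological
   1–20 µS band (open-air contact faults read ≈0.93 µS), and a phasic /
   tonic split by subtracting the local ±4 s average.
3. **SCR detection** — onsets and peaks from smoothed local extrema
   with a 0.05 µS (optionally 0.01 µS) onset amplitude criterion,
   refined by a canonical-SCR template fit; each event is characterized
   by latency class (ER-SCR when onset follows the stimulus by 1–5 s),
   peak amplitude (peak minus onset), rise time, full width at half
   amplitude, and 50 %-recovery time (censored when the recording ends
   first).
4. **Categorization** — each trace becomes `stressed`, `not_stressed`
   or `invalid` via pattern, magnitude and peak-count rules; cohorts
   are summarized as counts and half-up integer percentages.
5. **ML layer** — per-trace features (peak amplitude, peak width, mean
   GSR, amplitude−mean, phasic maximum, each also min–max normalized),
   K-means (k=2) stressed/relaxed pseudo-labeling, and SVM / NuSVM
   classification (linear and RBF kernels, γ=2.0 default, ν ∈ (0,1))
   with grid search under 5-fold cross-validation; precision, recall,
   F1 and accuracy from first-principles confusion counts.
6. **Synthetic cohorts** — a generator producing labeled traces
   (tonic 2–8 µS, SCR bumps with 1–5 s latency, 0.2–3 µS amplitude,
   5–35 s linear rise, slower exponential recovery, 0.02 µS noise,
   120 s at one sample per 2 s) plus the inverse conductance→ADC
   mapping, so the entire pipeline is testable offline with ground
   truth.

## Worked example

```python
from edastress import (SCRShape, simulate_trace, phasic_component,
                       detect_events, validity_flags, categorize_trace)

shape = SCRShape(stimulus_time=10, latency=3, amplitude=1.8,
                 rise_time=20, recovery_half_time=30)
sim = simulate_trace([shape], tonic_baseline=4.0, noise_sd=0.02, seed=11)
phasic = phasic_component(sim.trace)
events = detect_events(sim.trace, phasic, stimulus_time=10.0)
cat = categorize_trace(sim.trace, events, validity_flags(sim.trace))
```

prints (via the fields of `events[0]` and `cat`):

```
events detected : 1
onset           : 14 s at 4.01 uS
peak            : 32 s at 5.79 uS
amplitude       : 1.79 uS  (injected 1.80)
rise time       : 18 s    (injected 20)
recovery time   : 30.6 s (injected half-time 30)
latency class   : ER_SCR (latency 4 s)
category        : stressed -- 1 qualifying SCR(s); largest amplitude 1.79 µS at t=32 s
```

The detector recovers the injected amplitude to 0.01 µS and the onset
to within the 2 s sampling grid; the onset landing 4 s after the
stimulus puts the event in the 1–5 s event-related window. The
exponential recovery's half-life (30 s) is exactly what the
50 %-recovery time estimates (30.6 s from noisy samples).

The same flow is available from a shell:

```sh
edastress simulate --n-stressed 36 --n-calm 12 --n-invalid 3 --seed 7 --out cohort/
edastress analyze cohort/ --report report.json --plots figs/
edastress ml --features features.csv --kernel rbf --gamma 2.0
```

`analyze` prints the cohort split, e.g.
`51 traces: 71% stressed, 24% not stressed, 6% invalid`.

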