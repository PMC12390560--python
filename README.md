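# tenssim

A desk-scale digital twin of a wearable, EMG-triggered closed-loop TENS
(transcutaneous electrical nerve stimulation) device, for engineers and
researchers who want to study sEMG-triggered neuromodulation control
without hardware on the bench.

Closed-loop TENS fires stimulation when the user's own muscle activity is
detected: surface EMG is amplified (G = 100, CMRR > 80 dB), band-passed
20–500 Hz, digitized at 12 bit / 1 kHz, smoothed into a sliding-RMS
envelope, and compared against a threshold (0.3 mV electrode-referred).
A detection triggers charge-balanced biphasic current pulses on up to six
channels, powered by a PI-controlled boost converter that steps a 3.7 V
cell up to ≤100 V. `tenssim` simulates every stage of that loop and
provides the evaluation harness that turns simulations into the metrics
such devices are judged by:

* **detection** — ROC/AUC, sensitivity and specificity of the RMS
  threshold detector on an annotated synthetic EMG benchmark;
* **latency** — the detection-point → stimulation-onset delay,
  composed from a calibrated per-stage timing model
  (mean 9.4 ms, sd ≈ 0.7 ms);
* **power regulation** — settling time and steady-state deviation of the
  averaged boost model `dI/dt = (V_in − (1−d)V)/L`, `dV/dt = ((1−d)I − V/R)/C`
  under load steps, with the PI law `d = clamp(Kp·e + Ki·∫e)`;
* **stimulation integrity** — charge balance, inter-channel leakage
  through a calibrated resistive coupling matrix, voltage compliance;
* **deployment arithmetic** — battery-runtime projections and the paired
  study-design sample size `n = ceil(((z_{1−α} + z_{1−β})/d)²)`.

## Worked example

```python
import numpy as np
from tenssim import (
    BurstSpec, NoiseSpec, synthesize_emg,          # signal in
    run_trial, run_latency_study, latency_stats,   # closed loop
    PiConfig, PlantParams, LoadProfile,
    simulate_boost, settling_metrics,              # power supply
)

# one voluntary activation burst, 1.2 mV over a 0.05 mV baseline
rec = synthesize_emg(
    BurstSpec(onset_times=(1.0,), durations=(0.8,), peak_amplitude=1.2),
    NoiseSpec(baseline_rms=0.05),
    duration=2.5, seed=101,
)
trial = run_trial(rec, seed=1)
print(f"latency {trial.latency_ms:.2f} ms")

stats = latency_stats(run_latency_study(n_trials=100, base_seed=42))
print(f"study: mean {stats['mean']:.2f} ms, sd {stats['sd']:.2f} ms, "
      f"normality p {stats['normality_p']:.2f}")

cfg = PiConfig(setpoint=80.0)                       # Kp 0.15, Ki 0.02
step = LoadProfile(breakpoints=(0.0, 0.05), resistances=(10_000.0, 500.0))
trace = simulate_boost(PlantParams(), cfg, step, duration=0.2)
settle, dev, _ = settling_metrics(trace, 0.05, cfg)
print(f"boost: settling {settle*1e3:.1f} ms, deviation {dev*100:.2f} %")
```

prints

```
latency 9.90 ms
study: mean 9.43 ms, sd 0.65 ms, normality p 0.59
boost: settling 0.0 ms, deviation 0.63 %
```

The trial latency is one draw from the calibrated stage-delay model; the
100-trial study recovers its mean and spread, and the Shapiro–Wilk p-value
says the sample is consistent with a normal distribution. The boost
converter, hit with a 10 kΩ → 500 Ω load step at 50 ms, never leaves the
±2.5 V band around 80 V (settling 0 ms) and holds a 0.63 % steady-state
deviation.

The same workflows are available from the shell:

```bash
tenssim run-loop --trials 100 --seed 42 --out latencies.csv
tenssim boost-sim --setpoint 80 --load-step 10000:500@0.05 --out trace.csv
tenssim stim-render --channels 6 --amp-ma 22 --phase-us 2000 --out wf.csv
tenssim evaluate roc --sessions 10 --users 2 --out score.json
tenssim evaluate power --duty 0.4 --active-ma 95 --idle-ma 11.67
tenssim evaluate design --d 0.6 --alpha 0.05 --power 0.8 --tails one
```

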