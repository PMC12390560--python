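# Methods

`tenssim` is a desk-scale digital twin of a wearable, sEMG-triggered
closed-loop TENS device: synthetic surface EMG goes in; simulated
acquisition, detection, power regulation and stimulation come out; the
package's metrics (latency, settling, leakage, ROC, battery life) are the
verification surface. This note records the models, the calibrations, and
the choices made where the design was genuinely open.

## Synthetic sEMG (`tenssim.emg`)

A recording is a sum of electrode-referred terms (mV):

* **baseline** — Gaussian noise band-limited to the 20–500 Hz sEMG band by a
  zero-phase 4th-order Butterworth band-pass, scaled to `baseline_rms`.
  Band-limited (not white) so the acquisition chain attenuates baseline and
  bursts alike and electrode-referred SNR survives to the detector.
* **bursts** — envelope × band-limited Gaussian carrier, one independent
  substream per burst. Envelopes are trapezoids (10 % ramps) or Hann
  windows; each burst is renormalized so its whole-burst RMS hits its
  target exactly, which makes burst RMS exactly linear in amplitude and
  lets the benchmark control per-burst SNR without sampling error.
* optionally mains hum (sine at `line_freq`) and sub-10 Hz random-walk
  motion transients at `artifact_rate` (default 0: bench conditions).

Native rate 4 kHz (8× the upper band edge); annotations are exact
`[onset, offset)` intervals by construction. Identical spec + seed gives
bit-identical samples (`numpy` `SeedSequence` spawning).

**Benchmark** (`generate_benchmark`): 20 one-second bursts per session,
~3 s apart with ±0.3 s jitter, sessions split round-robin over users; each
user carries one log-normal amplitude scale (σ = 0.10) applied to the whole
recording, emulating electrode/tissue gain differences between people.
Profiles:

| profile | per-burst SNR (dB) | baseline RMS |
|---|---|---|
| `clean` | N(20, 1) | 0.15 mV |
| `paper-bench` | N(6, 2) | 0.15 mV |

The `paper-bench` SNR mean and the user-scale σ are **calibrations, not
derivations**: the bench recordings behind the reported detection figures
were never published, so the profile is tuned once so the default
detector's benchmark AUC centres near 0.94 (observed 0.93–0.96 over
seeds). At this operating point the Youden sensitivity/specificity land in
the mid-80s to low-90s. What passing these tests shows is that the scoring
machinery reproduces the reported discrimination *on a corpus built to be
that discriminable* — not that real wrist-extension EMG is.

The generator has no motor-unit structure (no MUAP trains), no electrode
impedance model, and no multi-muscle spatial mixing.

## Acquisition front-end (`tenssim.frontend`)

* Instrumentation amplifier: `out = G·diff + (G/10^(CMRR/20))·cm`,
  G = 100 V/V, CMRR 80 dB.
* Band-pass 20–500 Hz: two cascaded Butterworth biquads (2nd-order
  high-pass + 2nd-order low-pass, bilinear transform). The hardware's
  Sallen-Key stages fix topology and corners but not Q; Butterworth
  (Q = 0.707) is the standard maximally-flat reading. Loop-path filtering
  is causal — latency must include real group delay; zero-phase filtering
  exists only in offline analysis utilities.
* ADC: 6th-order Butterworth anti-alias at 0.45 × 1 kHz, integer
  decimation to 1 kHz, mid-rise quantization to 12 bits over a bipolar
  ±vref/2 range about a mid-supply virtual ground (the single-supply
  convention). `codes_to_mv` divides the gain back out: **detection
  thresholds are electrode-referred mV** (the 0.3 mV threshold is read as
  an electrode-referred quantity; the post-gain alternative would be
  30 mV at the ADC pins).

## Event detection (`tenssim.detector`)

Causal moving average (5 samples) → causal sliding RMS (5 samples) →
upward-crossing threshold with 0.5 s refractory. Event time is the first
sample at/above threshold, as a sample-clocked MCU would report. Window
lengths and refractory are not documented for the hardware; 5 ms windows
keep the envelope lag consistent with a sub-10 ms loop budget, and 0.5 s
refractory prevents re-triggering within one burst.

The adaptive variant (threshold = trailing-window mean + k·sd, window
excluding samples above the current threshold) is provided as an optional
mode. Note a small liberal bias: excluding above-threshold samples trims
the right tail of the baseline estimate, so on stationary noise its
false-positive rate can slightly exceed a fixed threshold set at the true
mean + k·sd. Its value is drift immunity, which the tests exercise
directly.

## Boost converter (`tenssim.boost`)

Averaged continuous-conduction model, RK4 at 1 µs, controller at 10 kHz:

    dI/dt = (V_in − R_s·I − (1−d)·V) / L
    dV/dt = ((1−d)·I − V/R_load) / C

with the inductor current floored at zero (discontinuous-conduction
guard). Switching ripple is out of scope — the bench claims checked here
(settling ≤ 20 ms, steady-state deviation < 3 %) are envelope-level. The
PI uses the printed gains (Kp = 0.15 duty/V, Ki = 0.02 duty/V·s) on the
output-referred voltage error, with conditional-integration anti-windup.

Two consequences of those gains drove the remaining design:

1. **Integrator preset.** Boosting 3.7 V to 80 V needs duty ≈ 0.954. At
   Ki = 0.02 an integrator starting from zero would need ~30 V·s of
   accumulated error (hundreds of seconds) to supply it. The controller
   therefore presets the integrator to the feedforward operating duty,
   `(1 − V_in/setpoint)/Ki` — standard soft-start practice; the PI then
   trims around the operating point.
2. **Plant constants.** L = 47 µH, C = 100 µF, R_s = 50 mΩ,
   duty_max = 0.98. The duty ceiling must exceed 0.954 for an 80 V
   setpoint to be reachable at all. The output capacitance is sized so
   the high proportional gain (loop gain ≈ Kp·V/(1−d) ≈ 260) rides as a
   small limit cycle (±0.5 V at 500 Ω) instead of a ±3+ V one; with tens
   of µF the loop would chatter outside the ±2.5 V settling band. These
   are plant choices; the gains are fixed.

Metrics: settling time = last out-of-band instant after the event;
steady-state deviation = mean |V − setpoint|/setpoint over the final 20 %
of the trace; overshoot = max positive excursion. A trace that never
re-enters the band returns `inf` with a warning.

## Stimulation engine (`tenssim.stim`)

Rectangular biphasic constant-current trains (cathodic-first by default),
rendered at 100 kHz (≥10 samples per 100 µs phase); net charge per pulse
is zero to within one sample-quantum. The admissible phase width runs to
2.5 ms so both the 20–500 µs hardware range and the 2 ms bench waveform
are representable.

Crosstalk is an instantaneous resistive coupling matrix — the minimal
model consistent with peak-leakage measurements: `observed = (I + C)·driven`,
zero diagonal. The packaged `leakage_table.csv` holds the per-channel
bench means/sds (0.11–0.20 mA at 22 mA drive); the calibrated default
matrix reproduces those means exactly, and `isolation_study` replays the
bench protocol (each channel driven in turn, 10 noisy reads per channel,
read noise N(0, 0.02 mA), averaged).

The output stage is an ideal current source; voltage compliance is
reported separately (`check_compliance`) rather than enforced by clipping.
That keeps a real tension visible: ±22 mA into 10 kΩ needs 220 V, more
than the 100 V supply can give. The simulator does not resolve it.

## Closed loop and latency (`tenssim.loop`)

A trial feeds a synthetic burst through the causal chain and reports
latency from the *detection point* (the envelope crossing referred to the
analog input) to stimulation onset. The per-stage delays are **calibration
constants standing in for hardware stages** (they are not derivable from
the synthetic chain):

| stage | model |
|---|---|
| sampling phase | Uniform(0, 1 ms) — ADC clock asynchronous to the muscle |
| envelope chain lag | 2.0 ms constant |
| processing | 1.4 ms fixed |
| output stage | 5.5 ms + N(0, 0.6 ms), truncated at 0 |

Sum: mean 9.4 ms, sd ≈ 0.67 ms. The device's decision sample embeds the
chain lag, so the detection point is reconstructed as decision time minus
the calibrated constant — the lag is counted exactly once. Setting the
constant to zero recovers the bare 6.9 ms + sampling-phase composition.

The *synthetic* chain's own crossing lag, measurable with
`measured_envelope_lag` (causal vs zero-phase processing of the same
recording), is ≈5 ms with the default windows — larger than the 2.0 ms
hardware calibration constant. The two numbers answer different
questions (this simulator's filters vs the device's firmware chain), and
the package deliberately reports latency with the hardware calibration.

`run_latency_study` replays one synthesized burst across all trials, as a
bench function generator would; per-trial randomness is the delay draws.
`latency_stats` adds Shapiro–Wilk normality and a blocked one-way ANOVA
(k = 5 consecutive blocks) as a stationarity check; constant input is
flagged degenerate (NaN p-values).

## Evaluation (`tenssim.evaluate`)

* **Scoring**: a detection is a true positive within ±100 ms of an
  unmatched annotated onset (greedy nearest-first). Event detection has no
  natural negative, so specificity is defined over 100 ms decision windows
  tiling the inter-burst baseline (guard band of one tolerance around each
  burst); a window with no detection is a true negative. The 100 ms
  tolerance is a declared default — the hardware evaluation's window was
  never stated.
* **ROC**: 50 log-spaced thresholds across the observed envelope range,
  trapezoidal AUC anchored at (0,0)/(1,1), Youden-optimal operating point.
  The sweep disables the refractory hold-off: refractory is an online
  actuation policy, and leaving it on caps the reachable false-positive
  rate (at 0.5 s hold-off, at most one event per 5 windows) so the curve
  could never approach (1,1).
* **Battery**: runtime = capacity / effective current, effective =
  duty-weighted mix of active and idle draw. 400 mAh/95 mA = 4.2 h;
  400 mAh/45 mA = 8.9 h.
* **Sample size**: normal-approximation paired design,
  `n = ceil(((z_{1−α[/2]} + z_{power})/d)²)`. With d = 0.6, α = 0.05
  one-tailed, power 0.8 this gives 18, matching the published plan; the
  exact noncentral-t calculation gives 19–20, and the one-tailed reading
  is inferred from the printed 18. Both facts are documented rather than
  hidden.
* **RMSSD / baseline normalization**: standard time-domain HRV statistic
  and `(x − baseline mean)/baseline mean`; the paired t-test on trial data
  is out of scope (the human study has not run).

## Problem sizes and determinism

Default problem sizes were chosen so the whole suite stays light: 100-trial
latency studies; a 10-session × ~61 s benchmark (≈2.4 M native samples)
for the ROC; 200 ms boost transients at 1 µs steps (200 k RK4 steps).
`scripts/acceptance.py` recomputes every headline number from scratch in
well under a minute. All randomness flows from explicit integer seeds
through `SeedSequence`; every reported quantity is bit-reproducible given
the seed.

## Known limitations

* All detection-performance claims are relative to a calibrated synthetic
  corpus; no real sEMG is involved anywhere.
* The latency distribution is calibrated, not emergent: the study
  validates the composition and statistics machinery, not firmware timing.
* The compliance inconsistency (220 V required vs 100 V available at the
  bench amplitude/load) is reported, not resolved.
* The averaged boost model cannot show switching ripple, EMI or thermal
  effects; BLE transport and the mobile interface are out of scope.
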