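"""Real-time sEMG event detection chain.

Moving-average smoothing, causal RMS envelope, and fixed-threshold upward
crossing detection with refractory suppression — the decision logic an MCU
runs sample-by-sample.  An adaptive-threshold variant (baseline mean +
k*sigma over a trailing window) is provided as an optional mode for
drift-robust operation.

Event time is the first sample at/above threshold (sample-clocked, not
interpolated).  Thresholds are electrode-referred mV, matching the envelope
produced after :func:`tenssim.frontend.codes_to_mv`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetectorConfig",
    "DetectionEvent",
    "moving_average",
    "rms_envelope",
    "detect_events",
    "adaptive_threshold",
]


@dataclass(frozen=True)
class DetectorConfig:
    ma_window: int = 5  # samples (5 ms at 1 kHz)
    rms_window: int = 5  # samples
    threshold: float = 0.3  # mV, electrode-referred
    refractory: float = 0.5  # seconds
    mode: str = "fixed"  # or "adaptive"

    def __post_init__(self) -> None:
        if self.ma_window < 1 or self.rms_window < 1:
            raise ValueError("windows must be >= 1 sample")
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")
        if self.refractory < 0:
            raise ValueError("refractory must be >= 0")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class DetectionEvent:
    time: float  # seconds: first sample at/above threshold
    envelope_value: float  # mV


def _causal_window_sum(x: np.ndarray, w: int) -> np.ndarray:
    """Sum over the trailing w samples (shorter windows at the start)."""
    c = np.cumsum(np.concatenate(([0.0], x)))
    upper = c[1:]
    lower = c[np.maximum(np.arange(len(x)) + 1 - w, 0)]
    return upper - lower


def _window_lengths(n: int, w: int) -> np.ndarray:
    return np.minimum(np.arange(n) + 1, w)


def moving_average(x: np.ndarray, w: int) -> np.ndarray:
    """Causal mean over the last ``w`` samples; same length as input."""
    if w < 1:
        raise ValueError("w must be >= 1")
    x = np.asarray(x, dtype=float)
    return _causal_window_sum(x, w) / _window_lengths(len(x), w)


def rms_envelope(x: np.ndarray, w: int) -> np.ndarray:
    """Causal sliding root-mean-square over the last ``w`` samples."""
    if w < 1:
        raise ValueError("w must be >= 1")
    x = np.asarray(x, dtype=float)
    ms = _causal_window_sum(x**2, w) / _window_lengths(len(x), w)
    return np.sqrt(np.maximum(ms, 0.0))


def detect_events(
    envelope: np.ndarray,
    fs: float,
    cfg: DetectorConfig,
    thresholds: np.ndarray | None = None,
) -> list[DetectionEvent]:
    """Upward-crossing detector with refractory suppression.

    Emits an event where the previous sample is below threshold and the
    current one at/above it (the first sample counts if already above);
    events within ``refractory`` seconds of the last emission are
    suppressed.

    ``thresholds`` optionally supplies a per-sample threshold sequence (the
    adaptive mode); otherwise the fixed ``cfg.threshold`` is used.
    """
    env = np.asarray(envelope, dtype=float)
    if thresholds is None:
        thr = np.full(len(env), cfg.threshold)
    else:
        thr = np.asarray(thresholds, dtype=float)
        if thr.shape != env.shape:
            raise ValueError("per-sample thresholds must match envelope length")
    above = env >= thr
    crossing = above & ~np.concatenate(([False], above[:-1]))
    idx = np.flatnonzero(crossing)
    events: list[DetectionEvent] = []
    last = -np.inf
    for i in idx:
        t = i / fs
        if t - last >= cfg.refractory:
            events.append(DetectionEvent(time=t, envelope_value=float(env[i])))
            last = t
    return events


def adaptive_threshold(
    envelope: np.ndarray,
    fs: float,
    k_sigma: float = 3.0,
    baseline_window: float = 2.0,
) -> np.ndarray:
    """Per-sample threshold = trailing baseline mean + k_sigma * baseline sd.

    The trailing window excludes samples that were already above the
    threshold current at their time, so bursts do not inflate the baseline
    estimate.  Runs sample-by-sample like the MCU would.
    """
    if baseline_window <= 0:
        raise ValueError("baseline_window must be > 0")
    env = np.asarray(envelope, dtype=float)
    n = len(env)
    w = max(1, int(round(baseline_window * fs)))
    thr = np.empty(n)
    # ring buffer of baseline samples with running sums
    buf = np.zeros(w)
    head = 0
    count = 0
    s1 = 0.0
    s2 = 0.0
    current = np.inf  # before any baseline estimate exists, nothing is excluded
    for i in range(n):
        if count >= 2:
            mean = s1 / count
            var = max(s2 / count - mean * mean, 0.0)
            current = mean + k_sigma * np.sqrt(var)
        elif count == 1:
            current = s1
        thr[i] = current if np.isfinite(current) else env[i]
        if env[i] < current or not np.isfinite(current):
            if count == w:
                old = buf[head]
                s1 -= old
                s2 -= old * old
            else:
                count += 1
            buf[head] = env[i]
            s1 += env[i]
            s2 += env[i] * env[i]
            head = (head + 1) % w
    return thr
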