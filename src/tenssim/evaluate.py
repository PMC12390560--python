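"""Evaluation harness: detection scoring, ROC, power/battery projections,
and study-design statistics.

Detection scoring conventions
-----------------------------
A detection is a true positive if it lands within ``tolerance`` seconds of
a not-yet-matched annotated onset (greedy nearest-first matching).  There
is no natural "negative" for event detection, so specificity is defined
over fixed-length decision windows (length = the matching tolerance) tiling
the inter-burst baseline: a window containing no detection is a true
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .detector import DetectorConfig, DetectionEvent, detect_events
from .emg import EmgRecording
from .frontend import FrontendConfig
from .loop import process_recording

__all__ = [
    "DetectionScore",
    "PowerModel",
    "StudyDesign",
    "score_detections",
    "roc_auc",
    "battery_runtime",
    "implied_idle_current",
    "sample_size_paired",
    "rmssd",
    "normalize_to_baseline",
]

#: Default matching tolerance (s) for scoring a detection against an onset.
MATCH_TOLERANCE = 0.1

#: Number of log-spaced thresholds in the default ROC sweep.
ROC_SWEEP_POINTS = 50


@dataclass(frozen=True)
class DetectionScore:
    sensitivity: float
    specificity: float
    auc: float
    optimal_threshold: float  # mV
    n_sessions: int
    curve: tuple = ()  # (fpr, tpr) pairs, threshold-ordered

    def __post_init__(self) -> None:
        for v in (self.sensitivity, self.specificity, self.auc):
            if not 0 <= v <= 1:
                raise ValueError("score fractions must be in [0, 1]")


@dataclass(frozen=True)
class PowerModel:
    battery_capacity: float = 400.0  # mAh
    battery_voltage: float = 3.7  # V
    active_current: float = 95.0  # mA (worst case of the 80-95 mA range)
    idle_current: float = 0.0  # mA
    duty: float = 1.0  # fraction of time stimulating

    def __post_init__(self) -> None:
        if self.battery_capacity <= 0:
            raise ValueError("capacity must be > 0")
        if self.active_current < 0 or self.idle_current < 0:
            raise ValueError("currents must be >= 0")
        if not 0 <= self.duty <= 1:
            raise ValueError("duty must be in [0, 1]")


@dataclass(frozen=True)
class StudyDesign:
    effect_size_d: float = 0.6
    alpha: float = 0.05
    power: float = 0.8
    tails: str = "one"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1 or not 0 < self.power < 1:
            raise ValueError("alpha and power must be in (0, 1)")
        if self.effect_size_d <= 0:
            raise ValueError("effect size must be > 0")
        if self.tails not in ("one", "two"):
            raise ValueError("tails must be 'one' or 'two'")


# ---------------------------------------------------------------------------
# Detection scoring

def _greedy_match(detections: np.ndarray, onsets: np.ndarray, tolerance: float) -> tuple[int, int, int]:
    """Greedy nearest-first matching; returns (TP, FP, FN)."""
    detections = np.sort(np.asarray(detections, dtype=float))
    onsets = np.sort(np.asarray(onsets, dtype=float))
    pairs = [
        (abs(d - o), i, j)
        for i, d in enumerate(detections)
        for j, o in enumerate(onsets)
        if abs(d - o) <= tolerance
    ]
    pairs.sort()
    used_d: set[int] = set()
    used_o: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_d or j in used_o:
            continue
        used_d.add(i)
        used_o.add(j)
        tp += 1
    return tp, len(detections) - tp, len(onsets) - tp


def _baseline_windows(onsets: np.ndarray, offsets: np.ndarray, duration: float, tolerance: float) -> list[tuple[float, float]]:
    """Decision windows of length ``tolerance`` tiling the inter-burst
    baseline (bursts are excluded with a +-tolerance guard band)."""
    edges = [0.0]
    for a, b in zip(onsets, offsets):
        edges.append(max(a - tolerance, 0.0))
        edges.append(min(b + tolerance, duration))
    edges.append(duration)
    windows = []
    for lo, hi in zip(edges[::2], edges[1::2]):
        k = int((hi - lo) / tolerance)
        for m in range(k):
            windows.append((lo + m * tolerance, lo + (m + 1) * tolerance))
    return windows


def score_detections(
    events: list[list[DetectionEvent]] | list[np.ndarray],
    truth: list[EmgRecording] | list[tuple[np.ndarray, np.ndarray, float]],
    tolerance: float = MATCH_TOLERANCE,
) -> tuple[float, float]:
    """Pooled sensitivity and specificity over aligned sessions.

    ``truth`` entries are either :class:`EmgRecording` or
    ``(onsets, offsets, duration)`` tuples.  Sensitivity counts greedily
    matched detections against annotated onsets; specificity counts
    detection-free baseline decision windows.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    tp = fp = fn = tn = n_windows = 0
    total_onsets = 0
    for ev, tr in zip(events, truth, strict=True):
        times = np.asarray([e.time if isinstance(e, DetectionEvent) else float(e) for e in ev])
        if isinstance(tr, EmgRecording):
            onsets, offsets, duration = tr.onsets, tr.offsets, tr.duration
        else:
            onsets, offsets, duration = tr
        total_onsets += len(onsets)
        a, b, c = _greedy_match(times, onsets, tolerance)
        tp, fp, fn = tp + a, fp + b, fn + c
        for lo, hi in _baseline_windows(np.asarray(onsets), np.asarray(offsets), duration, tolerance):
            n_windows += 1
            if not np.any((times >= lo) & (times < hi)):
                tn += 1
    if total_onsets == 0:
        raise ValueError("no annotated onsets: sensitivity undefined")
    sensitivity = tp / (tp + fn)
    specificity = tn / n_windows if n_windows else float("nan")
    return sensitivity, specificity


def roc_auc(
    recordings: list[EmgRecording],
    thresholds: np.ndarray | None = None,
    frontend: FrontendConfig | None = None,
    det: DetectorConfig | None = None,
    tolerance: float = MATCH_TOLERANCE,
) -> DetectionScore:
    """ROC of the fixed-threshold detector over a threshold sweep.

    Default sweep: :data:`ROC_SWEEP_POINTS` log-spaced thresholds across the
    observed envelope range.  AUC by trapezoid with (0,0)/(1,1) anchoring;
    the optimal threshold maximizes Youden's J.

    The sweep characterizes the threshold statistic itself, so events are
    collected with the refractory suppression disabled: refractory hold-off
    is an online actuation policy (one trigger per burst), and leaving it
    on would cap the achievable false-positive rate at the refractory rate
    and distort the curve.
    """
    frontend = frontend or FrontendConfig()
    det = det or DetectorConfig()
    envs = [process_recording(rec, frontend, det) for rec in recordings]
    if thresholds is None:
        all_env = np.concatenate([e for e, _ in envs])
        lo = max(np.percentile(all_env, 5), 1e-6)
        hi = all_env.max()
        thresholds = np.geomspace(lo, hi, ROC_SWEEP_POINTS)
    else:
        thresholds = np.asarray(thresholds, dtype=float)
        if np.any(np.diff(thresholds) < 0):
            import warnings

            warnings.warn("threshold sweep not monotone; sorting", stacklevel=2)
            thresholds = np.sort(thresholds)
        if len(thresholds) < 2:
            raise ValueError("need >= 2 thresholds")

    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for k, thr in enumerate(thresholds):
        cfg_k = DetectorConfig(
            ma_window=det.ma_window,
            rms_window=det.rms_window,
            threshold=float(thr),
            refractory=0.0,
            mode=det.mode,
        )
        events = [detect_events(e, fs, cfg_k) for e, fs in envs]
        sens[k], spec[k] = score_detections(events, recordings, tolerance)

    fpr = 1.0 - spec
    order = np.argsort(fpr, kind="stable")
    fx = np.concatenate(([0.0], fpr[order], [1.0]))
    ty = np.concatenate(([0.0], sens[order], [1.0]))
    auc = float(np.trapezoid(ty, fx))
    j = sens + spec - 1.0
    best = int(np.argmax(j))
    return DetectionScore(
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        auc=min(max(auc, 0.0), 1.0),
        optimal_threshold=float(thresholds[best]),
        n_sessions=len(recordings),
        curve=tuple(zip(fpr.tolist(), sens.tolist())),
    )


# ---------------------------------------------------------------------------
# Power and battery

def battery_runtime(model: PowerModel) -> float:
    """Runtime in hours: capacity / effective current.

    Effective current = active at duty 1, else the duty-weighted mix of
    active and idle draw.
    """
    if model.duty == 1.0:
        eff = model.active_current
    else:
        eff = model.duty * model.active_current + (1.0 - model.duty) * model.idle_current
    if eff <= 0:
        raise ValueError("effective current is zero: runtime undefined")
    return model.battery_capacity / eff


def implied_idle_current(active: float, duty: float, target_effective: float) -> float:
    """Idle draw that makes the duty-weighted average hit the target."""
    if not duty < 1:
        raise ValueError("duty must be < 1")
    idle = (target_effective - duty * active) / (1.0 - duty)
    if idle < 0:
        raise ValueError(f"inconsistent inputs: implied idle current {idle:.2f} mA < 0")
    return idle


# ---------------------------------------------------------------------------
# Study design statistics

def sample_size_paired(design: StudyDesign) -> int:
    """Normal-approximation sample size for a paired two-condition design.

    n = ceil(((z_{1-alpha[/2]} + z_{power}) / d)^2).  The exact
    noncentral-t calculation gives one to two participants more; the normal
    approximation is used here deliberately (see the methods note).
    """
    alpha = design.alpha / 2 if design.tails == "two" else design.alpha
    z_a = stats.norm.ppf(1.0 - alpha)
    z_b = stats.norm.ppf(design.power)
    return int(math.ceil(((z_a + z_b) / design.effect_size_d) ** 2))


def rmssd(rr_intervals) -> float:
    """Root mean square of successive differences of RR intervals (ms)."""
    rr = np.asarray(rr_intervals, dtype=float)
    if len(rr) < 2:
        raise ValueError("need >= 2 intervals")
    return float(np.sqrt(np.mean(np.diff(rr) ** 2)))


def normalize_to_baseline(x, baseline_window: float, fs: float) -> np.ndarray:
    """Per-sample relative change from the leading-window baseline mean:
    ``(x - mean) / mean``."""
    x = np.asarray(x, dtype=float)
    n_base = int(round(baseline_window * fs))
    if not 0 < n_base < len(x):
        raise ValueError("baseline window must be shorter than the signal")
    mean = np.mean(x[:n_base])
    if mean == 0:
        raise ValueError("baseline mean is zero")
    return (x - mean) / mean
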