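"""Analog front-end and ADC model.

Models the acquisition chain of the device: an instrumentation amplifier
(gain 100 V/V, finite CMRR), a second-order Sallen-Key style band-pass
(20-500 Hz) realised digitally as two cascaded Butterworth biquads, and a
12-bit ADC sampling at 1 kHz behind a 6th-order anti-alias low-pass.

Filtering in the loop path is causal — loop latency must include real group
delay.  Zero-phase filtering is reserved for offline analysis utilities.

Signals entering :func:`amplify` are electrode-referred mV; after the
amplifier they are amplifier-output mV; :func:`codes_to_mv` maps ADC codes
back to electrode-referred mV so detection thresholds are stated at the
electrode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FrontendConfig",
    "AdcStream",
    "amplify",
    "bandpass",
    "bandpass_sos",
    "bandpass_group_delay",
    "digitize",
    "codes_to_mv",
]


class NyquistViolationError(ValueError):
    pass


@dataclass(frozen=True)
class FrontendConfig:
    gain: float = 100.0  # V/V
    cmrr_db: float = 80.0
    band_low: float = 20.0  # Hz
    band_high: float = 500.0  # Hz
    adc_bits: int = 12
    adc_fs: float = 1000.0  # Hz
    adc_vref: float = 3.3  # V full-scale; bipolar +-vref/2 about mid-supply

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not 8 <= self.adc_bits <= 24:
            raise ValueError("adc_bits must be in [8, 24]")

    @property
    def lsb_volts(self) -> float:
        return self.adc_vref / 2**self.adc_bits

    @property
    def midscale(self) -> int:
        return 2 ** (self.adc_bits - 1)


@dataclass
class AdcStream:
    """Quantized samples plus the bookkeeping needed to undo them."""

    codes: np.ndarray  # integer codes in [0, 2^bits)
    fs: float
    lsb_volts: float
    origin_shift: float = 0.0  # anti-alias group delay, seconds


def amplify(differential: np.ndarray, common_mode: np.ndarray, cfg: FrontendConfig) -> np.ndarray:
    """Instrumentation-amplifier model with finite common-mode rejection.

    ``out = gain * differential + (gain / 10^(cmrr_db/20)) * common_mode``
    """
    differential = np.asarray(differential, dtype=float)
    common_mode = np.asarray(common_mode, dtype=float)
    if differential.shape != common_mode.shape:
        raise ValueError("differential and common_mode must have equal length")
    cm_gain = cfg.gain / 10 ** (cfg.cmrr_db / 20.0) if np.isfinite(cfg.cmrr_db) else 0.0
    return cfg.gain * differential + cm_gain * common_mode


def bandpass_sos(cfg: FrontendConfig, rate: float) -> np.ndarray:
    """Band-pass as two cascaded biquads (Butterworth, Q = 0.707).

    One 2nd-order high-pass at ``band_low`` and one 2nd-order low-pass at
    ``band_high``, bilinear transform with prewarping (scipy's default).
    """
    if rate <= 2 * cfg.band_high:
        raise NyquistViolationError(
            f"rate {rate} Hz too low for band edge {cfg.band_high} Hz"
        )
    hp = signal.butter(2, cfg.band_low, btype="highpass", fs=rate, output="sos")
    lp = signal.butter(2, cfg.band_high, btype="lowpass", fs=rate, output="sos")
    return np.vstack([hp, lp])


def bandpass(x: np.ndarray, rate: float, cfg: FrontendConfig, zero_phase: bool = False) -> np.ndarray:
    """Apply the band-pass.  Causal by default; ``zero_phase`` is for offline
    analysis only (never in the simulated loop path)."""
    sos = bandpass_sos(cfg, rate)
    x = np.asarray(x, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x)
    return signal.sosfilt(sos, x)


def bandpass_frequency_response(cfg: FrontendConfig, rate: float, freqs) -> np.ndarray:
    """Complex response of the designed discrete-time band-pass at ``freqs`` Hz."""
    sos = bandpass_sos(cfg, rate)
    _, h = signal.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=rate)
    return h


def bandpass_group_delay(cfg: FrontendConfig, rate: float, freq: float = 100.0) -> float:
    """Group delay (s) of the designed band-pass at ``freq``.

    Single source of truth consumed by the closed-loop timing model when
    accounting for analog-chain delay explicitly.
    """
    sos = bandpass_sos(cfg, rate)
    total = 0.0
    for section in sos:
        w, gd = signal.group_delay((section[:3], section[3:]), w=[freq], fs=rate)
        total += gd[0]
    return float(total / rate)


def _antialias_sos(cfg: FrontendConfig, rate: float) -> np.ndarray:
    return signal.butter(6, 0.45 * cfg.adc_fs, btype="lowpass", fs=rate, output="sos")


def digitize(x_mv: np.ndarray, native_rate: float, cfg: FrontendConfig) -> AdcStream:
    """Anti-alias, decimate to ``adc_fs`` and quantize to ``adc_bits``.

    Input is amplifier-output mV.  The ADC sees a bipolar +-vref/2 range
    about a mid-supply virtual ground; mid-rise quantization, clamped at the
    rails.

    Raises
    ------
    ValueError
        If ``native_rate`` is not an integer multiple of ``adc_fs``.
    """
    factor = native_rate / cfg.adc_fs
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"native rate {native_rate} Hz is not an integer multiple of adc_fs {cfg.adc_fs} Hz"
        )
    factor = int(round(factor))
    x = np.asarray(x_mv, dtype=float)
    if factor > 1:
        sos = _antialias_sos(cfg, native_rate)
        x = signal.sosfilt(sos, x)
        x = x[::factor]
    volts = x / 1000.0
    codes = np.floor(volts / cfg.lsb_volts).astype(np.int64) + cfg.midscale
    codes = np.clip(codes, 0, 2**cfg.adc_bits - 1)
    # group-delay bookkeeping for offline alignment (approximate, passband)
    shift = _antialias_group_delay(cfg, native_rate) if factor > 1 else 0.0
    return AdcStream(codes=codes, fs=cfg.adc_fs, lsb_volts=cfg.lsb_volts, origin_shift=shift)


def _antialias_group_delay(cfg: FrontendConfig, rate: float, freq: float = 100.0) -> float:
    sos = _antialias_sos(cfg, rate)
    total = 0.0
    for section in sos:
        _, gd = signal.group_delay((section[:3], section[3:]), w=[freq], fs=rate)
        total += gd[0]
    return float(total / rate)


def codes_to_mv(stream: AdcStream, cfg: FrontendConfig) -> np.ndarray:
    """Map ADC codes back to electrode-referred mV (undo gain and offset)."""
    return (stream.codes - cfg.midscale) * stream.lsb_volts * 1000.0 / cfg.gain
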