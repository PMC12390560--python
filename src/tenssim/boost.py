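"""Averaged-model simulation of the PI-controlled boost converter.

The high-voltage supply steps a 3.7 V cell up to a programmable setpoint
(up to 100 V) under a proportional-integral duty-cycle controller.  The
plant is the textbook averaged continuous-conduction boost model

    dI/dt = (v_in - esr*I - (1 - d) * v_out) / L
    dV/dt = ((1 - d) * I - v_out / R) / C

integrated with explicit RK4, with the inductor current floored at zero
(discontinuous-conduction guard).  PWM switching ripple is deliberately not
modelled: the bench claims this simulator checks (settling time, steady
state deviation) are envelope-level quantities, and the duty variable
stands in for the PWM command.

The controller output saturates at [0, duty_max] with conditional-
integration anti-windup: the integrator is not advanced while the output is
pinned against the error sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlantParams",
    "PiConfig",
    "LoadProfile",
    "SimTrace",
    "pi_step",
    "simulate_boost",
    "settling_metrics",
]


class BoostInstabilityError(RuntimeError):
    pass


@dataclass(frozen=True)
class PlantParams:
    """Physical constants of the averaged boost plant.

    Defaults are typical for a compact battery-to-100 V converter.  The
    duty ceiling of 0.98 leaves an ideal CCM reach of v_in/0.02 = 185 V, so
    an 80 V setpoint (needing d = 1 - 3.7/80 = 0.954) is attainable.
    """

    v_in: float = 3.7  # V
    inductance: float = 47e-6  # H
    capacitance: float = 100e-6  # F
    esr: float = 0.05  # Ohm, series resistance in the inductor path
    duty_max: float = 0.98
    divider_ratio: float = 1.0 / 41.0  # feedback divider (modelled exact)

    def __post_init__(self) -> None:
        vals = (self.v_in, self.inductance, self.capacitance, self.esr, self.duty_max, self.divider_ratio)
        if any(v <= 0 for v in vals[:4]) or self.divider_ratio <= 0:
            raise ValueError("plant parameters must be positive")
        if not self.duty_max < 1:
            raise ValueError("duty_max must be < 1")


@dataclass(frozen=True)
class PiConfig:
    """PI gains act on the output-referred voltage error (volts)."""

    setpoint: float = 80.0  # V
    kp: float = 0.15  # duty per volt of error
    ki: float = 0.02  # duty per volt-second
    band: float = 2.5  # V, settling band half-width
    update_rate: float = 10_000.0  # Hz
    integrator_limit: float = float("inf")  # V*s

    def __post_init__(self) -> None:
        if self.kp < 0 or self.ki < 0:
            raise ValueError("gains must be >= 0")
        if self.band <= 0:
            raise ValueError("band must be > 0")
        if self.setpoint > 100:
            raise ValueError("setpoint exceeds the 100 V supply ceiling")


@dataclass(frozen=True)
class LoadProfile:
    """Piecewise-constant resistive load: ``resistances[i]`` applies from
    ``breakpoints[i]`` until the next breakpoint."""

    breakpoints: tuple[float, ...] = (0.0,)
    resistances: tuple[float, ...] = (10_000.0,)

    def __post_init__(self) -> None:
        if len(self.breakpoints) != len(self.resistances):
            raise ValueError("breakpoints and resistances must align")
        if any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be increasing")
        if any(not 100 <= r <= 1e6 for r in self.resistances):
            raise ValueError("resistances must lie in [100, 1e6] Ohm")

    def at(self, t: float) -> float:
        i = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.resistances[max(i, 0)]


@dataclass
class SimTrace:
    time: np.ndarray
    v_out: np.ndarray
    i_L: np.ndarray
    duty: np.ndarray
    load: np.ndarray
    setpoint: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "v_out": self.v_out,
                "i_L": self.i_L,
                "duty": self.duty,
                "load_ohm": self.load,
            }
        )


def pi_step(
    error: float,
    integrator: float,
    dt: float,
    cfg: PiConfig,
    duty_max: float = 0.98,
) -> tuple[float, float]:
    """One controller update; returns ``(duty, advanced integrator)``.

    Conditional-integration anti-windup: the integrator holds while the
    unsaturated output is pinned at a rail on the same side as the error.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    lim = cfg.integrator_limit
    proposed = float(np.clip(integrator + error * dt, -lim, lim))
    duty_raw = cfg.kp * error + cfg.ki * proposed
    if duty_raw > duty_max and error > 0:
        return duty_max, integrator
    if duty_raw < 0.0 and error < 0:
        return 0.0, integrator
    return float(np.clip(duty_raw, 0.0, duty_max)), proposed


def simulate_boost(
    plant: PlantParams,
    cfg: PiConfig,
    load: LoadProfile,
    duration: float = 0.2,
    dt_sim: float = 1e-6,
    duty_override: float | None = None,
    v0: float | None = None,
    i0: float = 0.0,
    integ0: float | None = None,
) -> SimTrace:
    """Closed-loop simulation: RK4 plant at ``dt_sim``, PI updates at
    ``cfg.update_rate``.

    ``duty_override`` disables the controller and holds a constant duty
    (open-loop analysis, e.g. the CCM gain check).  The capacitor starts
    pre-charged to the battery (``v0 = v_in``) and the inductor relaxed
    unless stated otherwise.

    ``integ0`` sets the initial integrator state (V*s).  By default it is
    preset to the feedforward operating duty ``(1 - v_in/setpoint) / ki``
    (soft-start practice): the integral gain printed on the controller is a
    trim gain around the operating point, far too slow to build the ~0.95
    boost duty from zero within a transient test.

    Raises
    ------
    BoostInstabilityError
        If ``|v_out|`` exceeds 10x the setpoint (diverging simulation).
    """
    if dt_sim > 1.0 / cfg.update_rate + 1e-15:
        raise ValueError("dt_sim must be <= one controller update period")
    n = int(round(duration / dt_sim))
    ctrl_every = max(1, int(round(1.0 / (cfg.update_rate * dt_sim))))
    L, C, esr, vin = plant.inductance, plant.capacitance, plant.esr, plant.v_in

    v = plant.v_in if v0 is None else v0
    i = i0
    duty = duty_override if duty_override is not None else 0.0
    if integ0 is not None:
        integ = integ0
    elif cfg.ki > 0:
        integ = max(1.0 - vin / cfg.setpoint, 0.0) / cfg.ki
    else:
        integ = 0.0
    abort_level = 10.0 * abs(cfg.setpoint)

    t_arr = np.arange(n) * dt_sim
    v_arr = np.empty(n)
    i_arr = np.empty(n)
    d_arr = np.empty(n)
    r_arr = np.empty(n)

    bps = np.asarray(load.breakpoints)
    rs = np.asarray(load.resistances)

    def deriv(ii: float, vv: float, d: float, R: float) -> tuple[float, float]:
        di = (vin - esr * ii - (1.0 - d) * vv) / L
        dv = ((1.0 - d) * ii - vv / R) / C
        return di, dv

    for k in range(n):
        t = t_arr[k]
        R = rs[max(int(np.searchsorted(bps, t, side="right")) - 1, 0)]
        if duty_override is None and k % ctrl_every == 0:
            err = cfg.setpoint - v
            duty, integ = pi_step(err, integ, ctrl_every * dt_sim, cfg, plant.duty_max)
        v_arr[k] = v
        i_arr[k] = i
        d_arr[k] = duty
        r_arr[k] = R

        k1i, k1v = deriv(i, v, duty, R)
        k2i, k2v = deriv(i + 0.5 * dt_sim * k1i, v + 0.5 * dt_sim * k1v, duty, R)
        k3i, k3v = deriv(i + 0.5 * dt_sim * k2i, v + 0.5 * dt_sim * k2v, duty, R)
        k4i, k4v = deriv(i + dt_sim * k3i, v + dt_sim * k3v, duty, R)
        i += dt_sim / 6.0 * (k1i + 2 * k2i + 2 * k3i + k4i)
        v += dt_sim / 6.0 * (k1v + 2 * k2v + 2 * k3v + k4v)
        if i < 0.0:
            i = 0.0  # DCM guard: the diode blocks reverse inductor current
        if abs(v) > abort_level:
            raise BoostInstabilityError(
                f"v_out diverged to {v:.1f} V at t={t * 1e3:.2f} ms (>|10x setpoint|)"
            )

    return SimTrace(time=t_arr, v_out=v_arr, i_L=i_arr, duty=d_arr, load=r_arr, setpoint=cfg.setpoint)


def settling_metrics(
    trace: SimTrace,
    event_time: float,
    cfg: PiConfig,
) -> tuple[float, float, float]:
    """Transient metrics after a load event.

    Returns ``(settling_time, steady_state_deviation, overshoot)``:

    * settling_time — last instant after the event at which ``|v_out -
      setpoint|`` is outside the +-band, minus the event time (0 if never
      outside; ``inf`` with a warning if still outside at the end).
    * steady_state_deviation — mean ``|v_out - setpoint| / setpoint`` over
      the final 20 % of the trace.
    * overshoot — max ``(v_out - setpoint) / setpoint`` after the event.
    """
    t, v, sp = trace.time, trace.v_out, cfg.setpoint
    if not t[0] <= event_time <= t[-1]:
        raise ValueError("event_time outside trace")
    after = t >= event_time
    dev = np.abs(v[after] - sp)
    out = dev > cfg.band
    if out[-1]:
        warnings.warn("trace never re-enters the settling band", stacklevel=2)
        settling = float("inf")
    elif not out.any():
        settling = 0.0
    else:
        settling = float(t[after][np.flatnonzero(out)[-1]] + (t[1] - t[0]) - event_time)
    tail = slice(int(0.8 * len(t)), None)
    ss_dev = float(np.mean(np.abs(v[tail] - sp)) / sp)
    overshoot = float(max(np.max(v[after] - sp), 0.0) / sp)
    return settling, ss_dev, overshoot
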