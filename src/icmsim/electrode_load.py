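"""Electrical model of the electrode–electrolyte interface under current
drive, with compliance-voltage clamping.

The interface is the standard simplified equivalent circuit: an access
(series) resistance Rs in series with a parallel pair (Rp ∥ Cp) standing for
the charge-transfer resistance and double-layer capacitance. The stimulator
behaves as an ideal current source while its output voltage stays inside the
±2.42 V compliance window; beyond it the output clamps at the limit voltage
and the delivered current falls below command, decaying as the double layer
keeps charging — the signature seen when driving high-impedance loads near
±80 μA.

The system is piecewise linear, so the simulator uses exact per-step
exponential updates (no explicit-Euler drift) and resolves the
source→clamp crossing analytically inside a step.

Units: Ω, F, V, s internally for circuit quantities; waveform exchange with
the generator model is in μs/μA.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .current_generator import CurrentWaveform

DEFAULT_V_LIMIT = 2.42


@dataclass(frozen=True)
class InterfaceModel:
    """Series resistance + parallel RC interface with a compliance limit."""

    r_series_ohm: float
    r_parallel_ohm: float
    c_parallel_f: float
    v_limit_v: float = DEFAULT_V_LIMIT

    def __post_init__(self) -> None:
        for name in ("r_series_ohm", "r_parallel_ohm", "c_parallel_f", "v_limit_v"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_source_s(self) -> float:
        """Time constant while current-driven: Rp·Cp."""
        return self.r_parallel_ohm * self.c_parallel_f

    @property
    def tau_clamp_s(self) -> float:
        """Time constant while voltage-clamped: (Rs ∥ Rp)·Cp."""
        rs, rp = self.r_series_ohm, self.r_parallel_ohm
        return rs * rp / (rs + rp) * self.c_parallel_f

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "r_series_ohm": self.r_series_ohm,
            "r_parallel_ohm": self.r_parallel_ohm,
            "c_parallel_f": self.c_parallel_f,
            "v_limit_v": self.v_limit_v,
        }, indent=1) + "\n")

    @classmethod
    def from_json(cls, source: str | Path | dict) -> "InterfaceModel":
        if not isinstance(source, dict):
            source = json.loads(Path(source).read_text())
        return cls(**{k: float(v) for k, v in source.items()})


def impedance_magnitude(model: InterfaceModel, f_hz: float) -> float:
    """|Z| of the interface at frequency f: |Rs + Rp/(1 + j·2πf·Rp·Cp)|.

    Monotonically non-increasing in f, from Rs+Rp at DC to Rs at high f.
    """
    if f_hz < 0:
        raise ValueError("frequency must be >= 0")
    z = model.r_series_ohm + model.r_parallel_ohm / (
        1 + 1j * 2 * math.pi * f_hz * model.r_parallel_ohm * model.c_parallel_f
    )
    return abs(z)


def fit_parallel_resistance(
    z_target_ohm: float,
    c_parallel_f: float,
    f_hz: float = 1000.0,
    r_series_ohm: float = 1000.0,
    v_limit_v: float = DEFAULT_V_LIMIT,
) -> InterfaceModel:
    """Solve for the parallel resistance that gives a target |Z| at f.

    With Rs and Cp fixed, |Z|(f) grows monotonically with Rp from Rs toward
    the capacitive ceiling sqrt(Rs² + 1/(2πf·Cp)²), so a bracketing
    root-find recovers Rp; raises if the target exceeds that ceiling.
    """
    w = 2 * math.pi * f_hz
    ceiling = math.hypot(r_series_ohm, 1.0 / (w * c_parallel_f))
    if not r_series_ohm < z_target_ohm < ceiling:
        raise ValueError(
            f"target {z_target_ohm:.3g} Ω unreachable with Cp={c_parallel_f:.3g} F "
            f"(must be between Rs={r_series_ohm:.3g} and {ceiling:.3g} Ω)"
        )

    def err(rp: float) -> float:
        m = InterfaceModel(r_series_ohm, rp, c_parallel_f, v_limit_v)
        return impedance_magnitude(m, f_hz) - z_target_ohm

    rp = brentq(err, 1e-3, 1e12, xtol=1e-9, rtol=1e-14)
    return InterfaceModel(r_series_ohm, float(rp), c_parallel_f, v_limit_v)


def bench_load(name: str) -> InterfaceModel:
    """One of the two versioned bench model circuits.

    ``"metal_33k7"`` mimics a metal microelectrode usable for intracortical
    stimulation (~33.7 kΩ at 1 kHz); ``"small_tip_325k"`` a similar electrode
    with much smaller surface area (~325 kΩ at 1 kHz). Both use Rs = 1 kΩ;
    component values were fitted to the 1 kHz impedance (see data file).
    """
    text = resources.files("icmsim.data").joinpath("bench_loads.json").read_text()
    doc = json.loads(text)
    if name not in doc["models"]:
        raise KeyError(f"unknown bench load {name!r}; available: {sorted(doc['models'])}")
    return InterfaceModel.from_json(doc["models"][name])


@dataclass(frozen=True)
class DriveResult:
    """Outcome of driving an interface with a commanded current waveform."""

    commanded_uA: np.ndarray
    actual_uA: np.ndarray
    terminal_voltage_V: np.ndarray
    capacitor_voltage_V: np.ndarray
    sample_times_us: np.ndarray
    clamped_intervals_us: tuple[tuple[float, float], ...]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "time_us": self.sample_times_us,
            "i_cmd_uA": self.commanded_uA,
            "i_actual_uA": self.actual_uA,
            "v_out_V": self.terminal_voltage_V,
            "v_cap_V": self.capacitor_voltage_V,
        }).to_csv(path, index=False)


def _source_step(model: InterfaceModel, vc: float, i_amp: float, dt_s: float) -> float:
    """Exact capacitor-voltage update over dt with constant source current."""
    target = i_amp * model.r_parallel_ohm
    return target + (vc - target) * math.exp(-dt_s / model.tau_source_s)

def _clamp_step(model: InterfaceModel, vc: float, v_clamp: float, dt_s: float) -> float:
    """Exact update over dt with the terminal held at the clamp voltage."""
    rs, rp = model.r_series_ohm, model.r_parallel_ohm
    target = v_clamp * rp / (rs + rp)
    return target + (vc - target) * math.exp(-dt_s / model.tau_clamp_s)


def simulate_drive(
    model: InterfaceModel,
    commanded: CurrentWaveform,
    vc0_V: float = 0.0,
) -> DriveResult:
    """Drive the interface with a commanded current trace.

    Per sample interval (the commanded current is constant within it): if
    the terminal voltage I·Rs + Vc stays within ±v_limit, the source mode
    integrates dVc/dt = (I − Vc/Rp)/Cp exactly; if it would cross the limit
    mid-step, the crossing time is solved analytically and the remainder of
    the step runs voltage-clamped at ±v_limit with I = (±v_limit − Vc)/Rs.
    Samples record the state at the start of each interval.
    """
    dt_s = commanded.dt_us * 1e-6
    if dt_s <= 0:
        raise ValueError("waveform sample step must be positive")
    i_cmd_A = commanded.current_uA * 1e-6
    n = i_cmd_A.size
    rs = model.r_series_ohm
    vlim = model.v_limit_v

    i_act = np.empty(n)
    v_out = np.empty(n)
    v_cap = np.empty(n)
    clamped = np.zeros(n, dtype=bool)
    vc = vc0_V

    for k in range(n):
        i = i_cmd_A[k]
        v = i * rs + vc
        if abs(v) <= vlim:
            # current-source mode; check for a limit crossing inside the step
            i_act[k], v_out[k], v_cap[k] = i, v, vc
            vc_end = _source_step(model, vc, i, dt_s)
            v_end = i * rs + vc_end
            if abs(v_end) > vlim:
                v_clamp = math.copysign(vlim, v_end)
                # solve i·Rs + Vc(t*) = v_clamp for the crossing time
                target = i * model.r_parallel_ohm
                num = (v_clamp - i * rs) - target
                den = vc - target
                t_cross = -model.tau_source_s * math.log(num / den)
                vc = _source_step(model, vc, i, t_cross)
                vc = _clamp_step(model, vc, v_clamp, dt_s - t_cross)
            else:
                vc = vc_end
        else:
            v_clamp = math.copysign(vlim, v)
            i_act[k] = (v_clamp - vc) / rs
            v_out[k] = v_clamp
            v_cap[k] = vc
            clamped[k] = True
            vc = _clamp_step(model, vc, v_clamp, dt_s)

    intervals: list[tuple[float, float]] = []
    t = commanded.sample_times_us
    start = None
    for k in range(n):
        if clamped[k] and start is None:
            start = t[k]
        elif not clamped[k] and start is not None:
            intervals.append((float(start), float(t[k])))
            start = None
    if start is not None:
        intervals.append((float(start), float(t[-1])))

    return DriveResult(
        commanded_uA=commanded.current_uA.copy(),
        actual_uA=i_act * 1e6,
        terminal_voltage_V=v_out,
        capacitor_voltage_V=v_cap,
        sample_times_us=t.copy(),
        clamped_intervals_us=tuple(intervals),
    )


def inrush_peak(model: InterfaceModel, v_mismatch_V: float, suppression_on: bool) -> float:
    """Peak inrush current (μA) when an output switch connects to the load.

    A potential mismatch between the idle output and the electrode drives a
    transient of v_mismatch/Rs at the connection instant. The 2-bit ICS
    setting enables pre-equalization of the potentials, which removes the
    transient entirely in this idealized model.
    """
    if suppression_on:
        return 0.0
    return abs(v_mismatch_V) / model.r_series_ohm * 1e6


def short_to_reference(model: InterfaceModel, vc_V: float, duration_s: float) -> float:
    """Residual capacitor voltage after shorting the output to Vref.

    Accumulated interface charge discharges through the series access path,
    so Vc decays exponentially with time constant Rs·Cp.
    """
    if duration_s < 0:
        raise ValueError("duration must be >= 0")
    return vc_V * math.exp(-duration_s / (model.r_series_ohm * model.c_parallel_f))
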