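"""Forward simulator of whole-cell voltage-clamp recordings.

The membrane model is a Boltzmann-gated, ohmic-driving-force chloride
conductance plus an optional linear leak:

    I(t) = C * [ g(V) * (V - Erev) + g_leak * (V - E_leak) ] * 1e-3   [pA]

with g in pS/pF, V in mV and C in pF.  Gating is instantaneous by default;
an optional first-order relaxation time constant reproduces the mild time
dependence seen at strongly depolarized potentials.  An osmotic "switch"
condition blends the isotonic channel state into the hypotonic state with a
configurable time constant, emulating bath-exchange activation of the
volume-sensitive current.

Capacitive transients are deliberately not modeled: the analysis chain reads
steady-state windows only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

__all__ = [
    "Segment",
    "VoltageProtocol",
    "ChannelModel",
    "CellModel",
    "CurrentTrace",
    "make_step_protocol",
    "make_ramp_protocol",
    "boltzmann_conductance",
    "simulate_trace",
    "write_trace",
    "read_trace",
]


@dataclass(frozen=True)
class Segment:
    """One piece of a command waveform: a constant level or a linear ramp."""

    kind: str  # "hold" | "step" | "ramp"
    v0_mV: float
    v1_mV: float
    duration_ms: float

    def __post_init__(self) -> None:
        if self.kind not in ("hold", "step", "ramp"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ValueError("segment duration must be positive")
        if self.kind in ("hold", "step") and self.v0_mV != self.v1_mV:
            raise ValueError("hold/step segments must have v0 == v1")


@dataclass
class VoltageProtocol:
    """Command-voltage protocol: an ordered list of segments per sweep."""

    sweeps: list[list[Segment]]
    sampling_interval_ms: float = 1.0
    test_segment_index: int | None = None  # which segment carries the test level
    name: str = "protocol"

    def __post_init__(self) -> None:
        if self.sampling_interval_ms <= 0:
            raise ValueError("sampling interval must be positive")
        if not self.sweeps:
            raise ValueError("protocol needs at least one sweep")

    @property
    def n_sweeps(self) -> int:
        return len(self.sweeps)

    def sweep_duration_ms(self, sweep: int) -> float:
        return sum(s.duration_ms for s in self.sweeps[sweep])

    @property
    def test_levels_mV(self) -> np.ndarray:
        if self.test_segment_index is None:
            raise ValueError("protocol has no designated test segment")
        return np.array(
            [sw[self.test_segment_index].v0_mV for sw in self.sweeps], dtype=float
        )

    def sweep_waveform(self, sweep: int) -> tuple[np.ndarray, np.ndarray]:
        """Sampled (time within sweep, command voltage) for one sweep."""
        dt = self.sampling_interval_ms
        total = self.sweep_duration_ms(sweep)
        n = int(round(total / dt))
        t = np.arange(n) * dt
        v = np.empty(n)
        start = 0.0
        for seg in self.sweeps[sweep]:
            sel = (t >= start - 1e-9) & (t < start + seg.duration_ms - 1e-9)
            if seg.kind == "ramp":
                frac = (t[sel] - start) / seg.duration_ms
                v[sel] = seg.v0_mV + frac * (seg.v1_mV - seg.v0_mV)
            else:
                v[sel] = seg.v0_mV
            start += seg.duration_ms
        return t, v

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "sampling_interval_ms": self.sampling_interval_ms,
            "test_segment_index": self.test_segment_index,
            "sweeps": [[asdict(s) for s in sw] for sw in self.sweeps],
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "VoltageProtocol":
        payload = json.loads(Path(path).read_text())
        return cls(
            sweeps=[[Segment(**s) for s in sw] for sw in payload["sweeps"]],
            sampling_interval_ms=payload["sampling_interval_ms"],
            test_segment_index=payload["test_segment_index"],
            name=payload.get("name", "protocol"),
        )


def make_step_protocol(
    holding_mV: float = -30.0,
    v_start_mV: float = 80.0,
    v_stop_mV: float = -100.0,
    dv_mV: float = -10.0,
    test_ms: float = 200.0,
    pre_ms: float = 50.0,
    post_ms: float = 50.0,
    sampling_interval_ms: float = 1.0,
) -> VoltageProtocol:
    """Square-step family: 200 ms steps from a -30 mV holding level to +80
    through -100 mV in 10 mV increments (19 sweeps by default)."""
    if dv_mV == 0:
        raise ValueError("dv must be nonzero")
    n = int(round((v_stop_mV - v_start_mV) / dv_mV)) + 1
    levels = v_start_mV + dv_mV * np.arange(n)
    sweeps = [
        [
            Segment("hold", holding_mV, holding_mV, pre_ms),
            Segment("step", float(v), float(v), test_ms),
            Segment("hold", holding_mV, holding_mV, post_ms),
        ]
        for v in levels
    ]
    return VoltageProtocol(
        sweeps=sweeps,
        sampling_interval_ms=sampling_interval_ms,
        test_segment_index=1,
        name="step_family",
    )


def make_ramp_protocol(
    n_repeats: int = 1,
    holding_mV: float = -30.0,
    v_min_mV: float = -100.0,
    v_max_mV: float = 80.0,
    dvdt_V_per_s: float = 0.25,
    interval_s: float = 6.0,
    sampling_interval_ms: float = 1.0,
) -> VoltageProtocol:
    """Constant-slope ramps (|dV/dt| = 0.25 V/s) repeated at 6 s intervals.

    Each repeat descends from holding to ``v_min``, ramps up to ``v_max``,
    returns to holding and then holds until the next onset 6 s later.  The
    whole record is one continuous sweep.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rate = dvdt_V_per_s  # mV/ms numerically equals V/s
    d_down = (holding_mV - v_min_mV) / rate
    d_up = (v_max_mV - v_min_mV) / rate
    d_back = (v_max_mV - holding_mV) / rate
    active = d_down + d_up + d_back
    hold_ms = interval_s * 1e3 - active
    if hold_ms <= 0:
        raise ValueError("ramp excursion does not fit in the repeat interval")
    segments: list[Segment] = []
    for _ in range(n_repeats):
        segments += [
            Segment("ramp", holding_mV, v_min_mV, d_down),
            Segment("ramp", v_min_mV, v_max_mV, d_up),
            Segment("ramp", v_max_mV, holding_mV, d_back),
            Segment("hold", holding_mV, holding_mV, hold_ms),
        ]
    return VoltageProtocol(
        sweeps=[segments],
        sampling_interval_ms=sampling_interval_ms,
        test_segment_index=None,
        name="ramp_family",
    )


@dataclass
class ChannelModel:
    """Boltzmann-gated conductance density plus a linear leak.

    The activation curve is g(V) = gmax / (1 + exp(-(V - Vh)/k)) with k > 0,
    i.e. conductance grows with depolarization and a smaller k means a
    steeper curve.
    """

    gmax_pS_per_pF: float
    vh_mV: float
    k_mV: float
    erev_mV: float
    activation_tau_ms: float = 0.0
    leak_pS_per_pF: float = 0.0
    leak_erev_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.gmax_pS_per_pF < 0:
            raise ValueError("gmax must be non-negative")
        if self.k_mV == 0:
            raise ValueError("slope factor k must be nonzero")
        if self.activation_tau_ms < 0:
            raise ValueError("activation tau must be non-negative")


def boltzmann_conductance(model: ChannelModel, vm_mV) -> np.ndarray | float:
    """Steady-state conductance density g(Vm) = gmax / (1 + exp(-(Vm-Vh)/k))."""
    vm = np.asarray(vm_mV, dtype=float)
    with np.errstate(over="ignore"):
        g = model.gmax_pS_per_pF / (1.0 + np.exp(-(vm - model.vh_mV) / model.k_mV))
    return g if vm.ndim else float(g)


@dataclass
class CellModel:
    """One simulated cell: capacitance plus its iso- and hypotonic channel states."""

    iso: ChannelModel
    hypo: ChannelModel
    capacitance_pF: float = 10.0
    osmotic_transition_tau_s: float = 20.0
    noise_sd_pA: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance must be positive")
        if self.noise_sd_pA < 0:
            raise ValueError("noise sd must be non-negative")


@dataclass
class CurrentTrace:
    """Sampled whole-cell record: time, command voltage and current."""

    time_ms: np.ndarray
    v_mV: np.ndarray
    i_pA: np.ndarray
    capacitance_pF: float
    condition: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (len(self.time_ms) == len(self.v_mV) == len(self.i_pA)):
            raise ValueError("time, voltage and current must have equal length")
        if np.any(np.diff(self.time_ms) <= 0):
            raise ValueError("time must be strictly increasing")


def _gated_conductance(model: ChannelModel, v: np.ndarray, dt: float) -> np.ndarray:
    ginf = boltzmann_conductance(model, v)
    tau = model.activation_tau_ms
    if tau <= 0:
        return ginf
    # first-order relaxation toward the steady-state curve, initialized at rest
    a = math.exp(-dt / tau)
    zi = lfilter([1 - a], [1, -a], np.zeros(1), zi=np.array([ginf[0] * a]))[1]
    g, _ = lfilter([1 - a], [1, -a], ginf, zi=zi)
    return g


def _state_current(model: ChannelModel, v: np.ndarray, cap: float, dt: float) -> np.ndarray:
    g = _gated_conductance(model, v, dt)
    i = g * (v - model.erev_mV)
    i = i + model.leak_pS_per_pF * (v - model.leak_erev_mV)
    return cap * i * 1e-3  # pS/pF * mV * pF = fA -> pA


def simulate_trace(
    cell: CellModel,
    protocol: VoltageProtocol,
    condition: str = "iso",
    gmax_scale: float = 1.0,
) -> CurrentTrace:
    """Simulate a whole-cell record for one condition.

    ``condition`` is "iso", "hypo" or "switch"; "switch" blends the isotonic
    current into the hypotonic current with the cell's osmotic transition time
    constant (bath exchange at t = 0).  ``gmax_scale`` multiplies the gated
    gmax of the active state(s), modeling a channel blocker as a scalar
    occupancy factor.
    """
    if condition not in ("iso", "hypo", "switch"):
        raise ValueError(f"unknown condition {condition!r}")
    dt = protocol.sampling_interval_ms
    t_parts, v_parts = [], []
    offset = 0.0
    for s in range(protocol.n_sweeps):
        ts, vs = protocol.sweep_waveform(s)
        t_parts.append(ts + offset)
        v_parts.append(vs)
        offset += protocol.sweep_duration_ms(s)
    t = np.concatenate(t_parts)
    v = np.concatenate(v_parts)

    def scaled(model: ChannelModel) -> ChannelModel:
        if gmax_scale == 1.0:
            return model
        m = ChannelModel(**asdict(model))
        m.gmax_pS_per_pF *= gmax_scale
        return m

    cap = cell.capacitance_pF
    if condition == "iso":
        i = _state_current(scaled(cell.iso), v, cap, dt)
    elif condition == "hypo":
        i = _state_current(scaled(cell.hypo), v, cap, dt)
    else:
        w = 1.0 - np.exp(-t / (cell.osmotic_transition_tau_s * 1e3))
        i_iso = _state_current(scaled(cell.iso), v, cap, dt)
        i_hypo = _state_current(scaled(cell.hypo), v, cap, dt)
        i = (1.0 - w) * i_iso + w * i_hypo

    if cell.noise_sd_pA > 0:
        rng = np.random.default_rng(cell.seed)
        i = i + rng.normal(0.0, cell.noise_sd_pA, size=i.shape)

    meta = {
        "seed": cell.seed,
        "noise_sd_pA": cell.noise_sd_pA,
        "gmax_scale": gmax_scale,
        "model": asdict(cell.hypo if condition == "hypo" else cell.iso),
        "protocol": protocol.name,
    }
    return CurrentTrace(t, v, i, capacitance_pF=cap, condition=condition, meta=meta)


def write_trace(trace: CurrentTrace, csv_path: str | Path) -> None:
    """Write a trace as CSV (time_ms, v_mV, i_pA) with a JSON side-car."""
    csv_path = Path(csv_path)
    pd.DataFrame(
        {"time_ms": trace.time_ms, "v_mV": trace.v_mV, "i_pA": trace.i_pA}
    ).to_csv(csv_path, index=False)
    sidecar = {
        "capacitance_pF": trace.capacitance_pF,
        "condition": trace.condition,
        **trace.meta,
    }
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def read_trace(csv_path: str | Path) -> CurrentTrace:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    meta = json.loads(csv_path.with_suffix(".json").read_text())
    return CurrentTrace(
        time_ms=df["time_ms"].to_numpy(),
        v_mV=df["v_mV"].to_numpy(),
        i_pA=df["i_pA"].to_numpy(),
        capacitance_pF=float(meta.pop("capacitance_pF")),
        condition=str(meta.pop("condition")),
        meta=meta,
    )
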