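"""Voltage-clamp analysis chain: trace -> steady-state I-V -> difference
current -> reversal potential -> conductance curve -> Boltzmann fit.

The chain mirrors standard whole-cell practice for swelling-activated anion
currents: per-sweep steady-state current densities are read from the tail of
each test step, hypotonic-minus-isotonic difference currents cancel any
shared background/leak conductance, division by the ohmic driving force
(V - Erev) converts current density to conductance density, and the
conductance-voltage relation is fit with a two-state Boltzmann

    g(V) = gmax / (1 + exp(-(V - Vh)/k)),   k > 0,

where gmax is the maximal conductance density (pS/pF), Vh the half-activation
voltage and k the slope factor (smaller k = steeper activation).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy import stats as sps

from .ephys_sim import CurrentTrace, VoltageProtocol
from .stats import benjamini_hochberg  # re-exported: part of this module's surface

__all__ = [
    "IVCurve",
    "ConductanceCurve",
    "BoltzmannFit",
    "step_iv",
    "difference_current",
    "estimate_reversal",
    "conductance_transform",
    "fit_boltzmann",
    "fit_difference_boltzmann",
    "benjamini_hochberg",
]


@dataclass
class IVCurve:
    """Per-voltage steady-state current density (pA/pF)."""

    vm_mV: np.ndarray
    density_pA_per_pF: np.ndarray
    condition: str = ""
    cell_id: str | None = None

    def __post_init__(self) -> None:
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        self.density_pA_per_pF = np.asarray(self.density_pA_per_pF, dtype=float)
        if self.vm_mV.shape != self.density_pA_per_pF.shape:
            raise ValueError("voltage and density arrays must match")
        order = np.argsort(self.vm_mV)
        self.vm_mV = self.vm_mV[order]
        self.density_pA_per_pF = self.density_pA_per_pF[order]
        if np.any(np.diff(self.vm_mV) <= 0):
            raise ValueError("voltages must be distinct")


@dataclass
class ConductanceCurve:
    """Per-voltage conductance density (pS/pF), with near-reversal points excluded."""

    vm_mV: np.ndarray
    g_pS_per_pF: np.ndarray
    excluded_vm_mV: np.ndarray
    erev_mV: float

    def __post_init__(self) -> None:
        self.vm_mV = np.asarray(self.vm_mV, dtype=float)
        self.g_pS_per_pF = np.asarray(self.g_pS_per_pF, dtype=float)
        self.excluded_vm_mV = np.asarray(self.excluded_vm_mV, dtype=float)


@dataclass
class BoltzmannFit:
    """Fitted (gmax, Vh, k) with 95 % confidence intervals and diagnostics."""

    gmax_pS_per_pF: float
    vh_mV: float
    k_mV: float
    ci95: dict[str, tuple[float, float]] = field(default_factory=dict)
    rss: float = float("nan")
    n_points: int = 0
    method: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def step_iv(
    trace: CurrentTrace,
    protocol: VoltageProtocol,
    window_ms: tuple[float, float] = (180.0, 200.0),
    cell_id: str | None = None,
) -> IVCurve:
    """Steady-state I-V from a step-family trace.

    For each sweep the current is averaged over ``window_ms`` (relative to the
    start of the test segment; the default is the final 20 ms of a 200 ms
    step) and divided by the cell capacitance.
    """
    if protocol.test_segment_index is None:
        raise ValueError("protocol has no test segment; cannot extract an I-V")
    if trace.capacitance_pF <= 0:
        raise ValueError("trace is missing a positive capacitance")
    idx = protocol.test_segment_index
    w0, w1 = window_ms
    densities = []
    offset = 0.0
    for s in range(protocol.n_sweeps):
        segs = protocol.sweeps[s]
        test_start = offset + sum(seg.duration_ms for seg in segs[:idx])
        test_dur = segs[idx].duration_ms
        if not (0.0 <= w0 < w1 <= test_dur):
            raise ValueError(
                f"window {window_ms} outside the {test_dur} ms test segment"
            )
        mask = (trace.time_ms >= test_start + w0 - 1e-9) & (
            trace.time_ms < test_start + w1 - 1e-9
        )
        if not np.any(mask):
            raise ValueError(f"no samples in the measurement window of sweep {s}")
        densities.append(float(np.mean(trace.i_pA[mask])) / trace.capacitance_pF)
        offset += protocol.sweep_duration_ms(s)
    return IVCurve(
        vm_mV=protocol.test_levels_mV,
        density_pA_per_pF=np.array(densities),
        condition=trace.condition,
        cell_id=cell_id,
    )


def difference_current(hypo: IVCurve, iso: IVCurve) -> IVCurve:
    """Pointwise hypotonic minus isotonic current density.

    Requires identical voltage grids and matching cell ids: conditions are
    paired within cell, and no interpolation across cells is performed.
    """
    if not np.array_equal(hypo.vm_mV, iso.vm_mV):
        raise ValueError("voltage grids differ; difference currents must be paired")
    if hypo.cell_id != iso.cell_id:
        raise ValueError(
            f"cell ids differ ({hypo.cell_id!r} vs {iso.cell_id!r}); "
            "difference currents are within-cell"
        )
    return IVCurve(
        vm_mV=hypo.vm_mV.copy(),
        density_pA_per_pF=hypo.density_pA_per_pF - iso.density_pA_per_pF,
        condition="difference",
        cell_id=hypo.cell_id,
    )


def estimate_reversal(iv: IVCurve, expected_mV: float | None = None) -> float:
    """Zero-crossing voltage of an I-V curve by linear interpolation.

    With several sign changes the crossing nearest ``expected_mV`` is chosen;
    with none, the curve does not reverse in range and an error is raised.
    """
    v, i = iv.vm_mV, iv.density_pA_per_pF
    crossings = [float(v[j]) for j in np.flatnonzero(i == 0.0)]
    for j in np.flatnonzero(i[:-1] * i[1:] < 0.0):
        crossings.append(float(v[j] - i[j] * (v[j + 1] - v[j]) / (i[j + 1] - i[j])))
    if not crossings:
        raise ValueError("current does not reverse within the voltage range")
    if len(crossings) == 1:
        return crossings[0]
    if expected_mV is None:
        raise ValueError(
            f"multiple zero crossings at {sorted(crossings)}; "
            "pass expected_mV to disambiguate"
        )
    return min(crossings, key=lambda c: abs(c - expected_mV))


def conductance_transform(
    iv: IVCurve, erev_mV: float, exclusion_half_width_mV: float = 10.0
) -> ConductanceCurve:
    """Divide current density by the driving force: g(V) = I(V) / (V - Erev).

    Voltages within ``exclusion_half_width_mV`` of the reversal potential are
    excluded (the division is numerically unstable there); they are recorded
    on the returned curve.  Result in pS/pF.
    """
    if not np.isfinite(erev_mV):
        raise ValueError("reversal potential must be finite")
    dv = iv.vm_mV - erev_mV
    keep = np.abs(dv) >= exclusion_half_width_mV
    if not np.any(keep):
        raise ValueError("all voltages fall inside the reversal exclusion window")
    g = iv.density_pA_per_pF[keep] / dv[keep] * 1e3  # pA/pF/mV -> pS/pF
    return ConductanceCurve(
        vm_mV=iv.vm_mV[keep],
        g_pS_per_pF=g,
        excluded_vm_mV=iv.vm_mV[~keep],
        erev_mV=erev_mV,
    )


def _boltzmann(params: np.ndarray, v: np.ndarray) -> np.ndarray:
    gmax, vh, k = params
    with np.errstate(over="ignore"):
        return gmax / (1.0 + np.exp(-(v - vh) / k))


def _jacobian(params: np.ndarray, v: np.ndarray) -> np.ndarray:
    gmax, vh, k = params
    u = (v - vh) / k
    with np.errstate(over="ignore"):
        s = 1.0 / (1.0 + np.exp(-u))
    ds = s * (1.0 - s)
    return np.column_stack([s, -gmax * ds / k, -gmax * ds * u / k])


# Deterministic multi-start grid: every (Vh, k) pair is tried with
# gmax = max observed conductance; the best-RSS solution wins, ties broken by
# the lower fitted Vh.
_START_VH = (-40.0, 0.0, 40.0)
_START_K = (15.0, 40.0)


def _solve(
    v: np.ndarray, g: np.ndarray, x0: np.ndarray, tol: float = 1e-15
) -> tuple[np.ndarray, float]:
    scale = max(float(np.max(np.abs(g))), 1e-12)
    res = least_squares(
        lambda p: _boltzmann(p, v) - g,
        x0,
        jac=lambda p: _jacobian(p, v),
        bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
        method="trf",
        x_scale=[scale, 30.0, 15.0],
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=2000,
    )
    return res.x, float(np.sum(res.fun**2))


def _point_estimate(v: np.ndarray, g: np.ndarray) -> tuple[np.ndarray, float]:
    g0 = max(float(np.max(g)), 1e-9)
    best: tuple[np.ndarray, float] | None = None
    for vh0 in _START_VH:
        for k0 in _START_K:
            try:
                x, rss = _solve(v, g, np.array([g0, vh0, k0]))
            except Exception:
                continue
            if (
                best is None
                or rss < best[1] * (1.0 - 1e-12)
                or (abs(rss - best[1]) <= 1e-12 * max(rss, best[1]) and x[1] < best[0][1])
            ):
                best = (x, rss)
    if best is None:
        raise RuntimeError("Boltzmann fit failed to converge from every start")
    return best


def fit_boltzmann(
    curve: ConductanceCurve,
    ci_method: str = "bootstrap",
    n_boot: int = 1000,
    seed: int | None = 0,
) -> BoltzmannFit:
    """Nonlinear least-squares Boltzmann fit of a conductance-voltage curve.

    Requires at least five retained points spanning at least 60 mV.  95 %
    confidence intervals come from a seeded percentile wild bootstrap with
    HC3 leverage adjustment (default; robust to the heteroscedastic noise the
    driving-force division creates) or from the asymptotic covariance with
    Student-t quantiles.
    """
    v = np.asarray(curve.vm_mV, dtype=float)
    g = np.asarray(curve.g_pS_per_pF, dtype=float)
    if v.size < 5:
        raise ValueError("need at least 5 conductance points to fit")
    if np.ptp(v) < 60.0:
        raise ValueError("voltage span below 60 mV; fit would be ill-determined")
    if ci_method not in ("bootstrap", "asymptotic"):
        raise ValueError(f"unknown ci method {ci_method!r}")

    x, rss = _point_estimate(v, g)
    resid = g - _boltzmann(x, v)

    if ci_method == "asymptotic":
        J = _jacobian(x, v)
        dof = max(v.size - 3, 1)
        cov = rss / dof * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        tcrit = float(sps.t.ppf(0.975, dof))
        lo, hi = x - tcrit * se, x + tcrit * se
    else:
        rng = np.random.default_rng(seed)
        yhat = _boltzmann(x, v)
        # Wild bootstrap with HC3 leverage adjustment: conductance residuals
        # are strongly heteroscedastic (driving-force division inflates noise
        # near the reversal), so each point keeps its own residual magnitude
        # instead of pooling them; 1/(1-h) undoes the fit's shrinkage.
        J = _jacobian(x, v)
        h = np.clip(np.diag(J @ np.linalg.pinv(J.T @ J) @ J.T), 0.0, 0.99)
        adj = resid / (1.0 - h)
        draws = np.empty((n_boot, 3))
        for b in range(n_boot):
            yb = yhat + adj * rng.standard_normal(adj.size)
            # warm start at the point estimate; resample fits need less precision
            xb, _ = _solve(v, yb, x, tol=1e-10)
            draws[b] = xb
        lo = np.percentile(draws, 2.5, axis=0)
        hi = np.percentile(draws, 97.5, axis=0)

    names = ("gmax_pS_per_pF", "vh_mV", "k_mV")
    ci = {
        n: (min(float(l), float(e)), max(float(h), float(e)))
        for n, l, h, e in zip(names, lo, hi, x)
    }
    return BoltzmannFit(
        gmax_pS_per_pF=float(x[0]),
        vh_mV=float(x[1]),
        k_mV=float(x[2]),
        ci95=ci,
        rss=rss,
        n_points=int(v.size),
        method=ci_method,
    )


def fit_difference_boltzmann(
    hypo: IVCurve,
    iso: IVCurve,
    erev_mV: float,
    exclusion_half_width_mV: float = 10.0,
    **fit_kwargs,
) -> BoltzmannFit:
    """Boltzmann fit of the hypotonic-minus-isotonic difference conductance.

    Because any background conductance common to both conditions subtracts
    out, the fitted parameters describe only the swelling-activated component.
    """
    diff = difference_current(hypo, iso)
    scale = max(
        float(np.max(np.abs(hypo.density_pA_per_pF))),
        float(np.max(np.abs(iso.density_pA_per_pF))),
        1e-12,
    )
    if float(np.max(np.abs(diff.density_pA_per_pF))) <= 1e-9 * scale:
        raise ValueError(
            "degenerate input: hypotonic and isotonic currents are identical, "
            "the difference conductance is zero everywhere"
        )
    curve = conductance_transform(diff, erev_mV, exclusion_half_width_mV)
    return fit_boltzmann(curve, **fit_kwargs)
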