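"""Hemodynamic and wall-mechanics metrics of a network flow solution.

All quantities derive from the (A, Q, p) time series of a
:class:`~shuntflow.hemodynamics.FlowSolution` under the same reduced-order
closures as the solver itself:

* wall shear stress from the parabolic profile, tau_w = 4 mu Q / (pi R^3)
  with the deformed radius R = sqrt(A/pi);
* TAWSS as the final-cycle mean of |tau_w| (magnitude convention);
* von Mises wall stress from the thin-walled biaxial pressure-vessel state
  sigma_theta = p R / h, sigma_z = p R / (2 h), sigma_r ~ 0, so
  sigma_vm = sigma_theta * sqrt(3)/2;
* radial displacement u_r = sqrt(A/pi) - sqrt(A0/pi).

These are lower-fidelity analogues of 3-D near-wall gradients and bending
stress concentrations; scenario comparisons are therefore direction-of-effect
tools, not magnitude reproductions of any specific 3-D anatomy.

Relative deviations between scenarios use the symmetric definition
max_t |x1 - x2| / max(|x1|, |x2|, eps), invariant (up to sign) to which
scenario is the baseline.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hemodynamics import (
    FlowSolution,
    FluidProperties,
    SolverError,
    VesselNetwork,
    shunt_flow_series,
    solve_pulsatile,
)

__all__ = [
    "wall_shear_stress",
    "tawss",
    "von_mises_wall_stress",
    "radial_displacement",
    "MetricReport",
    "metric_report",
    "relative_deviation",
    "compare_scenarios",
    "measure_pulse_wave_speed",
]

EPS = 1e-12


def _require_converged(solution: FlowSolution) -> None:
    if not solution.converged:
        raise SolverError(
            "metrics require a converged (periodic) solution; residual history "
            f"{solution.residual_history}"
        )


def wall_shear_stress(
    solution: FlowSolution, fluid: FluidProperties | None = None
) -> dict[str, np.ndarray]:
    """Wall shear stress series per segment node, Pa (signed with the flow)."""
    _require_converged(solution)
    mu = (fluid or solution.fluid).viscosity
    out = {}
    for name, seg in solution.segments.items():
        R = np.sqrt(seg.A / np.pi)
        out[name] = 4.0 * mu * seg.Q / (np.pi * R**3)
    return out


def tawss(
    wss: np.ndarray, t: np.ndarray, period: float, n_cycles: int | None = None
) -> np.ndarray:
    """Time-averaged |WSS| over the final full cycle, Pa.

    ``wss`` is (nt,) or (nt, nx) sampled at times ``t`` which must span at
    least one full cycle; the average is (1/T) int |tau_w| dt over the last
    complete cycle.
    """
    t = np.asarray(t, float)
    span = t[-1] - t[0]
    if span + 1e-9 < period:
        raise ValueError(f"series spans {span:.4f}s, less than one period {period}s")
    k = n_cycles if n_cycles is not None else int(np.floor((t[-1] + 1e-9) / period))
    mask = (t > k * period - period - 1e-12) & (t <= k * period + 1e-12)
    tt = t[mask]
    w = np.abs(np.asarray(wss)[mask])
    return np.trapezoid(w, tt, axis=0) / (tt[-1] - tt[0])


def von_mises_wall_stress(
    solution: FlowSolution, network: VesselNetwork | None = None
) -> dict[str, np.ndarray]:
    """Thin-wall von Mises stress series per segment node, kPa."""
    _require_converged(solution)
    out = {}
    for name, seg in solution.segments.items():
        R = np.sqrt(seg.A / np.pi)
        s_theta = seg.p * R / seg.h
        out[name] = np.sqrt(3.0) / 2.0 * s_theta / 1e3
    return out


def radial_displacement(
    solution: FlowSolution, network: VesselNetwork | None = None
) -> dict[str, np.ndarray]:
    """Radial wall displacement series per segment node, mm."""
    _require_converged(solution)
    out = {}
    for name, seg in solution.segments.items():
        out[name] = (np.sqrt(seg.A / np.pi) - np.sqrt(seg.A0 / np.pi)) * 1e3
    return out


@dataclass(frozen=True)
class MetricReport:
    """Per-segment summary metrics of one converged run."""

    scenario: dict
    table: pd.DataFrame  # indexed by segment
    shunt_mean_flow_ml_min: float
    shunt_peak_flow_ml_min: float

    def segment(self, name: str) -> pd.Series:
        return self.table.loc[name]


def metric_report(solution: FlowSolution, scenario: dict | None = None) -> MetricReport:
    """Compute the summary metric table of a converged solution.

    Peaks and means are taken over the final cycle and over segment nodes:
    peak WSS (Pa), TAWSS (Pa, node max), peak von Mises stress (kPa), peak
    radial displacement (mm), and the shunt cycle statistics.
    """
    _require_converged(solution)
    mask = solution.final_cycle_mask()
    t = solution.t
    wss = wall_shear_stress(solution)
    vm = von_mises_wall_stress(solution)
    disp = radial_displacement(solution)
    rows = {}
    for name, seg in solution.segments.items():
        w = wss[name]
        rows[name] = {
            "peak_wss_pa": float(np.max(np.abs(w[mask]))),
            "mean_wss_pa": float(np.mean(np.abs(w[mask]))),
            "tawss_pa": float(np.max(tawss(w, t, solution.period, solution.n_cycles_run))),
            "peak_von_mises_kpa": float(np.max(vm[name][mask])),
            "peak_displacement_mm": float(np.max(np.abs(disp[name][mask]))),
            "peak_pressure_mmhg": float(np.max(seg.p[mask]) / 133.322),
        }
    table = pd.DataFrame(rows).T
    if solution.network.shunt is not None:
        sf = shunt_flow_series(solution)
        mean_q, peak_q = sf.mean_ml_min, sf.peak_ml_min
    else:
        mean_q = peak_q = float("nan")
    return MetricReport(
        scenario=dict(scenario or {}),
        table=table,
        shunt_mean_flow_ml_min=mean_q,
        shunt_peak_flow_ml_min=peak_q,
    )


def relative_deviation(x1: np.ndarray, x2: np.ndarray, eps: float = EPS) -> float:
    """Symmetric relative deviation max|x1-x2| / max(|x1|, |x2|, eps)."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    scale = max(float(np.max(np.abs(x1))), float(np.max(np.abs(x2))), eps)
    return float(np.max(np.abs(x1 - x2))) / scale


def _resample_cycle(sf, n: int = 200) -> np.ndarray:
    grid = np.linspace(sf.t[0], sf.t[-1], n)
    return np.interp(grid, sf.t, sf.q)


def compare_scenarios(
    cells: dict,
    solver=solve_pulsatile,
) -> pd.DataFrame:
    """Run a scenario matrix and tabulate metrics plus pairwise deviations.

    ``cells`` maps a scenario label (any hashable, e.g. a (aorta, shunt,
    placement) tuple) to a zero-argument callable returning a converged
    :class:`FlowSolution` (or to a pre-computed solution).  Unconverged or
    failing cells are reported with ``status`` set and NaN metrics rather
    than aborting the whole comparison.

    Returns a DataFrame with one row per cell; pairwise shunt-flow and
    descending-aorta WSS deviations are attached as a ``.attrs['deviations']``
    DataFrame.
    """
    solutions: dict = {}
    rows = []
    for label, cell in cells.items():
        try:
            sol = cell() if callable(cell) else cell
            rep = metric_report(sol, scenario={"label": label})
            solutions[label] = sol
            row = {
                "label": str(label),
                "status": "ok",
                "shunt_mean_flow_ml_min": rep.shunt_mean_flow_ml_min,
                "shunt_peak_flow_ml_min": rep.shunt_peak_flow_ml_min,
            }
            for seg in ("shunt", "desc_aorta"):
                if seg in rep.table.index:
                    row[f"{seg}_peak_wss_pa"] = rep.table.loc[seg, "peak_wss_pa"]
                    row[f"{seg}_tawss_pa"] = rep.table.loc[seg, "tawss_pa"]
                    row[f"{seg}_peak_von_mises_kpa"] = rep.table.loc[seg, "peak_von_mises_kpa"]
                    row[f"{seg}_peak_displacement_mm"] = rep.table.loc[
                        seg, "peak_displacement_mm"
                    ]
        except (SolverError, ValueError) as exc:
            row = {"label": str(label), "status": f"failed: {exc}"}
        rows.append(row)
    table = pd.DataFrame(rows).set_index("label")

    dev_rows = []
    for (l1, s1), (l2, s2) in itertools.combinations(solutions.items(), 2):
        try:
            q1 = _resample_cycle(shunt_flow_series(s1))
            q2 = _resample_cycle(shunt_flow_series(s2))
            dev = {"pair": f"{l1} vs {l2}", "shunt_flow_dev": relative_deviation(q1, q2)}
            if "desc_aorta" in s1.segments and "desc_aorta" in s2.segments:
                w1 = wall_shear_stress(s1)["desc_aorta"]
                w2 = wall_shear_stress(s2)["desc_aorta"]
                m1, m2 = s1.final_cycle_mask(), s2.final_cycle_mask()
                dev["desc_aorta_wss_dev"] = relative_deviation(
                    np.max(np.abs(w1[m1]), axis=0), np.max(np.abs(w2[m2]), axis=0)
                )
            dev_rows.append(dev)
        except (SolverError, ValueError):
            continue
    table.attrs["deviations"] = pd.DataFrame(dev_rows)
    return table


def measure_pulse_wave_speed(
    solution: FlowSolution, segment: str, x1: float, x2: float
) -> float:
    """Pulse transit speed between two stations of one segment, m/s.

    Locates the pressure-peak arrival time at each station with a parabolic
    refinement around the sampled maximum; intended for a single transient
    pulse launched into a uniform tube (Moens-Korteweg validation).
    """
    seg = solution.segments[segment]
    t = solution.t

    def arrival(x: float) -> float:
        i = int(np.argmin(np.abs(seg.x - x)))
        series = seg.p[:, i]
        k = int(np.argmax(series))
        if 0 < k < series.size - 1:
            y0, y1, y2 = series[k - 1 : k + 2]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            return float(t[k] + delta * (t[min(k + 1, t.size - 1)] - t[k - 1]) / 2.0)
        return float(t[k])

    t1, t2 = arrival(x1), arrival(x2)
    if t2 <= t1:
        raise ValueError("pulse peak did not propagate between the stations")
    return (x2 - x1) / (t2 - t1)
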