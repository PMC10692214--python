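"""Derived pumping metrics for a completed chain simulation.

All metrics are evaluated on the final complete contraction cycle of a
periodic steady-state result: ejection fraction and fractional pump
function, cycle-averaged and peak flows, wall shear stress statistics and
their signal-to-noise ratio, radial contraction velocity, valvular energy
loss, activation integration, the bottleneck trace and per-lymphangion mean
pressures.

Spatial sampling convention: the "monitored" area series averages the middle
node of each lymphangion -- the locations the kymograph-style readouts
sample.  All-node chain averages and per-lymphangion values are reported
alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .activation import ActivationField
from .solver import SimulationResult
from .units import (
    CM3_S_TO_UL_H,
    CM_S_TO_MM_S,
    CM_S_TO_UM_S,
    CMH2O_TO_DYN_PER_CM2,
)

__all__ = [
    "MetricsReport",
    "ejection_fraction",
    "fractional_pump_function",
    "wall_shear_stress",
    "wss_snr",
    "radial_velocity",
    "valve_energy_loss",
    "activation_integration",
    "bottleneck_trace",
    "summarize",
]

SNR_WINDOW_DEFAULT = 100  # samples (0.5 s at the 5 ms default step)
AI_SCALE = 1000.0  # AI = per-mille mean occupancy of the space-time domain


def ejection_fraction(area_series: np.ndarray) -> float:
    """EF = (A_EDA - A_ESA) / A_EDA from an average-area series.

    ``area_series`` may be 1D (already averaged) or 2D ``(nodes, steps)``,
    in which case the node mean is taken first.  End-diastolic area is the
    cycle maximum of the averaged series, end-systolic the minimum.
    """
    a = np.asarray(area_series, dtype=float)
    if a.ndim == 2:
        a = a.mean(axis=0)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    a_eda = float(a.max())
    a_esa = float(a.min())
    if a_eda <= 0:
        raise ValueError("end-diastolic area must be positive")
    return (a_eda - a_esa) / a_eda


def fractional_pump_function(ef: float, frequency: float) -> float:
    """FPF (1/min) = contraction frequency (1/min) x ejection fraction."""
    if not 0.0 <= ef <= 1.0:
        raise ValueError("EF must lie in [0, 1]")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return frequency * ef


def wall_shear_stress(Q, d, mu: float, zeta: float = 2.0) -> np.ndarray:
    """WSS (dyn/cm^2) from the 1D friction closure.

    WSS = tau/(pi d) = -2 (zeta+2) mu Q / (A d); for zeta = 2 this is the
    Hagen-Poiseuille wall shear 32 mu Q / (pi d^3), negative during forward
    (antegrade) flow by convention.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    A = 0.25 * np.pi * d * d
    wss_cmh2o = -2.0 * (zeta + 2.0) * mu * np.asarray(Q) / (A * d)
    out = wss_cmh2o * CMH2O_TO_DYN_PER_CM2
    return out if np.ndim(out) else float(out)


def moving_average_trailing(x: np.ndarray, window_size: int) -> np.ndarray:
    """Trailing moving average with truncated averaging at the start."""
    x = np.asarray(x, dtype=float)
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    c = np.cumsum(np.insert(x, 0, 0.0))
    n = x.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - window_size + 1)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def wss_snr(wss_series, window_size: int = SNR_WINDOW_DEFAULT) -> float:
    """Signal-to-noise ratio of a WSS series, SNR = ln((MSE0/MSE)^2).

    MSE is the root-mean-square deviation between the series and its
    trailing moving-average filtered counterpart, MSE0 the root mean square
    of the raw series.  A perfectly smooth series (zero filter residual)
    returns +inf; an identically zero series is undefined and raises.
    """
    x = np.asarray(wss_series, dtype=float)
    if x.size < window_size:
        raise ValueError("series shorter than the filter window")
    smooth = moving_average_trailing(x, window_size)
    mse0 = math.sqrt(float(np.mean(x * x)))
    if mse0 == 0.0:
        raise ValueError("SNR undefined for an identically zero series")
    mse = math.sqrt(float(np.mean((x - smooth) ** 2)))
    if mse <= 1e-14 * mse0:  # residual at roundoff: perfectly smooth signal
        return math.inf
    return math.log((mse0 / mse) ** 2)


def radial_velocity(d_series: np.ndarray, dt: float) -> np.ndarray:
    """Radial wall velocity v = dr/dt (same length units as ``d_series``/s).

    Central differences on the radius series r = d/2 (one-sided at the
    ends); exact for linearly varying radii.
    """
    d = np.asarray(d_series, dtype=float)
    if d.shape[-1] < 3:
        raise ValueError("need at least 3 samples")
    r = d / 2.0
    return np.gradient(r, dt, axis=-1)


def valve_energy_loss(P_up, u_up, P_down, u_down, rho_f: float):
    """Total mechanical-energy drop across a valve (cmH2O).

    Phi = P + rho u^2 / 2 per volume; returns Phi_upstream - Phi_downstream.
    """
    phi_up = np.asarray(P_up, dtype=float) + 0.5 * rho_f * np.asarray(u_up) ** 2
    phi_down = (
        np.asarray(P_down, dtype=float) + 0.5 * rho_f * np.asarray(u_down) ** 2
    )
    out = phi_up - phi_down
    return out if np.ndim(out) else float(out)


def activation_integration(
    field_or_values, scale: float = AI_SCALE
) -> float:
    """Activation integration AI: space-time integral of t_act.

    Convention: the integral is taken on the normalized domain (z/L, t/T),
    which reduces to the mean of t_act over all grid samples, and scaled by
    ``scale`` (default 1000: AI is the per-mille occupancy of the space-time
    domain).  The convention is a calibration choice and is reported with
    the metric.
    """
    values = (
        field_or_values.values
        if isinstance(field_or_values, ActivationField)
        else np.asarray(field_or_values, dtype=float)
    )
    if values.size == 0:
        return 0.0
    return float(values.mean()) * scale


def bottleneck_trace(q_field: np.ndarray) -> tuple[np.ndarray, float]:
    """Bottleneck node (argmax |Q| per step) and its stationarity score.

    ``q_field`` is ``(nodes, steps)`` for one lymphangion.  Ties break
    toward the most upstream node (numpy argmax convention).  The score is
    the fraction of steps spent at the modal node.
    """
    q = np.abs(np.asarray(q_field, dtype=float))
    if q.ndim != 2 or q.shape[1] < 1:
        raise ValueError("q_field must be (nodes, steps) with >= 1 step")
    trace = np.argmax(q, axis=0)
    modal = np.bincount(trace).argmax()
    score = float(np.mean(trace == modal))
    return trace, score


@dataclass
class MetricsReport:
    """All derived quantities for one simulation run."""

    scenario: str
    ef: float
    ef_chain_all_nodes: float
    ef_per_lymphangion: list[float]
    fpf_per_min: float
    frequency_per_min: float
    mean_flow_ul_h: float
    peak_flow_ul_h: float
    min_flow_ul_h: float
    area_reduction_pct: float
    area_reduction_all_nodes_pct: float
    mean_pressure_per_lymphangion: list[float]
    wss_mean_dyn_cm2: float
    wss_mean_abs_dyn_cm2: float
    wss_peak_systolic_dyn_cm2: float
    wss_peak_diastolic_dyn_cm2: float
    wss_snr: float
    wss_snr_window: int
    peak_forward_velocity_mm_s: float
    peak_reverse_velocity_mm_s: float
    contraction_velocity_peak_um_s: float
    energy_loss_per_valve_cmh2o: list[float]
    ai: float
    ai_convention: str
    bottleneck_scores: list[float]
    mass_conservation_residual: float
    converged: bool
    n_cycles_run: int
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None, **meta) -> str:
        payload = {**asdict(self), **meta}
        text = json.dumps(payload, indent=2, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_flat_frame(self):
        import pandas as pd

        flat = {}
        for key, val in asdict(self).items():
            if isinstance(val, list):
                for i, v in enumerate(val):
                    flat[f"{key}_{i}"] = v
            elif isinstance(val, dict):
                continue
            else:
                flat[key] = val
        return pd.DataFrame([flat])


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if o in (math.inf, -math.inf):
        return str(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def summarize(
    result: SimulationResult,
    frequency_per_min: float,
    activation: ActivationField | None = None,
    scenario: str = "",
    snr_window: int = SNR_WINDOW_DEFAULT,
) -> MetricsReport:
    """Populate a :class:`MetricsReport` from a steady-state result."""
    from .solver import check_mass_conservation

    geo = result.geometry
    idx = result.last_cycle()
    M = geo.nodes_per_lymphangion
    mid_nodes = geo.mid_node_indices()
    dt = float(result.t[1] - result.t[0])

    # areas and EF ---------------------------------------------------------
    a_mon = result.A[mid_nodes][:, idx]
    ef = ejection_fraction(a_mon)
    a_all = result.A[:, idx]
    ef_all = ejection_fraction(a_all)
    ef_per_l = [
        ejection_fraction(result.A[ell * M : (ell + 1) * M, idx])
        for ell in range(geo.n_lymphangions)
    ]
    fpf = fractional_pump_function(ef, frequency_per_min)
    series = a_mon.mean(axis=0)
    area_red = (series.max() - series.min()) / series.max() * 100.0
    series_all = a_all.mean(axis=0)
    area_red_all = (series_all.max() - series_all.min()) / series_all.max() * 100.0

    # flows ----------------------------------------------------------------
    mean_flow = result.cycle_mean_outflow() * CM3_S_TO_UL_H
    q_cycle = result.Q[:, idx]
    peak_flow = float(q_cycle.max()) * CM3_S_TO_UL_H
    min_flow = float(q_cycle.min()) * CM3_S_TO_UL_H

    # velocities -----------------------------------------------------------
    q_node = result.node_flow()[:, idx]
    u = q_node / result.A[:, idx]
    peak_fwd = float(u.max()) * CM_S_TO_MM_S
    peak_rev = float(u.min()) * CM_S_TO_MM_S

    # wall shear stress ----------------------------------------------------
    wss = wall_shear_stress(
        q_node, result.d[:, idx], result.fluid.mu, result.fluid.zeta
    )
    wss_mean = float(wss.mean())
    mid_chain_node = geo.n_nodes // 2
    wss_mid = wall_shear_stress(
        result.node_flow()[mid_chain_node, idx],
        result.d[mid_chain_node, idx],
        result.fluid.mu,
        result.fluid.zeta,
    )
    snr = wss_snr(wss_mid, snr_window)

    # contraction velocity -------------------------------------------------
    v_rad = radial_velocity(result.d[mid_nodes][:, idx], dt)
    v_peak = float(np.max(np.abs(v_rad))) * CM_S_TO_UM_S

    # pressures ------------------------------------------------------------
    mean_p = [
        float(result.P[ell * M : (ell + 1) * M, idx].mean())
        for ell in range(geo.n_lymphangions)
    ]

    # valvular energy loss -------------------------------------------------
    up, down = result.valve_end_pressures()
    n_valves = geo.n_valves
    q_valves = result.Q[result.valve_faces]
    losses = []
    for v in range(n_valves):
        up_node = v * M - 1 if v > 0 else 0
        down_node = v * M if v < n_valves - 1 else geo.n_nodes - 1
        a_up = result.A[up_node, idx]
        a_down = result.A[down_node, idx]
        u_up = q_valves[v, idx] / a_up
        u_down = q_valves[v, idx] / a_down
        dphi = valve_energy_loss(
            up[v, idx], u_up, down[v, idx], u_down, result.fluid.rho_f
        )
        losses.append(float(np.mean(np.abs(dphi))))

    # activation integration ----------------------------------------------
    if activation is not None:
        ai = activation_integration(activation)
    else:
        ai = activation_integration(result.t_act[:, idx])

    # bottleneck -----------------------------------------------------------
    scores = []
    for ell in range(geo.n_lymphangions):
        _, score = bottleneck_trace(q_node[ell * M : (ell + 1) * M])
        scores.append(score)

    return MetricsReport(
        scenario=scenario,
        ef=ef,
        ef_chain_all_nodes=ef_all,
        ef_per_lymphangion=ef_per_l,
        fpf_per_min=fpf,
        frequency_per_min=frequency_per_min,
        mean_flow_ul_h=mean_flow,
        peak_flow_ul_h=peak_flow,
        min_flow_ul_h=min_flow,
        area_reduction_pct=float(area_red),
        area_reduction_all_nodes_pct=float(area_red_all),
        mean_pressure_per_lymphangion=mean_p,
        wss_mean_dyn_cm2=wss_mean,
        wss_mean_abs_dyn_cm2=abs(wss_mean),
        wss_peak_systolic_dyn_cm2=float(wss.min()),
        wss_peak_diastolic_dyn_cm2=float(wss.max()),
        wss_snr=snr,
        wss_snr_window=snr_window,
        peak_forward_velocity_mm_s=peak_fwd,
        peak_reverse_velocity_mm_s=peak_rev,
        contraction_velocity_peak_um_s=v_peak,
        energy_loss_per_valve_cmh2o=losses,
        ai=ai,
        ai_convention=f"mean t_act over the (node, step) grid x {AI_SCALE:g}",
        bottleneck_scores=scores,
        mass_conservation_residual=check_mass_conservation(result),
        converged=result.converged,
        n_cycles_run=len(result.cycle_outflows),
    )
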