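"""Configuration schema and builders for a chain simulation.

The full configuration mirrors the simulation-parameter and contractility
tables: geometry (three 1 mm lymphangions, dz = 50 um), fluid properties
(viscosity 1e-5 cmH2O s, density 1070e-6 cmH2O s^2/cm^2, velocity-profile
constant 2), boundary pressures (3.5 / 4 cmH2O), wall-curve coefficients,
valve sigmoid parameters, solver controls and the activation metrics of the
selected scenario.  Unknown keys are rejected; structured-text (YAML/JSON)
files round-trip losslessly.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import activation as act
from .solver import ChainGeometry, ChainSolver, FluidParams, SimulationResult
from .valve import ValveParams
from .wall import ConstitutiveCurveSet, calibrate_default_curves

__all__ = [
    "SimulationConfig",
    "load_config",
    "default_config",
    "run_simulation",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ActivationConfig(_Model):
    sites_per_cm: float = Field(10.0, gt=0)
    conduction_speed_cm_s: float = Field(0.98, gt=0)
    frequency_per_min: float = Field(8.3, gt=0)
    period_s: float = Field(7.23, gt=0)
    pattern: Literal["antegrade", "alternating", "retrograde"] = "antegrade"


class GeometryConfig(_Model):
    n_lymphangions: int = Field(3, ge=1)
    lymphangion_length_cm: float = Field(0.1, gt=0)
    dz_cm: float = Field(0.005, gt=0)
    taper: float = 0.0


class FluidConfig(_Model):
    viscosity_cmh2o_s: float = Field(1e-5, gt=0)
    density_cmh2o_s2_cm2: float = Field(1070e-6, gt=0)
    zeta: float = Field(2.0, ge=2.0)
    delta_s: Optional[float] = None


class WallConfig(_Model):
    d0_um: float = Field(255.0, gt=0)
    anchor_pressure_cmh2o: float = Field(3.75, gt=0)
    pre_max_ratio: float = Field(1.03, gt=0)
    pre_min_ratio: float = Field(0.55, gt=0)
    peak_plateau_ratio: float = Field(0.39, gt=0)
    peak_min_ratio: float = Field(0.27, gt=0)
    peak_k_per_cmh2o: float = Field(1.0, gt=0)
    lumen_floor_ratio: float = Field(0.05, gt=0, lt=1)


class ValveConfig(_Model):
    rv_min: float = Field(6.6e3, gt=0)
    rv_max: float = Field(1.0e7, gt=0)
    s_o: float = Field(19.5, gt=0)
    p_o: float = -0.46
    s_f: float = Field(2.0, gt=0)
    p_f: float = -40.0


class BoundaryConfig(_Model):
    p_in_cmh2o: float = 3.5
    p_out_cmh2o: float = 4.0


class SolverConfig(_Model):
    dt_s: float = Field(0.005, gt=0)
    n_cycles_max: int = Field(15, ge=1)
    min_cycles: int = Field(5, ge=1)
    steady_tol: float = Field(0.01, gt=0)
    picard_tol: float = Field(1e-8, gt=0)
    picard_max_iter: int = Field(80, ge=1)


class SimulationConfig(_Model):
    scenario: str = "WT"
    activation: ActivationConfig = ActivationConfig()
    geometry: GeometryConfig = GeometryConfig()
    fluid: FluidConfig = FluidConfig()
    wall: WallConfig = WallConfig()
    valve: ValveConfig = ValveConfig()
    boundary: BoundaryConfig = BoundaryConfig()
    solver: SolverConfig = SolverConfig()

    @model_validator(mode="after")
    def _period_divisible(self):
        spc = self.activation.period_s / self.solver.dt_s
        if abs(spc - round(spc)) > 1e-9:
            raise ValueError("period_s must be an integer multiple of dt_s")
        return self

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.model_dump(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def load_config(path) -> SimulationConfig:
    """Load and validate a YAML/JSON configuration file.

    An empty file yields the full default configuration (the wild-type
    scenario); unknown or invalid keys raise a descriptive error.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return SimulationConfig.model_validate(data or {})


def default_config() -> SimulationConfig:
    return SimulationConfig()


# -- builders -------------------------------------------------------------


def build_geometry(cfg: SimulationConfig) -> ChainGeometry:
    g = cfg.geometry
    return ChainGeometry(
        n_lymphangions=g.n_lymphangions,
        lymphangion_length=g.lymphangion_length_cm,
        dz=g.dz_cm,
        taper=g.taper,
    )


def build_fluid(cfg: SimulationConfig) -> FluidParams:
    f = cfg.fluid
    return FluidParams(
        mu=f.viscosity_cmh2o_s,
        rho_f=f.density_cmh2o_s2_cm2,
        zeta=f.zeta,
        delta_s=f.delta_s,
    )


def build_curves(cfg: SimulationConfig) -> ConstitutiveCurveSet:
    w = cfg.wall
    return calibrate_default_curves(
        D0_um=w.d0_um,
        anchor_pressure=w.anchor_pressure_cmh2o,
        pre_max_ratio=w.pre_max_ratio,
        pre_min_ratio=w.pre_min_ratio,
        peak_plateau_ratio=w.peak_plateau_ratio,
        peak_min_ratio=w.peak_min_ratio,
        peak_k=w.peak_k_per_cmh2o,
    )


def build_valves(cfg: SimulationConfig) -> ValveParams:
    v = cfg.valve
    return ValveParams(
        rv_min=v.rv_min, rv_max=v.rv_max, s_o=v.s_o, p_o=v.p_o,
        s_f=v.s_f, p_f=v.p_f,
    )


def build_activation(cfg: SimulationConfig) -> act.ActivationField:
    a = cfg.activation
    geometry = build_geometry(cfg)
    params = act.derive_activation_params(
        sites_per_length=a.sites_per_cm,
        conduction_speed=a.conduction_speed_cm_s,
        frequency=a.frequency_per_min,
        period_T=a.period_s,
    )
    sites = act.place_pacemakers(
        chain_length=geometry.chain_length,
        sites_per_length=a.sites_per_cm,
        pattern=a.pattern,
        period_T=a.period_s,
        conduction_speed=a.conduction_speed_cm_s,
    )
    spc = int(round(a.period_s / cfg.solver.dt_s))
    t_grid = np.arange(spc) * cfg.solver.dt_s
    return act.build_activation_field(sites, params, geometry.node_z, t_grid)


def build_solver(cfg: SimulationConfig) -> ChainSolver:
    return ChainSolver(
        geometry=build_geometry(cfg),
        fluid=build_fluid(cfg),
        curves=build_curves(cfg),
        valve_params=build_valves(cfg),
        activation=build_activation(cfg),
        p_in=cfg.boundary.p_in_cmh2o,
        p_out=cfg.boundary.p_out_cmh2o,
        dt=cfg.solver.dt_s,
        picard_tol=cfg.solver.picard_tol,
        picard_max_iter=cfg.solver.picard_max_iter,
        lumen_floor_ratio=cfg.wall.lumen_floor_ratio,
        d0_um=cfg.wall.d0_um,
    )


def run_simulation(cfg: SimulationConfig) -> SimulationResult:
    """Build every model component from the configuration and run to
    periodic steady state (or the cycle cap)."""
    solver = build_solver(cfg)
    return solver.run(
        n_cycles_max=cfg.solver.n_cycles_max,
        min_cycles=cfg.solver.min_cycles,
        steady_tol=cfg.solver.steady_tol,
    )
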