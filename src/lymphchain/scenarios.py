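"""Scenario presets and drivers: WT, KO Cases 1-3, and sensitivity sweeps.

The wild-type (WT) preset carries the contractility metrics of the healthy
mouse line (conduction speed 0.98 cm/s, 10 initiation sites/cm, frequency
8.3/min, period 7.23 s, all signals antegrade); the three Connexin-45
knock-out (KO) presets share one metric set (0.063 cm/s, 11 sites/cm,
15.8/min, 3.80 s) and differ only in pacemaking-signal directionality:
Case 1 all antegrade, Case 2 alternating antegrade/retrograde, Case 3 all
retrograde.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .config import (
    SimulationConfig,
    build_activation,
    run_simulation,
)
from .metrics import MetricsReport, summarize
from .solver import SimulationResult

__all__ = [
    "SCENARIOS",
    "scenario_config",
    "run_scenario",
    "sensitivity_sweep",
]

log = logging.getLogger("lymphchain")

#: contractility metrics per scenario (speed cm/s, sites/cm, freq/min,
#: period s, signal-direction pattern)
SCENARIOS: dict[str, dict] = {
    "WT": dict(
        conduction_speed_cm_s=0.98, sites_per_cm=10.0,
        frequency_per_min=8.3, period_s=7.23, pattern="antegrade",
    ),
    "KO1": dict(
        conduction_speed_cm_s=0.063, sites_per_cm=11.0,
        frequency_per_min=15.8, period_s=3.80, pattern="antegrade",
    ),
    "KO2": dict(
        conduction_speed_cm_s=0.063, sites_per_cm=11.0,
        frequency_per_min=15.8, period_s=3.80, pattern="alternating",
    ),
    "KO3": dict(
        conduction_speed_cm_s=0.063, sites_per_cm=11.0,
        frequency_per_min=15.8, period_s=3.80, pattern="retrograde",
    ),
}


def scenario_config(name: str, **overrides) -> SimulationConfig:
    """Full configuration for a named scenario preset.

    Keyword overrides are applied to the activation block (e.g. a swept
    frequency); any other configuration field can be changed on the
    returned object.
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        )
    metrics = {**SCENARIOS[name], **overrides}
    cfg = SimulationConfig(scenario=name)
    for key, val in metrics.items():
        setattr(cfg.activation, key, val)
    return cfg


def run_scenario(
    name: str,
    outdir: str | Path | None = None,
    config: SimulationConfig | None = None,
) -> tuple[SimulationResult, MetricsReport]:
    """Run one scenario to periodic steady state and summarize it.

    The pipeline is fully deterministic (no randomness anywhere); when
    ``outdir`` is given, tidy per-node and per-valve CSVs, the metrics JSON
    (with a provenance block: config hash and package version) and the
    activation kymograph are persisted there.
    """
    cfg = config if config is not None else scenario_config(name)
    log.info("running scenario %s (period %.2f s)", name, cfg.activation.period_s)
    result = run_simulation(cfg)
    field = build_activation(cfg)
    report = summarize(
        result,
        frequency_per_min=cfg.activation.frequency_per_min,
        activation=field,
        scenario=name,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.to_tidy_frame().to_csv(outdir / f"{name}_nodes.csv", index=False)
        result.valve_frame().to_csv(outdir / f"{name}_valves.csv", index=False)
        report.to_json(
            outdir / f"{name}_metrics.json",
            provenance={
                "config_hash": cfg.config_hash(),
                "lymphchain_version": __version__,
            },
        )
        cfg.to_yaml(outdir / f"{name}_config.yaml")
        field.plot_kymograph(outdir / f"{name}_activation.png")
    return result, report


def sensitivity_sweep(
    scenario: str = "KO1",
    frequencies_per_min=None,
    sites_per_cm=None,
):
    """Grid sweep over contraction frequency and pacemaker density.

    One simulation per grid point; the contraction period is tied to the
    swept frequency (T = 60/f).  Failures at individual grid points are
    logged and reported as NaN rows so the sweep always completes.  Returns
    a tidy DataFrame (frequency, sites_per_cm, mean_flow_ul_h, ef).
    """
    import pandas as pd

    base = SCENARIOS[scenario]
    if frequencies_per_min is None:
        # minimum measured and mean KO frequency
        frequencies_per_min = [14.5, base["frequency_per_min"]]
    if sites_per_cm is None:
        sites_per_cm = [9.0, base["sites_per_cm"]]

    rows = []
    for freq in frequencies_per_min:
        for sites in sites_per_cm:
            period = 60.0 / freq
            cfg = scenario_config(scenario)
            cfg.activation.frequency_per_min = freq
            cfg.activation.sites_per_cm = sites
            # keep the period an exact multiple of dt
            dt = cfg.solver.dt_s
            period = round(period / dt) * dt
            cfg.activation.period_s = period
            try:
                _, report = run_scenario(scenario, config=cfg)
                rows.append(
                    dict(
                        frequency_per_min=freq,
                        sites_per_cm=sites,
                        mean_flow_ul_h=report.mean_flow_ul_h,
                        ef=report.ef,
                    )
                )
            except Exception as exc:  # per-point failure: log and continue
                log.warning(
                    "sweep point (f=%.2f, sites=%.1f) failed: %s",
                    freq, sites, exc,
                )
                rows.append(
                    dict(
                        frequency_per_min=freq,
                        sites_per_cm=sites,
                        mean_flow_ul_h=np.nan,
                        ef=np.nan,
                    )
                )
    return pd.DataFrame(rows)
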