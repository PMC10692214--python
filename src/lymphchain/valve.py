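"""Secondary-valve mechanics: sigmoidal pressure-dependent resistance.

Each intraluminal valve is a lumped, zero-length resistive junction whose
resistance depends on the trans-valvular pressure difference
``dp = P_upstream - P_downstream`` (favorable pressure positive):

* open state, ``dp > p_o``:        Rv -> Rv_min;
* closed plateau, ``p_f < dp < p_o``: Rv -> Rv_min + Rv_max;
* failure, ``dp < p_f``:           resistance collapses again (leaflet
  prolapse under a large adverse load).

The transition is a sum of two logistic sigmoids in the Bertram lineage,

    Rv(dp) = Rv_min + Rv_max * ( sigma(s_o (p_o - dp))
                               + sigma(s_f (dp - p_f)) - 1 ),

with sigma the logistic function and s_o, s_f > 0.  A slightly negative
opening threshold p_o biases the valve to remain open at a zero pressure
gradient, which favors forward wave propagation.  The default failure
threshold sits far outside the physiological operating range, so failure
never triggers in the shipped scenarios.

Default numeric values are calibrated stand-ins (the cited experimental
sigmoid is only available graphically); every parameter is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

__all__ = ["ValveParams", "valve_resistance", "valve_flow"]


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ValveParams:
    """Sigmoidal valve-resistance parameters (cmH2O, s, cm^3)."""

    rv_min: float = 6.6e3  # cmH2O s/cm^3, open-valve resistance
    rv_max: float = 1.0e7  # cmH2O s/cm^3, added resistance when closed
    s_o: float = 19.5  # 1/cmH2O, opening-transition steepness
    p_o: float = -0.46  # cmH2O, opening threshold (biased open)
    s_f: float = 2.0  # 1/cmH2O, failure-transition steepness
    p_f: float = -40.0  # cmH2O, failure threshold (outside operating range)

    def __post_init__(self) -> None:
        if not (self.rv_min > 0 and self.rv_max > 0):
            raise InvalidParameterError("rv_min and rv_max must be positive")
        if not (self.s_o > 0 and self.s_f > 0):
            raise InvalidParameterError("sigmoid slopes must be positive")
        if not self.p_f < self.p_o:
            raise InvalidParameterError("failure threshold p_f must be < p_o")


def valve_resistance(delta_p, params: ValveParams):
    """Valve resistance Rv (cmH2O s/cm^3) at pressure difference ``delta_p``.

    ``delta_p`` is upstream minus downstream pressure; positive values favor
    forward flow.  Returns a value in [~Rv_min, Rv_min + Rv_max].
    """
    dp = np.asarray(delta_p, dtype=float)
    gate = expit(params.s_o * (params.p_o - dp)) + expit(
        params.s_f * (dp - params.p_f)
    ) - 1.0
    rv = params.rv_min + params.rv_max * np.clip(gate, 0.0, 1.0)
    return rv if rv.ndim else float(rv)


def valve_flow_linearization(delta_p, params: ValveParams):
    """Tangent-line coefficients of the valve flow at ``delta_p``.

    Returns ``(a, b)`` with ``Q ~= a + b * dp`` near the expansion point:
    ``b = dQ/d(dp)`` clamped to a small positive floor so the linearized
    junction always behaves as a (possibly tiny) conductance, and
    ``a = Q(delta_p) - b * delta_p``.  Used by the implicit solver's Newton
    iteration on the valve states.
    """
    dp = np.asarray(delta_p, dtype=float)
    x_o = params.s_o * (params.p_o - dp)
    x_f = params.s_f * (dp - params.p_f)
    sig_o = expit(x_o)
    sig_f = expit(x_f)
    gate = np.clip(sig_o + sig_f - 1.0, 0.0, 1.0)
    rv = params.rv_min + params.rv_max * gate
    dgate = -params.s_o * sig_o * (1.0 - sig_o) + params.s_f * sig_f * (1.0 - sig_f)
    drv = params.rv_max * dgate
    b = (rv - dp * drv) / (rv * rv)
    b_floor = 1e-3 / (params.rv_min + params.rv_max)
    b = np.maximum(b, b_floor)
    a = dp / rv - b * dp
    return a, b


def valve_flow(P_upstream, P_downstream, params: ValveParams):
    """Flow (cm^3/s) through the valve for the given end pressures.

    Q = dp / Rv(dp) with dp = P_upstream - P_downstream; continuous in dp and
    strongly rectifying (forward conductance ~1/Rv_min, reverse conductance
    ~1/(Rv_min + Rv_max)).
    """
    dp = np.asarray(P_upstream, dtype=float) - np.asarray(P_downstream, dtype=float)
    q = dp / valve_resistance(dp, params)
    return q if q.ndim else float(q)
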