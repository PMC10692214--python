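"""Wall (solid) mechanics: constitutive pressure-diameter behaviour.

The vessel wall is described by two monotone pressure->diameter curves: the
*pre-twitch* curve (muscle fully relaxed, dilated configuration) and the
*peak-twitch* curve (maximal contractile state).  At any node the local
diameter is the activation-weighted average of the two curves evaluated at
the pressure of the previous time step,

    d = (d_peak - d_pre) * t_act + d_pre,

and the area compliance C = dA/dP follows from the chain rule for a circular
lumen, C = (pi/2) d (dd/dP), interpolated the same way between the
pre- and peak-twitch states.

The curve family is a saturating exponential d(P) = d_max - (d_max - d_min)
exp(-k P): concave, strain-stiffening (slope -> 0 at high pressure) and
monotone, matching the shape of rat mesenteric pressure-diameter data.  The
numeric coefficients shipped by :func:`calibrate_default_curves` are
calibrated stand-ins anchored to the resting diameter D0 at the mean
operating pressure and to a peak-twitch plateau giving a ~50-55% systolic
caliber reduction; every coefficient is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .units import CM_PER_UM, UM_PER_CM

__all__ = [
    "ConstitutiveCurve",
    "ConstitutiveCurveSet",
    "diameter_update",
    "compliance_update",
    "calibrate_default_curves",
]

#: pressure range (cmH2O) over which curve-set invariants are validated
OPERATING_RANGE = (0.0, 10.0)


class InvalidParameterError(ValueError):
    pass


@dataclass(frozen=True)
class ConstitutiveCurve:
    """Saturating-exponential pressure-diameter curve (internal units: cm).

    d(P) = d_max - (d_max - d_min) * exp(-k * P)
    """

    d_max: float  # cm, high-pressure plateau diameter
    d_min: float  # cm, zero-pressure diameter
    k: float  # 1/cmH2O, stiffening rate

    def __post_init__(self) -> None:
        if not (self.d_max > 0 and self.d_min > 0 and self.k > 0):
            raise InvalidParameterError("curve coefficients must be positive")
        if self.d_min > self.d_max:
            raise InvalidParameterError("d_min must not exceed d_max")

    def diameter_at(self, P):
        """Diameter (cm) at pressure P (cmH2O)."""
        P = np.asarray(P, dtype=float)
        d = self.d_max - (self.d_max - self.d_min) * np.exp(-self.k * P)
        return d if d.ndim else float(d)

    def slope_at(self, P):
        """dd/dP (cm per cmH2O) at pressure P."""
        P = np.asarray(P, dtype=float)
        s = self.k * (self.d_max - self.d_min) * np.exp(-self.k * P)
        return s if s.ndim else float(s)


@dataclass(frozen=True)
class ConstitutiveCurveSet:
    """Pre-twitch and peak-twitch curves; pre >= peak over the operating range."""

    pre: ConstitutiveCurve
    peak: ConstitutiveCurve

    def __post_init__(self) -> None:
        P = np.linspace(*OPERATING_RANGE, 101)
        if np.any(self.pre.diameter_at(P) < self.peak.diameter_at(P)):
            raise InvalidParameterError(
                "pre-twitch diameter must dominate peak-twitch diameter over "
                f"the operating range {OPERATING_RANGE} cmH2O"
            )


def _check_t_act(t_act) -> np.ndarray:
    t = np.asarray(t_act, dtype=float)
    if np.any(t < -1e-12) or np.any(t > 1.0 + 1e-12):
        raise InvalidParameterError("t_act must lie in [0, 1]")
    return np.clip(t, 0.0, 1.0)


def diameter_update(P_prev, t_act, curves: ConstitutiveCurveSet):
    """Diameter (cm) from previous-step pressure and current activation.

    Weighted average of the two constitutive states:
    ``d = (d_peak - d_pre) * t_act + d_pre`` with both curves evaluated at
    ``P_prev`` (the pressure lag makes the wall update explicit).
    """
    t = _check_t_act(t_act)
    d_pre = curves.pre.diameter_at(P_prev)
    d_peak = curves.peak.diameter_at(P_prev)
    return (d_peak - d_pre) * t + d_pre


def compliance_update(P_prev, t_act, curves: ConstitutiveCurveSet):
    """Area compliance C (cm^2/cmH2O) interpolated between twitch states.

    C_state = (pi/2) * d_state * (dd/dP)_state for a circular lumen, then
    ``C = (C_peak - C_pre) * t_act + C_pre``.
    """
    t = _check_t_act(t_act)
    c_pre = 0.5 * np.pi * curves.pre.diameter_at(P_prev) * curves.pre.slope_at(P_prev)
    c_peak = (
        0.5 * np.pi * curves.peak.diameter_at(P_prev) * curves.peak.slope_at(P_prev)
    )
    return (c_peak - c_pre) * t + c_pre


def curve_through_anchor(
    d_anchor_um: float,
    P_anchor: float,
    d_max_um: float,
    d_min_um: float,
) -> ConstitutiveCurve:
    """Curve with given plateau/intercept passing exactly through an anchor.

    Solves the stiffening rate k so that d(P_anchor) = d_anchor.
    """
    if not d_min_um < d_anchor_um < d_max_um:
        raise InvalidParameterError(
            "anchor diameter must lie strictly between d_min and d_max"
        )
    k = np.log((d_max_um - d_min_um) / (d_max_um - d_anchor_um)) / P_anchor
    return ConstitutiveCurve(
        d_max=d_max_um * CM_PER_UM, d_min=d_min_um * CM_PER_UM, k=float(k)
    )


def calibrate_default_curves(
    D0_um: float = 255.0,
    anchor_pressure: float = 3.75,
    pre_max_ratio: float = 1.03,
    pre_min_ratio: float = 0.55,
    peak_plateau_ratio: float = 0.39,
    peak_min_ratio: float = 0.27,
    peak_k: float = 1.0,
) -> ConstitutiveCurveSet:
    """Default curve set anchored at the resting diameter D0.

    The pre-twitch curve passes exactly through ``D0`` at the mean operating
    pressure (default 3.75 cmH2O, the average of the inlet and outlet
    boundary pressures); the peak-twitch curve plateaus near
    ``peak_plateau_ratio * D0`` so that a fully activated node constricts by
    roughly half its caliber, as observed during systole in healthy vessels.
    All ratios/rates are exposed for users with their own digitized
    pressure-diameter data.
    """
    if D0_um <= 0:
        raise InvalidParameterError("D0 must be positive")
    pre = curve_through_anchor(
        d_anchor_um=D0_um,
        P_anchor=anchor_pressure,
        d_max_um=pre_max_ratio * D0_um,
        d_min_um=pre_min_ratio * D0_um,
    )
    peak = ConstitutiveCurve(
        d_max=peak_plateau_ratio * D0_um * CM_PER_UM,
        d_min=peak_min_ratio * D0_um * CM_PER_UM,
        k=peak_k,
    )
    return ConstitutiveCurveSet(pre=pre, peak=peak)


def curveset_to_table(curves: ConstitutiveCurveSet, pressures=None):
    """Sample a curve set as (P, d_pre_um, d_peak_um) for CSV export."""
    import pandas as pd

    if pressures is None:
        pressures = np.linspace(*OPERATING_RANGE, 51)
    P = np.asarray(pressures, dtype=float)
    return pd.DataFrame(
        {
            "P_cmH2O": P,
            "d_pre_um": curves.pre.diameter_at(P) * UM_PER_CM,
            "d_peak_um": curves.peak.diameter_at(P) * UM_PER_CM,
        }
    )
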