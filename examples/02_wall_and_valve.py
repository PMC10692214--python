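"""Inspect the constitutive wall curves and the valve resistance sigmoid.

Shows the pressure-diameter states the activation interpolates between, the
resulting area compliances, and the valve's open/closed resistance levels
around its thresholds.
"""

import numpy as np

from lymphchain import (
    ValveParams,
    calibrate_default_curves,
    compliance_update,
    diameter_update,
    valve_resistance,
)

curves = calibrate_default_curves()  # anchored at D0 = 255 um @ 3.75 cmH2O

print("pressure  d_pre   d_peak  (um)   C_pre      C_peak  (cm^2/cmH2O)")
for P in (1.0, 2.5, 3.75, 5.0, 8.0):
    d0 = diameter_update(P, 0.0, curves) * 1e4
    d1 = diameter_update(P, 1.0, curves) * 1e4
    c0 = compliance_update(P, 0.0, curves)
    c1 = compliance_update(P, 1.0, curves)
    print(f"{P:7.2f}  {d0:6.1f}  {d1:6.1f}        {c0:.3e}  {c1:.3e}")

# full activation at the operating pressure halves the caliber (the
# measured systolic constriction) and stiffens the wall ~30-fold

vp = ValveParams()
print(f"\nvalve: open Rv = {vp.rv_min:.2e}, "
      f"closed Rv = {vp.rv_min + vp.rv_max:.2e} cmH2O s/cm^3")
print("dp (cmH2O)   Rv (cmH2O s/cm^3)")
for dp in (1.0, 0.0, vp.p_o, -0.6, -1.0):
    print(f"{dp:10.2f}   {valve_resistance(dp, vp):.3e}")

# the opening threshold sits slightly below zero: the valve stays open at a
# zero pressure gradient and only seals once the adverse load exceeds ~0.5
# cmH2O, which biases the chain toward forward hand-off of lymph
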