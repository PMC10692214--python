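"""Unit conventions and conversion factors.

The internal unit system is cm / s / cmH2O, matching the units in which the
lymph viscosity (cmH2O s) and density (cmH2O s^2/cm^2) are specified.
Micrometres are accepted at public interfaces and converted once on entry.
"""

UM_PER_CM = 1e4
CM_PER_UM = 1e-4

#: 1 cmH2O expressed in dyn/cm^2 (used for wall shear stress reporting).
CMH2O_TO_DYN_PER_CM2 = 980.665

#: 1 cm^3/s expressed in uL/h.
CM3_S_TO_UL_H = 3.6e6

#: 1 cm/s expressed in mm/s.
CM_S_TO_MM_S = 10.0

#: 1 cm/s expressed in um/s.
CM_S_TO_UM_S = 1e4
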