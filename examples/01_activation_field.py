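"""Build the wild-type and knock-out pacemaker activation fields.

Derives the Gaussian signal parameters from the measured contractility
metrics, places the pacemaker sites, sums and normalizes their signals, and
prints the quantities that characterize each field.  The conduction speed
enters twice: as the skew (correlation) of each site's space-time Gaussian
and as the firing delay between sites.
"""

import numpy as np

from lymphchain import (
    build_activation_field,
    derive_activation_params,
    place_pacemakers,
)

CHAIN_LENGTH = 0.3  # cm, three 1 mm lymphangions

for label, (speed, sites_per_cm, freq, period, pattern) in {
    "WT  (fast, coordinated)": (0.98, 10.0, 8.3, 7.23, "antegrade"),
    "KO3 (slow, retrograde) ": (0.063, 11.0, 15.8, 3.80, "retrograde"),
}.items():
    params = derive_activation_params(sites_per_cm, speed, freq, period)
    sites = place_pacemakers(CHAIN_LENGTH, sites_per_cm, pattern,
                             period_T=period, conduction_speed=speed)
    z = np.linspace(0.0, CHAIN_LENGTH, 61)
    t = np.arange(800) * (period / 800)
    field = build_activation_field(sites, params, z, t)

    spread = max(s.mu_t for s in sites) - min(s.mu_t for s in sites)
    print(f"{label}: sigma_z = {params.sigma_z * 1e4:.0f} um, "
          f"sigma_t = {params.sigma_t:.2f} s, rho = {params.rho:.4f}")
    print(f"    {len(sites)} sites at "
          f"{[round(s.position_z * 10, 2) for s in sites]} mm, "
          f"firing spread {spread:.2f} s of a {period:.2f} s period")
    print(f"    field max {field.values.max():.3f} (normalized), "
          f"mean occupancy {field.values.mean():.3f}")

# A small rho means the contraction wave is effectively synchronous within
# each site's footprint; the KO's rho ~ 0.19 visibly tilts the wave, and its
# firing delays (~1.4 s between sites) desynchronize the chain.
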