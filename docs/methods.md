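# Methods

`lymphchain` simulates lymph transport along a chain of collecting-lymphatic
pumping segments (lymphangions) whose contractions are prescribed by a
spatiotemporal pacemaker activation field. This note records the model, its
assumptions, the numerical scheme, the calibrated defaults and the known
limitations.

## Model overview

A chain of `N` lymphangions (default 3, each 1 mm long) is bounded by `N+1`
one-way secondary valves; the inlet and outlet connect to pressure
reservoirs `P_in = 3.5` and `P_out = 4` cmH2O, so the chain pumps against a
0.5 cmH2O adverse head. Lymph is incompressible and Newtonian (viscosity
`mu = 1e-5` cmH2O·s, density `rho = 1070e-6` cmH2O·s²/cm²). All internal
quantities use cm / s / cmH2O; micrometres are converted once at the
interfaces.

The model couples four components:

1. **Activation field** `t_act(z, t) in [0, 1]` — prescribed, not
   feedback-coupled (contractions are deliberately decoupled from pressure
   and shear).
2. **Wall mechanics** — the local diameter interpolates between a passive
   (pre-twitch) and a fully contracted (peak-twitch) pressure–diameter
   curve: `d = (d_peak - d_pre)·t_act + d_pre`, both curves evaluated at
   the *previous step's* pressure, which makes the wall update explicit.
   Area compliance uses the circular-lumen chain rule
   `C = (pi/2)·d·(dd/dP)` per state and the same linear blend in `t_act`
   (the blend of state compliances, not the derivative of the blended
   diameter — the two differ at partial activation and the blend is the
   model's closure).
3. **1D fluid mechanics** — cross-sectionally averaged mass and momentum
   balances with a power-law velocity profile of shape constant
   `zeta = 2` (parabolic): friction `tau = -2(zeta+2)·mu·pi·Q/A`, and
   momentum-flux correction `1 + delta_s` with `delta_s = 1/(zeta+1)`
   (i.e. 4/3 for the parabolic profile; `delta_s` is configurable).
4. **Valves** — lumped, zero-length resistive junctions with a sigmoidal
   resistance `Rv(dp)` between an open level `Rv_min` and a closed level
   `Rv_min + Rv_max`, plus a failure branch at large adverse loads
   (default far outside the operating range).

## Activation field

Each pacemaker site contributes a bivariate Gaussian in the (z, t) plane.
With pacemaking distance `L_pm = 1/sites_per_cm` and period `T`:

* `sigma_z = L_pm/8` — the wave decays (~4 standard deviations) over half
  the inter-site distance, so contraction vanishes between sites;
* `sigma_t = T/4` — one decay per period;
* correlation `rho = sigma_z/(c·sigma_t)`, from equating the Gaussian
  ridge slope `rho·sigma_t/sigma_z` to `1/c`; fast conduction gives
  `rho -> 0` (synchronous, unskewed), slow conduction a visibly tilted
  wave. Retrograde signals flip the sign of `rho`. `|rho|` is capped at
  0.99 (the covariance must stay positive definite; the wild-type and
  knock-out values, 0.007 and 0.19, are far below the cap).

Sites are evenly spaced at `L_pm`, centred on the chain. Each site fires
when a wave travelling at the conduction speed in the site's own direction
reaches it from the first site of that direction: antegrade
`delay = (z - z_first)/c`, retrograde `delay = (z_last - z)/c`, taken
modulo `T`. For the wild type the delays are ≤ 0.2 s of a 7.23 s period
(near-simultaneous); for the knock-out they are ~1.4 s apart, which
desynchronizes the chain. This delay rule is a modelling decision: with
strictly simultaneous firing the signal-direction scenarios are numerically
indistinguishable, because the per-site skew only acts over the ±2·sigma_z
(~0.02 cm) footprint — whereas with delays, direction reduces to a
near-negligible effect precisely when conduction is fast, which is the
stated reason direction is irrelevant for the wild type.

The raw field sums all sites and their periodic temporal images (±1
period; the `sigma_t` rule makes further images vanish at machine
precision) and is normalized by its global maximum, so `max(t_act) = 1`
exactly and the field is periodic by construction.

## Numerical scheme

Staggered grid per lymphangion: pressures at the `M` nodes (`dz = 50` um,
so `M = 21` per 1 mm segment), flows at the `M - 1` interior faces; the
two end faces are the valve junctions. Backward-Euler in time
(`dt = 5` ms), central differences in space.

**Mass balance with activation source.** Writing `A(P, t_act)` through the
constitutive interpolation and linearizing about the previous pressure,

    [C·(P^{n+1} - P^n) + (A_w - A^n)]·w/dt + (Q_out - Q_in) = 0,

with `A_w = A(P^n, t_act^{n+1})` and `C = C(P^n, t_act^{n+1})`; `w` is the
control-volume width (half cells at segment ends). The stored area is
`A^{n+1} = A_w + C·(P^{n+1} - P^n)`, so discrete lymph volume is conserved
exactly: trapped fluid cannot be squeezed — pressure rises instead. This
is what couples contraction *timing* to pumping efficacy. The
`C·dP/dt` part stabilizes the stiff wall/valve coupling implicitly; the
activation-driven wall motion enters as a source.

**Momentum.** Friction is implicit (linear in `Q^{n+1}`); the convective
flux `d(Q²/A)/dz` is lagged and iterated; fluid inertia uses the known
face area.

**Valve junctions.** `Q_v = dp/Rv(dp)` with `dp` the trans-valvular
pressure difference; the inlet/outlet valves see the reservoirs. Each
nonlinear step replaces the valve relation by its tangent line
`Q ≈ a + b·dp` (slope clamped positive) and solves the resulting
tridiagonal system — with pressures and flows interleaved along the chain
the Jacobian has bandwidth 1, so every iteration is one banded solve. The
expansion points are iterated (damped fixed point, tolerance 1e-8 relative
on P and Q); because a partially open valve under an adverse head has a
negative-differential-conductance branch on which fixed-point iteration
crawls, slow steps fall back to a root finder on the `N+1` valve pressure
differences (each function evaluation one banded solve). The valve fluxes
stored are those implied by the linearization that produced the final
solution, which keeps the discrete mass residual at machine precision
(~1e-14 relative over a cycle).

**Cycle driver.** Simulation starts from `P = P_in`, `Q = 0` and runs
whole contraction cycles until the cycle-averaged outflow changes by less
than 1% between consecutive cycles (minimum 5 cycles, cap 15). All four
shipped scenarios converge in 5 cycles; a full-resolution scenario takes a
few seconds on one core. The lumen diameter is floored at 5% of `D0` to
keep the friction term regular; the floor never engages in the shipped
scenarios.

**Verification.** A rigid tube with transparent valves reproduces the
series-resistance Hagen–Poiseuille closed form to <0.1%; the
cross-sectional mean of the velocity profile equals `Q/A` by quadrature;
halving `dz` and `dt` changes the cycle-averaged outflow of a pulsating
single-lymphangion pump by <2%; cycle-averaged flow is equal across all
valve planes to ~1e-14 at steady state; reruns are bit-identical (no
randomness anywhere in the pipeline).

## Calibrated defaults

Two inputs are only known graphically in the source literature, so their
numeric coefficients are calibrated stand-ins, every one overridable
through the configuration.

**Constitutive curves** (saturating exponentials
`d(P) = d_max - (d_max - d_min)·e^{-kP}`): the pre-twitch curve passes
exactly through `D0 = 255` um at the mean operating pressure 3.75 cmH2O
(plateau 1.03·D0, intercept 0.55·D0); the peak-twitch curve plateaus at
0.39·D0 (intercept 0.27·D0, k = 1/cmH2O), so a fully activated node
constricts to ~52% caliber — the observed systolic constriction — and the
monitored ejection fraction lands at the measured 0.78.

**Valve sigmoid**: `Rv_min = 6.6e3`, `Rv_max = 1e7` cmH2O·s/cm³,
opening threshold `p_o = -0.46` cmH2O with steepness `s_o = 19.5`/cmH2O,
failure at `p_f = -40` cmH2O (`s_f = 2`/cmH2O). The clearly negative
opening threshold means a valve stays open at zero pressure gradient and
only seals once the adverse load approaches the 0.5 cmH2O head. This is
the regime in which the model reproduces the knock-out signatures: the
first two lymphangions' mean pressures pin at the inlet head (their
strokes leak backward through still-open upstream valves), most pumping is
done by a single lymphangion, and the cross-case mean energy loss at
valve 3 is ~0.2 cmH2O (~40% of the head). It also reproduces the
wild-type signature of all three mean pressures at the reservoir average.

**WSS signal-to-noise window**: the SNR of the wall-shear series is
`ln((MSE0/MSE)²)` with the denoised series a trailing moving average
(truncated at the start). The window length is not fixed by the source;
shipped default 100 samples (0.5 s at the 5 ms step), which puts the
wild-type SNR at 1.38 and the knock-outs at 0.47–0.79 — the measured scale
and ordering. A 5-sample window would leave the residual at discretization
scale and inflate every SNR to 6–9.

**Activation integration (AI)** is reported as 1000× the mean of `t_act`
over the space–time grid (per-mille occupancy of the domain); the
convention is stored with the metric.

## Metric conventions

* **EF / area reduction** are computed on the mean area of the three
  lymphangion *mid-nodes* — the monitored locations, which for the
  wild-type spacing coincide with the pacemaker sites. A chain-wide
  all-node average is reported alongside (`ef_chain_all_nodes`); under the
  `sigma_z = L_pm/8` decay rule the all-node average is bounded near 0.40
  for any stroke, so only the monitored convention can reach the measured
  0.78.
* **FPF** = contraction frequency × EF, exactly.
* **WSS** = `-2(zeta+2)·mu·Q/(A·d)` converted to dyn/cm² (negative during
  forward flow); for `zeta = 2` this is the Hagen–Poiseuille wall shear
  `32·mu·Q/(pi·d³)`.
* **Valvular energy loss** = cycle mean of `|ΔΦ|` with
  `Φ = P + rho·u²/2` taken immediately up/downstream of the valve.
* **Bottleneck** = per lymphangion, the node of maximal `|Q|` at each
  step; the stationarity score is the fraction of steps at the modal node
  (ties break toward the upstream node).

## Known limitations

* The activation geometry follows the stated decay rules, which make the
  field spatially spiky (inter-site tissue never contracts). Consequently
  the chain-mean stroke, and with it the absolute flow scale, sits above
  the measured regime (~10.7 vs 5.44 uL/h wild type), peak lymph velocity
  below it (0.66 vs 2.4 mm/s), and the cycle-mean WSS magnitude below its
  measured 0.08 dyn/cm². The knock-out flow scale, EF bands, pressure
  signatures, SNR scale/ordering and valve-3 energy loss are reproduced.
* Signal directionality acts only through the per-site skew and the firing
  delays; its net effect on knock-out flow is a few percent (Case 3 lowest,
  Cases 1/2 equal within solver precision), much weaker than the measured
  spread between the antegrade and retrograde cases.
* No pressure/WSS-to-contraction feedback, no wall viscoelasticity or
  inertia, no valve leaflet dynamics, zero taper by default (a linear
  taper is configurable), and pacemaker firing is strictly periodic —
  stochastic pacemaker dominance is out of scope.
* Pressure-wave propagation at the elastic-tube wave speed (~1.4 m/s) is
  unresolved at the 5 ms step and damped by the backward-Euler scheme; the
  model targets cycle-scale transport, not wave-resolved hemodynamics.
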