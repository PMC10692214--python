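"""Implicit 1D finite-difference solver for the lymphangion chain.

Model
-----
Each lymphangion is an elastic tube carrying incompressible lymph.  On each
tube the cross-sectionally averaged balance laws are

    dA/dt + dQ/dz = 0                                   (mass)
    (rho/A) dQ/dt + dP/dz = tau/A
        - (1 + delta_s) (rho/A) d/dz (Q^2/A)            (momentum)

with ``tau = -2 (zeta+2) mu pi Q / A`` the viscous friction of a power-law
velocity profile with shape constant ``zeta`` (zeta = 2: Poiseuille) and
``delta_s = 1/(zeta+1)`` so that ``1 + delta_s`` is the momentum-flux
correction factor of that profile.

The wall supplies ``A(P, t_act)`` through the constitutive interpolation
(see :mod:`lymphchain.wall`).  Both curves are evaluated at the pressure of
the *previous* time step, which makes the wall update explicit; the residual
pressure dependence of the area within the step is kept to first order,

    A^{n+1} ~= A_w + C (P^{n+1} - P^n),
    A_w = A(P^n, t_act^{n+1}),  C = C(P^n, t_act^{n+1}),

so the discrete mass balance per node reads

    [C (P^{n+1} - P^n) + (A_w - A^n)] w/dt + (Q_out - Q_in) = 0.

This keeps the compliance term ``C dP/dt`` implicit (stabilizing the stiff
valve/wall coupling), injects the activation-driven wall motion as a source,
and conserves the discrete lymph volume exactly: trapped fluid cannot be
squeezed -- pressure rises instead, which is what couples contraction timing
to pumping efficacy.

Discretization
--------------
Staggered grid per lymphangion: pressures at the ``M`` nodes, flows at the
``M - 1`` interior faces between them; the two end faces of every lymphangion
are valve junctions whose flow is the lumped relation ``Q = dp/Rv(dp)`` (the
inlet valve sees the reservoir ``P_in``, the outlet valve ``P_out``).
Backward-Euler in time, central differences in space; the friction term is
implicit, the convective term and the valve resistances are lagged and
Picard-iterated.  With pressures and flows interleaved along the chain the
Jacobian is tridiagonal and each iteration is a banded solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

from .activation import ActivationField
from .valve import ValveParams, valve_resistance
from .wall import ConstitutiveCurveSet, compliance_update, diameter_update

__all__ = [
    "ChainGeometry",
    "FluidParams",
    "SimulationResult",
    "ChainSolver",
    "friction_term",
    "velocity_profile",
    "check_mass_conservation",
]


class SolverError(RuntimeError):
    pass


class DegenerateLumenError(ValueError):
    pass


@dataclass(frozen=True)
class ChainGeometry:
    """Discretized chain of lymphangions separated by valves."""

    n_lymphangions: int = 3
    lymphangion_length: float = 0.1  # cm
    dz: float = 0.005  # cm
    taper: float = 0.0  # fractional linear taper of D0 along the chain

    def __post_init__(self) -> None:
        n_int = self.lymphangion_length / self.dz
        if abs(n_int - round(n_int)) > 1e-9:
            raise ValueError("lymphangion_length must be a multiple of dz")
        if self.n_lymphangions < 1:
            raise ValueError("need at least one lymphangion")

    @property
    def nodes_per_lymphangion(self) -> int:
        return int(round(self.lymphangion_length / self.dz)) + 1

    @property
    def n_nodes(self) -> int:
        return self.n_lymphangions * self.nodes_per_lymphangion

    @property
    def n_valves(self) -> int:
        return self.n_lymphangions + 1

    @property
    def chain_length(self) -> float:
        return self.n_lymphangions * self.lymphangion_length

    @property
    def node_z(self) -> np.ndarray:
        """Axial coordinate of every pressure node (valve junctions have
        coincident nodes on either side)."""
        M = self.nodes_per_lymphangion
        z = np.empty(self.n_nodes)
        for ell in range(self.n_lymphangions):
            z[ell * M : (ell + 1) * M] = (
                ell * self.lymphangion_length + np.arange(M) * self.dz
            )
        return z

    def mid_node_indices(self) -> np.ndarray:
        """Index of the middle node of each lymphangion."""
        M = self.nodes_per_lymphangion
        return np.array([ell * M + M // 2 for ell in range(self.n_lymphangions)])

    def taper_factor(self) -> np.ndarray:
        """Per-node diameter scaling for a linear taper (1 at mid-chain)."""
        z = self.node_z
        zc = self.chain_length / 2.0
        return 1.0 + self.taper * (z - zc) / self.chain_length


@dataclass(frozen=True)
class FluidParams:
    """Lymph properties and 1D profile closure constants."""

    mu: float = 1e-5  # cmH2O s, lymph viscosity
    rho_f: float = 1070e-6  # cmH2O s^2/cm^2, lymph density
    zeta: float = 2.0  # velocity-profile shape constant
    delta_s: float | None = None  # convective correction; default 1/(zeta+1)

    def __post_init__(self) -> None:
        if not (self.mu > 0 and self.rho_f > 0):
            raise ValueError("mu and rho_f must be positive")
        if self.zeta < 2.0:
            raise ValueError("zeta must be >= 2")
        if self.delta_s is None:
            object.__setattr__(self, "delta_s", 1.0 / (self.zeta + 1.0))


def friction_term(Q, A, params: FluidParams):
    """Viscous force per unit length, tau = -2 (zeta+2) mu pi Q / A."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DegenerateLumenError("cross-sectional area must be positive")
    tau = -2.0 * (params.zeta + 2.0) * params.mu * np.pi * np.asarray(Q) / A
    return tau if tau.ndim else float(tau)


def velocity_profile(d_radial, Q, A, zeta: float = 2.0):
    """Axial velocity at radial coordinate ``d_radial`` (cm from the axis).

    u(r) = (Q/A) (zeta+2)/zeta [1 - (r/r_i)^zeta]; the cross-sectional
    average recovers Q/A and u = 0 at the wall (no slip).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise DegenerateLumenError("cross-sectional area must be positive")
    r_i = np.sqrt(A / np.pi)
    r = np.asarray(d_radial, dtype=float)
    if np.any(r < 0) or np.any(r > r_i * (1 + 1e-12)):
        raise ValueError("radial coordinate must lie within the lumen")
    u = (np.asarray(Q) / A) * (zeta + 2.0) / zeta * (1.0 - (r / r_i) ** zeta)
    return u if u.ndim else float(u)


@dataclass
class SimulationResult:
    """Full time history of the chain state plus convergence metadata.

    Arrays are indexed ``[node_or_face, step]`` with step 0 the initial
    condition.  Faces are numbered so that face ``ell*M`` is valve ``ell``
    (``M`` = nodes per lymphangion) and face ``n_lymphangions*M`` is the
    outlet valve.
    """

    geometry: ChainGeometry
    fluid: FluidParams
    t: np.ndarray  # (n_steps+1,)
    P: np.ndarray  # (n_nodes, n_steps+1) cmH2O
    Q: np.ndarray  # (n_faces, n_steps+1) cm^3/s, valve faces included
    A: np.ndarray  # (n_nodes, n_steps+1) cm^2
    d: np.ndarray  # (n_nodes, n_steps+1) cm
    C: np.ndarray  # (n_nodes, n_steps+1) cm^2/cmH2O
    Rv: np.ndarray  # (n_valves, n_steps+1) cmH2O s/cm^3
    t_act: np.ndarray  # (n_nodes, n_steps+1)
    steps_per_cycle: int
    cycle_outflows: list[float] = field(default_factory=list)
    converged: bool = False
    p_in: float = 3.5
    p_out: float = 4.0
    clamp_events: int = 0

    @property
    def n_steps(self) -> int:
        return self.t.size - 1

    @property
    def valve_faces(self) -> np.ndarray:
        M = self.geometry.nodes_per_lymphangion
        return np.arange(self.geometry.n_valves) * M

    def last_cycle(self) -> np.ndarray:
        """Step indices of the final complete contraction cycle."""
        spc = self.steps_per_cycle
        if self.n_steps < spc:
            raise ValueError("result does not contain a complete cycle")
        return np.arange(self.n_steps - spc + 1, self.n_steps + 1)

    def cycle_mean_outflow(self) -> float:
        """Cycle-averaged flow (cm^3/s) through the outlet valve."""
        idx = self.last_cycle()
        return float(self.Q[self.valve_faces[-1], idx].mean())

    def to_tidy_frame(self, steps=None):
        """Nodewise state as a tidy DataFrame (time, node, z, P, Q, A, d, C)."""
        import pandas as pd

        if steps is None:
            steps = self.last_cycle()
        steps = np.asarray(steps)
        M = self.geometry.nodes_per_lymphangion
        node = np.arange(self.geometry.n_nodes)
        q_node = self.node_flow()
        rows = {
            "time_s": np.repeat(self.t[steps], node.size),
            "node": np.tile(node, steps.size),
            "z_cm": np.tile(self.geometry.node_z, steps.size),
            "lymphangion": np.tile(node // M, steps.size),
            "P_cmH2O": self.P[:, steps].T.ravel(),
            "Q_cm3_s": q_node[:, steps].T.ravel(),
            "A_cm2": self.A[:, steps].T.ravel(),
            "d_cm": self.d[:, steps].T.ravel(),
            "C_cm2_cmH2O": self.C[:, steps].T.ravel(),
            "t_act": self.t_act[:, steps].T.ravel(),
        }
        return pd.DataFrame(rows)

    def valve_frame(self, steps=None):
        """Per-valve history (time, valve, Rv, Q, dp) as a DataFrame."""
        import pandas as pd

        if steps is None:
            steps = self.last_cycle()
        steps = np.asarray(steps)
        nv = self.geometry.n_valves
        up, down = self.valve_end_pressures()
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.t[steps], nv),
                "valve": np.tile(np.arange(nv), steps.size),
                "Rv_cmH2O_s_cm3": self.Rv[:, steps].T.ravel(),
                "Q_cm3_s": self.Q[self.valve_faces][:, steps].T.ravel(),
                "dp_cmH2O": (up - down)[:, steps].T.ravel(),
            }
        )

    def node_flow(self) -> np.ndarray:
        """Flow interpolated to pressure nodes (average of adjacent faces)."""
        M = self.geometry.nodes_per_lymphangion
        q = np.empty_like(self.P)
        for ell in range(self.geometry.n_lymphangions):
            faces = slice(ell * M, (ell + 1) * M + 1)
            qf = self.Q[faces]
            q[ell * M : (ell + 1) * M] = 0.5 * (qf[:-1] + qf[1:])
        return q

    def valve_end_pressures(self) -> tuple[np.ndarray, np.ndarray]:
        """(upstream, downstream) pressures at every valve and step."""
        M = self.geometry.nodes_per_lymphangion
        nv = self.geometry.n_valves
        up = np.empty((nv, self.t.size))
        down = np.empty((nv, self.t.size))
        for v in range(nv):
            up[v] = self.p_in if v == 0 else self.P[v * M - 1]
            down[v] = self.p_out if v == nv - 1 else self.P[v * M]
        return up, down


class ChainSolver:
    """Implicit solver for one lymphangion chain configuration."""

    def __init__(
        self,
        geometry: ChainGeometry,
        fluid: FluidParams,
        curves: ConstitutiveCurveSet,
        valve_params: ValveParams,
        activation: ActivationField,
        p_in: float = 3.5,
        p_out: float = 4.0,
        dt: float = 0.005,
        picard_tol: float = 1e-8,
        picard_max_iter: int = 80,
        rv_relax: float = 0.5,
        lumen_floor_ratio: float = 0.05,
        d0_um: float = 255.0,
    ) -> None:
        self.geometry = geometry
        self.fluid = fluid
        self.curves = curves
        self.valve_params = valve_params
        self.activation = activation
        self.p_in = p_in
        self.p_out = p_out
        self.dt = dt
        self.picard_tol = picard_tol
        self.picard_max_iter = picard_max_iter
        self.rv_relax = rv_relax
        self.d_floor = lumen_floor_ratio * d0_um * 1e-4  # cm
        self._setup_indexing()
        self._setup_activation_table()
        self.clamp_events = 0

    # -- static index bookkeeping -------------------------------------------------
    def _setup_indexing(self) -> None:
        g = self.geometry
        M = g.nodes_per_lymphangion
        nL = g.n_lymphangions
        self.M = M
        self.n_nodes = g.n_nodes
        self.n_faces = nL * M + 1  # valve faces included
        self.n_unknowns = self.n_nodes + nL * (M - 1)

        # position of each P node / interior Q face in the interleaved vector
        self.pos_P = np.empty(self.n_nodes, dtype=int)
        int_faces = []
        pos_Q = {}
        pos = 0
        for ell in range(nL):
            for j in range(M):
                self.pos_P[ell * M + j] = pos
                pos += 1
                if j < M - 1:
                    f = ell * M + j + 1
                    pos_Q[f] = pos
                    int_faces.append(f)
                    pos += 1
        assert pos == self.n_unknowns
        self.interior_faces = np.array(int_faces, dtype=int)
        self.pos_Q = np.array([pos_Q[f] for f in int_faces], dtype=int)
        # face f = ell*M + j (1<=j<=M-1) sits between nodes (ell,j-1),(ell,j)
        ell_of_face = (self.interior_faces - 1) // M
        j_of_face = self.interior_faces - ell_of_face * M
        self.face_left = ell_of_face * M + j_of_face - 1
        self.face_right = self.face_left + 1

        # valve bookkeeping: valve v is face v*M
        self.valve_faces = np.arange(nL + 1) * M
        self.valve_up_node = np.array(
            [-1] + [v * M - 1 for v in range(1, nL + 1)]
        )  # -1 => inlet reservoir
        self.valve_down_node = np.array(
            [v * M for v in range(nL)] + [-1]
        )  # -1 => outlet reservoir

        # control-volume widths (half cells at lymphangion ends)
        w = np.full(self.n_nodes, g.dz)
        for ell in range(nL):
            w[ell * M] = g.dz / 2.0
            w[(ell + 1) * M - 1] = g.dz / 2.0
        self.node_w = w

        self.is_first_node = np.zeros(self.n_nodes, dtype=bool)
        self.is_last_node = np.zeros(self.n_nodes, dtype=bool)
        self.is_first_node[[ell * M for ell in range(nL)]] = True
        self.is_last_node[[(ell + 1) * M - 1 for ell in range(nL)]] = True
        self.taper = g.taper_factor()

    def _setup_activation_table(self) -> None:
        """Pre-evaluate the activation field on the solver grid for one cycle."""
        act = self.activation
        spc = int(round(act.period_T / self.dt))
        if abs(spc * self.dt - act.period_T) > 1e-9:
            raise ValueError("contraction period must be a multiple of dt")
        self.steps_per_cycle = spc
        if (
            act.values.shape[0] == self.n_nodes
            and act.values.shape[1] == spc
            and np.allclose(act.z_grid, self.geometry.node_z)
        ):
            self.act_table = act.values
        else:
            # resample by periodic nearest-step lookup / linear z interpolation
            cols = []
            for i in range(spc):
                col = np.interp(
                    self.geometry.node_z,
                    act.z_grid,
                    act.values[:, act.step_index(i * self.dt)],
                )
                cols.append(col)
            self.act_table = np.column_stack(cols)

    # -- physics helpers ----------------------------------------------------------
    def _wall_state(self, P_prev: np.ndarray, step: int):
        """Explicit wall update: target diameter/area/compliance at ``step``."""
        t_act = self.act_table[:, step % self.steps_per_cycle]
        d_w = diameter_update(P_prev, t_act, self.curves) * self.taper
        low = d_w < self.d_floor
        if np.any(low):
            self.clamp_events += int(low.sum())
            d_w = np.where(low, self.d_floor, d_w)
        C = compliance_update(P_prev, t_act, self.curves) * self.taper**2
        A_w = 0.25 * np.pi * d_w * d_w
        return t_act, d_w, A_w, C

    def _valve_dp(self, P: np.ndarray) -> np.ndarray:
        up = np.where(self.valve_up_node >= 0, P[self.valve_up_node], self.p_in)
        down = np.where(
            self.valve_down_node >= 0, P[self.valve_down_node], self.p_out
        )
        return up - down

    # -- single implicit step -----------------------------------------------------
    def step(self, P_n, Q_n, A_n, step_index):
        """Advance one time step; returns (P, Q_faces, A, d, C, Rv, t_act).

        The valve relations are Newton-linearized about the current
        trans-valvular pressure difference and iterated together with the
        lagged convective term; on slow convergence the step is retried
        with progressively damped valve updates before giving up.
        """
        t_act, d_w, A_w, C = self._wall_state(P_n, step_index + 1)
        last = None
        for relax, iters in ((1.0, self.picard_max_iter),
                             (0.5, 2 * self.picard_max_iter)):
            out = self._attempt_step(P_n, Q_n, A_n, A_w, C, relax, iters)
            P, Qi, q_valves, dp_lin, ok, dP, dQ, ddp = out
            if ok:
                break
            last = (dP, dQ, ddp)
        else:
            # the flux-vs-dp relation of a partially open valve under an
            # adverse head has a negative-slope branch on which the damped
            # fixed point crawls; hand the 4 valve pressure differences to a
            # proper root finder (each evaluation is one banded solve)
            out = self._solve_by_root(P_n, Q_n, A_n, A_w, C, dp_lin)
            P, Qi, q_valves, dp_lin, ok, resid = out
            if not ok:
                dP, dQ, ddp = last
                if resid > 1e-7:
                    raise SolverError(
                        f"valve iteration failed at step {step_index}: "
                        f"dP={dP:.2e}, dQ={dQ:.2e}, d(dp)={ddp:.2e}, "
                        f"root residual {resid:.2e}"
                    )
                warnings.warn(
                    f"valve iteration truncated at step {step_index} "
                    f"(root residual {resid:.2e})",
                    stacklevel=2,
                )

        Rv = valve_resistance(self._valve_dp(P), self.valve_params)
        q_faces = np.zeros(self.n_faces)
        q_faces[self.interior_faces] = Qi
        q_faces[self.valve_faces] = q_valves
        A_new = A_w + C * (P - P_n)
        A_new = np.maximum(A_new, 0.25 * np.pi * self.d_floor**2)
        d_new = np.sqrt(4.0 * A_new / np.pi)
        return P, q_faces, A_new, d_new, C, Rv, t_act

    def _linearized_solve(self, P_n, Q_n, A_n, A_w, C, A_face, dp_lin, P, Qi):
        """Assemble and solve one tridiagonal system with the valve flows
        replaced by their tangent lines Q ~= a + b dp at ``dp_lin`` and the
        convective flux lagged from (P, Qi).

        Returns ``(P_new, Q_new, q_valves, dp_new)`` where ``q_valves`` is
        evaluated from the same linearization that produced the solution,
        keeping the discrete mass balance exact.
        """
        from .valve import valve_flow_linearization

        dt = self.dt
        fl = self.fluid
        fric = 2.0 * (fl.zeta + 2.0) * fl.mu * np.pi
        n = self.n_unknowns
        ab = np.zeros((3, n))
        rhs = np.zeros(n)
        nL = self.geometry.n_lymphangions
        M = self.M

        a_v, b_v = valve_flow_linearization(dp_lin, self.valve_params)
        q_valves_lag = a_v + b_v * self._valve_dp(P)

        # node flows for the lagged convective flux
        q_node = np.empty(self.n_nodes)
        q_faces_full = np.zeros(self.n_faces)
        q_faces_full[self.interior_faces] = Qi
        q_faces_full[self.valve_faces] = q_valves_lag
        for ell in range(nL):
            qf = q_faces_full[ell * M : (ell + 1) * M + 1]
            q_node[ell * M : (ell + 1) * M] = 0.5 * (qf[:-1] + qf[1:])
        phi = q_node * q_node / A_w  # momentum flux Q^2/A at nodes
        conv = (phi[self.face_right] - phi[self.face_left]) / self.geometry.dz

        # Banded layout: ab[0, j] holds element (j-1, j) [superdiag],
        # ab[1, j] holds (j, j), ab[2, j] holds (j+1, j) [subdiag].

        # mass balance rows (one per node)
        p_pos = self.pos_P
        cw = C * self.node_w / dt
        ab[1, p_pos] += cw
        rhs[p_pos] += cw * P_n - (A_w - A_n) * self.node_w / dt
        # interior face couplings: node left of face at pos q is row q-1,
        # coefficient +Q -> ab[0, q]; node right of it is row q+1,
        # coefficient -Q -> ab[2, q]
        np.add.at(ab[0], self.pos_Q, 1.0)
        np.add.at(ab[2], self.pos_Q, -1.0)

        # valve couplings: Q_v = a + b (P_up - P_down)
        for v in range(self.geometry.n_valves):
            a, b = a_v[v], b_v[v]
            un, dn = self.valve_up_node[v], self.valve_down_node[v]
            if un >= 0:
                pu = self.pos_P[un]
                # outflow from upstream node: +Q_v on the LHS
                ab[1, pu] += b
                rhs[pu] -= a
                if dn >= 0:
                    ab[0, self.pos_P[dn]] += -b  # (pu, pd), pd = pu + 1
                else:
                    rhs[pu] += b * self.p_out
            if dn >= 0:
                pd = self.pos_P[dn]
                # inflow to downstream node: -Q_v on the LHS
                ab[1, pd] += b
                rhs[pd] += a
                if un >= 0:
                    ab[2, self.pos_P[un]] += -b  # (pd, pu), pu = pd - 1
                else:
                    rhs[pd] += b * self.p_in

        # momentum rows (one per interior face)
        q_pos = self.pos_Q
        inert = fl.rho_f / (A_face * dt)
        ab[1, q_pos] = inert + fric / (A_face * A_face)
        # dP/dz coupling: (P_right - P_left)/dz
        np.add.at(ab[0], self.pos_P[self.face_right], 1.0 / self.geometry.dz)
        np.add.at(ab[2], self.pos_P[self.face_left], -1.0 / self.geometry.dz)
        rhs[q_pos] = inert * Q_n[self.interior_faces] - (
            (1.0 + fl.delta_s) * fl.rho_f / A_face
        ) * conv

        x = solve_banded((1, 1), ab, rhs)
        P_new = x[self.pos_P]
        Q_new = x[self.pos_Q]
        dp_new = self._valve_dp(P_new)
        q_valves = a_v + b_v * dp_new
        return P_new, Q_new, q_valves, dp_new

    def _attempt_step(self, P_n, Q_n, A_n, A_w, C, relax, max_iter):
        """Damped fixed-point iteration on the valve expansion points."""
        P = P_n.copy()
        Qi = Q_n[self.interior_faces].copy()
        dp_lin = self._valve_dp(P)
        A_face = 0.5 * (A_w[self.face_left] + A_w[self.face_right])
        converged = False
        dP = dQ = ddp = np.inf

        for _ in range(max_iter):
            P_new, Q_new, q_valves, dp_now = self._linearized_solve(
                P_n, Q_n, A_n, A_w, C, A_face, dp_lin, P, Qi
            )
            dP = np.max(np.abs(P_new - P)) / max(np.max(np.abs(P_new)), 1e-12)
            qscale = max(np.max(np.abs(Q_new)), 1e-12)
            dQ = np.max(np.abs(Q_new - Qi)) / qscale
            P, Qi = P_new, Q_new
            ddp = np.max(np.abs(dp_now - dp_lin))
            dp_lin = relax * dp_now + (1.0 - relax) * dp_lin
            if dP < self.picard_tol and dQ < self.picard_tol and ddp < 1e-9:
                converged = True
                break

        return P, Qi, q_valves, dp_lin, converged, dP, dQ, ddp

    def _solve_by_root(self, P_n, Q_n, A_n, A_w, C, dp_init):
        """Solve the valve fixed point with a Newton-Krylov style root
        finder on the 4 trans-valvular pressure differences."""
        from scipy.optimize import root

        A_face = 0.5 * (A_w[self.face_left] + A_w[self.face_right])
        state = {
            "P": P_n.copy(),
            "Qi": Q_n[self.interior_faces].copy(),
            "q_valves": None,
        }

        def residual(dp_lin):
            # settle the (fast-converging) convective lag at fixed dp_lin
            for _ in range(3):
                P_new, Q_new, q_valves, dp_now = self._linearized_solve(
                    P_n, Q_n, A_n, A_w, C, A_face, dp_lin,
                    state["P"], state["Qi"],
                )
                state["P"], state["Qi"] = P_new, Q_new
                state["q_valves"] = q_valves
            return dp_now - dp_lin

        sol = root(residual, dp_init, method="hybr", tol=1e-12)
        resid = float(np.max(np.abs(residual(sol.x))))
        ok = resid < 1e-10
        return state["P"], state["Qi"], state["q_valves"], sol.x, ok, resid

    # -- cycle driver -------------------------------------------------------------
    def run(
        self,
        n_cycles_max: int = 15,
        min_cycles: int = 5,
        steady_tol: float = 0.01,
    ) -> SimulationResult:
        """Run to periodic steady state (cycle-to-cycle outflow change below
        ``steady_tol``) or to ``n_cycles_max`` cycles."""
        spc = self.steps_per_cycle
        n_max = n_cycles_max * spc
        nn, nf, nv = self.n_nodes, self.n_faces, self.geometry.n_valves

        P = np.empty((nn, n_max + 1))
        Q = np.zeros((nf, n_max + 1))
        A = np.empty((nn, n_max + 1))
        d = np.empty((nn, n_max + 1))
        C = np.empty((nn, n_max + 1))
        Rv = np.empty((nv, n_max + 1))
        TA = np.empty((nn, n_max + 1))

        P[:, 0] = self.p_in
        t_act0, d_w0, A_w0, C0 = self._wall_state(P[:, 0], 0)
        A[:, 0], d[:, 0], C[:, 0], TA[:, 0] = A_w0, d_w0, C0, t_act0
        Rv[:, 0] = valve_resistance(self._valve_dp(P[:, 0]), self.valve_params)

        cycle_outflows: list[float] = []
        converged = False
        step = 0
        for cycle in range(n_cycles_max):
            for _ in range(spc):
                out = self.step(P[:, step], Q[:, step], A[:, step], step)
                step += 1
                (P[:, step], Q[:, step], A[:, step], d[:, step], C[:, step],
                 Rv[:, step], TA[:, step]) = out
            idx = np.arange(step - spc + 1, step + 1)
            outflow = float(Q[-1, idx].mean())
            cycle_outflows.append(outflow)
            if cycle + 1 >= min_cycles and len(cycle_outflows) >= 2:
                prev = cycle_outflows[-2]
                denom = max(abs(outflow), abs(prev), 1e-15)
                if abs(outflow - prev) / denom < steady_tol:
                    converged = True
                    break
        n_run = step

        result = SimulationResult(
            geometry=self.geometry,
            fluid=self.fluid,
            t=np.arange(n_run + 1) * self.dt,
            P=P[:, : n_run + 1],
            Q=Q[:, : n_run + 1],
            A=A[:, : n_run + 1],
            d=d[:, : n_run + 1],
            C=C[:, : n_run + 1],
            Rv=Rv[:, : n_run + 1],
            t_act=TA[:, : n_run + 1],
            steps_per_cycle=spc,
            cycle_outflows=cycle_outflows,
            converged=converged,
            p_in=self.p_in,
            p_out=self.p_out,
            clamp_events=self.clamp_events,
        )
        if not converged:
            warnings.warn(
                "simulation reached the cycle cap without meeting the "
                "periodic steady-state criterion; returning partial result",
                stacklevel=2,
            )
        return result


def check_mass_conservation(result: SimulationResult) -> float:
    """Maximum relative deviation of cycle-averaged flow across valve planes.

    At periodic steady state the cycle-averaged flow entering the first
    lymphangion must be constant along the chain; returns
    ``max_v |<Q>_v - <Q>_inlet| / |<Q>_inlet|`` over the final cycle.
    """
    idx = result.last_cycle()
    means = result.Q[result.valve_faces][:, idx].mean(axis=1)
    ref = means[0]
    if abs(ref) < 1e-18:
        warnings.warn(
            "zero mean inflow; returning absolute residual", stacklevel=2
        )
        return float(np.max(np.abs(means - ref)))
    return float(np.max(np.abs(means - ref) / abs(ref)))
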