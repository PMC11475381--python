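"""Implicit coupled 1D-0D pulsatile blood-flow solver.

Unknowns are cross-sectional area A and flow Q at every mesh node, plus the
two compliance-node pressures of each terminal Windkessel bed.  The 1D
continuity and momentum equations

    dA/dt + dQ/dx = 0
    (rho/A) dQ/dt + (rho/A) d(Q^2/A)/dx + dP/dx = -22 pi mu Q / A^2

are closed by the elastic tube law P(A) and collocated at the mesh nodes:
second-order central differences in the interior, second-order one-sided
differences at vessel ends, BDF2 in time (BDF1 on the first step).  At
bifurcations mass conservation and pressure continuity are imposed; at
terminals the 1D pressure couples to the bed through the characteristic
impedance R1.  Each time step solves the full nonlinear system by damped
Newton iteration on an analytic sparse Jacobian.

A steady mode drops every time derivative and closes the beds
algebraically; it is also used to initialise pulsatile runs, which makes
cycle-to-cycle periodicity converge quickly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .constitutive import MMHG, BloodProperties, WallLaw, exponent_b, wave_speed
from .mesh import Mesh1D, Vessel1D
from .waveforms import InflowWaveform
from .windkessel import WindkesselBed

log = logging.getLogger(__name__)

FRICTION_COEFF = 22.0 * np.pi  # viscous friction: -22 pi mu Q / A^2


class SolverError(RuntimeError):
    pass


class NegativeAreaError(SolverError):
    pass


@dataclass
class SolverConfig:
    """Numerical settings of the 1D-0D solver.

    ``dt`` time step (s); ``n_cycles`` maximum cardiac cycles;
    ``periodicity_tol`` relative L2 change of inlet pressure between
    consecutive cycles for early exit; ``newton_tol`` scaled-residual
    tolerance; ``steady`` solves the time-independent problem instead.
    """

    dt: float = 1e-4
    n_cycles: int = 5
    periodicity_tol: float = 0.005
    newton_tol: float = 1e-10
    newton_stall_tol: float = 1e-6  # accept a stalled iteration below this
    newton_maxit: int = 25
    max_dt_halvings: int = 4
    steady: bool = False
    junction_total_pressure: bool = False


@dataclass
class Solution:
    """P/Q/A history of the final cycle (or the steady state) at every node."""

    mesh: Mesh1D
    t: np.ndarray  # (n_t,)
    P: np.ndarray  # (n_t, n_nodes) dyn/cm^2
    Q: np.ndarray  # (n_t, n_nodes) cm^3/s
    A: np.ndarray  # (n_t, n_nodes) cm^2
    node_offset: dict[int, int]  # vessel_id -> first global node index
    periodicity: float = np.nan  # achieved cycle-to-cycle inlet-P change
    steady: bool = False

    def node_index(self, vessel_id: int, x: float) -> int:
        """Global index of the node of ``vessel_id`` nearest arc-length x (cm)."""
        v = self.mesh.vessel(vessel_id)
        i = int(np.argmin(np.abs(v.x - x)))
        return self.node_offset[vessel_id] + i

    def vessel_nodes(self, vessel_id: int) -> slice:
        v = self.mesh.vessel(vessel_id)
        off = self.node_offset[vessel_id]
        return slice(off, off + v.n_nodes)

    def root_inlet_node(self, vessel_id: int) -> int:
        """Global node index of the tree inlet above ``vessel_id``."""
        v = self.mesh.vessel(vessel_id)
        while v.parent is not None:
            v = self.mesh.vessel(v.parent)
        return self.node_offset[v.vessel_id]

    def mean_pressure(self, node: int) -> float:
        """Cycle-mean pressure at a node (dyn/cm^2)."""
        if len(self.t) == 1:
            return float(self.P[0, node])
        return float(np.trapezoid(self.P[:, node], self.t) / (self.t[-1] - self.t[0]))

    def junction_mass_error(self) -> float:
        """Max relative junction mass defect over all stored steps."""
        worst = 0.0
        for v in self.mesh.vessels:
            ch = self.mesh.children(v.vessel_id)
            if not ch:
                continue
            qp = self.Q[:, self.node_offset[v.vessel_id] + v.n_nodes - 1]
            qc = sum(self.Q[:, self.node_offset[c.vessel_id]] for c in ch)
            denom = np.maximum(np.abs(qp), 1e-30)
            worst = max(worst, float(np.max(np.abs(qp - qc) / denom)))
        return worst


class CoronarySolver:
    """Assembles and advances the coupled 1D-0D system on one coronary tree."""

    def __init__(
        self,
        mesh: Mesh1D,
        inflow: InflowWaveform,
        beds: list[WindkesselBed],
        blood: BloodProperties | None = None,
        wall: WallLaw | None = None,
        config: SolverConfig | None = None,
    ):
        self.mesh = mesh
        self.inflow = inflow
        self.blood = blood or BloodProperties()
        self.wall = wall or WallLaw()
        self.config = config or SolverConfig()
        roots = mesh.roots()
        if len(roots) != 1:
            raise ValueError("solver expects a single-rooted tree (one coronary side)")
        self.root = roots[0]
        bed_ids = {b.vessel_id for b in beds}
        term_ids = {v.vessel_id for v in mesh.terminals()}
        if bed_ids != term_ids:
            raise ValueError(f"beds {sorted(bed_ids)} do not match terminals {sorted(term_ids)}")
        self.beds = sorted(beds, key=lambda b: b.vessel_id)

        # global node numbering, vessel by vessel
        self.node_offset: dict[int, int] = {}
        off = 0
        for v in mesh.vessels:
            if v.n_nodes < 3:
                raise ValueError(f"vessel {v.vessel_id} has fewer than 3 nodes")
            self.node_offset[v.vessel_id] = off
            off += v.n_nodes
        self.n_nodes = off
        self.n_dof = 2 * self.n_nodes + 2 * len(self.beds)
        self.bed_base = 2 * self.n_nodes
        self.bed_index = {b.vessel_id: j for j, b in enumerate(self.beds)}

        # per-node reference geometry/stiffness
        self.A0 = np.concatenate([v.A0 for v in mesh.vessels])
        r0 = np.concatenate([v.r0 for v in mesh.vessels])
        self.c0 = wave_speed(r0, self.blood, self.wall)
        self.bexp = np.broadcast_to(
            np.asarray(exponent_b(self.c0, self.blood, self.wall), dtype=float), self.A0.shape
        ).copy()
        self.gamma_v = self.wall.Gamma / self.A0**1.5

        # residual scaling per row (pressure-type rows vs flow-type rows)
        self.q_ref = max(float(np.max(np.abs(inflow.values))), 1e-6)
        p_scale = 93.33 * MMHG
        s = np.empty(self.n_dof)
        for v in mesh.vessels:
            o = self.node_offset[v.vessel_id]
            n = v.n_nodes
            a_rows = 2 * (o + np.arange(n))
            q_rows = a_rows + 1
            s[a_rows] = self.q_ref  # continuity rows
            s[a_rows[0]] = p_scale  # one-sided momentum at node 0
            s[q_rows] = p_scale  # momentum rows
            s[q_rows[0]] = self.q_ref if v.parent is None else p_scale
            s[q_rows[-1]] = p_scale if mesh.is_terminal(v.vessel_id) else self.q_ref
        s[self.bed_base:] = self.q_ref if not self.config.steady else p_scale
        self.row_scale = s

    # ------------------------------------------------------------------
    # indexing helpers
    # ------------------------------------------------------------------
    def a_idx(self, vessel_id: int) -> np.ndarray:
        o = self.node_offset[vessel_id]
        n = self.mesh.vessel(vessel_id).n_nodes
        return 2 * (o + np.arange(n))

    def q_idx(self, vessel_id: int) -> np.ndarray:
        return self.a_idx(vessel_id) + 1

    # ------------------------------------------------------------------
    # assembly
    # ------------------------------------------------------------------
    def _pressure(self, A: np.ndarray, ct: float, rhs_a: np.ndarray):
        """Nodal pressure and dP/dA for the current time-derivative stencil."""
        if np.any(A <= 0):
            bad = int(np.argmin(A))
            raise NegativeAreaError(f"non-positive area at global node {bad}")
        ratio = A / self.A0
        el = (2.0 * self.blood.rho * self.c0**2 / self.bexp) * (ratio ** (self.bexp / 2.0) - 1.0)
        P = self.wall.Pext + self.wall.P0 + el
        dPdA = self.blood.rho * self.c0**2 * ratio ** (self.bexp / 2.0 - 1.0) / self.A0
        if self.wall.Gamma != 0.0:
            P = P + self.gamma_v * (ct * A - rhs_a)
            dPdA = dPdA + self.gamma_v * ct
        return P, dPdA

    def _assemble(self, U, t, ct, rhs, plv_dt):
        """Residual vector and sparse Jacobian at state U.

        ``ct`` is the implicit time-derivative coefficient (0 for steady),
        ``rhs`` the explicit part of the BDF stencil per unknown, and
        ``plv_dt`` the matching dPLV/dt per bed.
        """
        mesh, blood = self.mesh, self.blood
        rho, mu = blood.rho, blood.mu
        fric = FRICTION_COEFF * mu
        nn = self.n_nodes
        A = U[0 : 2 * nn : 2]
        Q = U[1 : 2 * nn : 2]
        rhs_a = rhs[0 : 2 * nn : 2]
        rhs_q = rhs[1 : 2 * nn : 2]
        P, dPdA = self._pressure(A, ct, rhs_a)
        Fm = Q * Q / A  # momentum flux
        dFdQ = 2.0 * Q / A
        dFdA = -(Q * Q) / (A * A)

        F = np.zeros(self.n_dof)
        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []

        def add(r, c, v):
            rows.append(np.atleast_1d(np.asarray(r, dtype=np.int64)))
            cols.append(np.atleast_1d(np.asarray(c, dtype=np.int64)))
            vals.append(np.atleast_1d(np.asarray(v, dtype=float)))

        for v in mesh.vessels:
            vid = v.vessel_id
            o = self.node_offset[vid]
            n = v.n_nodes
            h = v.spacing
            g = o + np.arange(n)
            ai = 2 * g
            qi = ai + 1
            Av, Qv, Pv = A[g], Q[g], P[g]
            Fv, dFdQv, dFdAv, dPdAv = Fm[g], dFdQ[g], dFdA[g], dPdA[g]
            adot = ct * Av - rhs_a[g]
            qdot = ct * Qv - rhs_q[g]

            # --- continuity, interior (central) and outlet end (one-sided)
            ii = np.arange(1, n - 1)
            F[ai[ii]] = adot[ii] + (Qv[ii + 1] - Qv[ii - 1]) / (2 * h)
            if ct != 0.0:
                add(ai[ii], ai[ii], np.full(n - 2, ct))
            add(ai[ii], qi[ii + 1], np.full(n - 2, 1.0 / (2 * h)))
            add(ai[ii], qi[ii - 1], np.full(n - 2, -1.0 / (2 * h)))

            F[ai[-1]] = adot[-1] + (3 * Qv[-1] - 4 * Qv[-2] + Qv[-3]) / (2 * h)
            if ct != 0.0:
                add(ai[-1], ai[-1], ct)
            add([ai[-1]] * 3, [qi[-1], qi[-2], qi[-3]],
                [3 / (2 * h), -4 / (2 * h), 1 / (2 * h)])

            # --- momentum helper: center node c with stencil (members, weights)
            def momentum(c_loc, members, weights, row):
                c = int(c_loc)
                flux = sum(w * Fv[m] for m, w in zip(members, weights))
                grad = sum(w * Pv[m] for m, w in zip(members, weights))
                F[row] = (rho / Av[c]) * qdot[c] + (rho / Av[c]) * flux + grad \
                    + fric * Qv[c] / Av[c] ** 2
                add(row, qi[c], (rho / Av[c]) * ct + fric / Av[c] ** 2)
                add(row, ai[c],
                    -(rho / Av[c] ** 2) * (qdot[c] + flux) - 2 * fric * Qv[c] / Av[c] ** 3)
                for m, w in zip(members, weights):
                    add(row, qi[m], (rho / Av[c]) * w * dFdQv[m])
                    add(row, ai[m], (rho / Av[c]) * w * dFdAv[m] + w * dPdAv[m])

            # vectorised central momentum for interior nodes
            ii = np.arange(1, n - 1)
            flux_c = (Fv[ii + 1] - Fv[ii - 1]) / (2 * h)
            grad_c = (Pv[ii + 1] - Pv[ii - 1]) / (2 * h)
            F[qi[ii]] = (rho / Av[ii]) * qdot[ii] + (rho / Av[ii]) * flux_c + grad_c \
                + fric * Qv[ii] / Av[ii] ** 2
            add(qi[ii], qi[ii], (rho / Av[ii]) * ct + fric / Av[ii] ** 2)
            add(qi[ii], ai[ii],
                -(rho / Av[ii] ** 2) * (qdot[ii] + flux_c) - 2 * fric * Qv[ii] / Av[ii] ** 3)
            for shift, sgn in ((1, 1.0), (-1, -1.0)):
                w = sgn / (2 * h)
                m = ii + shift
                add(qi[ii], qi[m], (rho / Av[ii]) * w * dFdQv[m])
                add(qi[ii], ai[m], (rho / Av[ii]) * w * dFdAv[m] + w * dPdAv[m])

            # one-sided momentum at node 0 (A-row of node 0)
            momentum(0, [0, 1, 2], [-3 / (2 * h), 4 / (2 * h), -1 / (2 * h)], ai[0])

            # --- inlet Q-row: prescribed inflow or pressure continuity
            if v.parent is None:
                F[qi[0]] = Qv[0] - float(self.inflow(t))
                add(qi[0], qi[0], 1.0)
            else:
                pv = mesh.vessel(v.parent)
                pg = self.node_offset[v.parent] + pv.n_nodes - 1
                F[qi[0]] = P[g[0]] - P[pg]
                add(qi[0], ai[0], dPdA[g[0]])
                add(qi[0], 2 * pg, -dPdA[pg])
                if self.config.junction_total_pressure:
                    F[qi[0]] += 0.5 * rho * ((Q[g[0]] / A[g[0]]) ** 2 - (Q[pg] / A[pg]) ** 2)
                    add(qi[0], qi[0], rho * Q[g[0]] / A[g[0]] ** 2)
                    add(qi[0], ai[0], -rho * Q[g[0]] ** 2 / A[g[0]] ** 3)
                    add(qi[0], 2 * pg + 1, -rho * Q[pg] / A[pg] ** 2)
                    add(qi[0], 2 * pg, rho * Q[pg] ** 2 / A[pg] ** 3)

            # --- outlet Q-row: junction mass balance or bed coupling
            children = mesh.children(vid)
            if children:
                F[qi[-1]] = Qv[-1]
                add(qi[-1], qi[-1], 1.0)
                for c in children:
                    cg = self.node_offset[c.vessel_id]
                    F[qi[-1]] -= Q[cg]
                    add(qi[-1], 2 * cg + 1, -1.0)
            else:
                j = self.bed_index[vid]
                b = self.beds[j]
                i1 = self.bed_base + 2 * j  # Pc1
                i2 = i1 + 1  # Pc2
                pc1, pc2 = U[i1], U[i2]
                F[qi[-1]] = P[g[-1]] - b.R1 * Qv[-1] - pc1
                add(qi[-1], ai[-1], dPdA[g[-1]])
                add(qi[-1], qi[-1], -b.R1)
                add(qi[-1], i1, -1.0)
                if self.config.steady or ct == 0.0:
                    # algebraic bed: steady flow through R2, R3
                    F[i1] = pc1 - pc2 - Qv[-1] * b.R2
                    add([i1, i1, i1], [i1, i2, qi[-1]], [1.0, -1.0, -b.R2])
                    F[i2] = pc2 - b.Pven - Qv[-1] * b.R3
                    add([i2, i2], [i2, qi[-1]], [1.0, -b.R3])
                else:
                    F[i1] = b.C1 * (ct * pc1 - rhs[i1]) - Qv[-1] + (pc1 - pc2) / b.R2
                    add([i1, i1, i1], [i1, i2, qi[-1]],
                        [b.C1 * ct + 1.0 / b.R2, -1.0 / b.R2, -1.0])
                    F[i2] = (
                        b.C2 * (ct * pc2 - rhs[i2])
                        - (pc1 - pc2) / b.R2
                        + (pc2 - b.Pven) / b.R3
                        - b.C2 * plv_dt[j]
                    )
                    add([i2, i2], [i2, i1],
                        [b.C2 * ct + 1.0 / b.R2 + 1.0 / b.R3, -1.0 / b.R2])

        J = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n_dof, self.n_dof),
        ).tocsc()
        return F, J

    # ------------------------------------------------------------------
    # Newton
    # ------------------------------------------------------------------
    def _newton(self, U0, t, ct, rhs, plv_dt):
        U = U0.copy()
        nn = self.n_nodes
        F, J = self._assemble(U, t, ct, rhs, plv_dt)
        res = np.max(np.abs(F / self.row_scale))
        for _ in range(self.config.newton_maxit):
            if res < self.config.newton_tol:
                return U, res, True
            dU = splu(J).solve(-F)
            alpha = 1.0
            accepted = False
            while alpha >= 1.0 / 64:
                Un = U + alpha * dU
                if np.all(Un[0 : 2 * nn : 2] > 0):
                    try:
                        Fn, Jn = self._assemble(Un, t, ct, rhs, plv_dt)
                    except NegativeAreaError:
                        alpha /= 2
                        continue
                    rn = np.max(np.abs(Fn / self.row_scale))
                    if rn < res or rn < self.config.newton_tol:
                        U, F, J, res = Un, Fn, Jn, rn
                        accepted = True
                        break
                alpha /= 2
            if not accepted:
                # stalled: with extreme wall stiffness the residual floor is
                # set by rounding of the tube law; accept if already small
                return U, res, res < self.config.newton_stall_tol
        return U, res, res < self.config.newton_tol

    # ------------------------------------------------------------------
    # initial guess and steady solve
    # ------------------------------------------------------------------
    def _subtree_fraction(self, vid: int) -> float:
        if self.mesh.is_terminal(vid):
            return self.beds[self.bed_index[vid]].flow_fraction
        return sum(self._subtree_fraction(c.vessel_id) for c in self.mesh.children(vid))

    def _initial_state(self, q_in: float) -> np.ndarray:
        U = np.zeros(self.n_dof)
        U[0 : 2 * self.n_nodes : 2] = self.A0
        for v in self.mesh.vessels:
            qv = q_in * self._subtree_fraction(v.vessel_id)
            U[self.q_idx(v.vessel_id)] = qv
        for j, b in enumerate(self.beds):
            q = q_in * b.flow_fraction
            U[self.bed_base + 2 * j + 1] = b.Pven + q * b.R3
            U[self.bed_base + 2 * j] = b.Pven + q * (b.R2 + b.R3)
        return U

    def _steady_state(self, q_in: float | None = None) -> np.ndarray:
        """Newton-solve the time-independent system; returns the state vector.

        Falls back to a flow-ramp continuation if the direct solve stalls
        (severe stenoses make the advective term strongly nonlinear).
        """
        q_target = float(self.inflow.mean) if q_in is None else float(q_in)
        rhs = np.zeros(self.n_dof)
        plv0 = np.zeros(len(self.beds))
        inflow_save = self.inflow
        try:
            self.inflow = InflowWaveform.constant(q_target, inflow_save.period,
                                                  side=inflow_save.side)
            U, res, ok = self._newton(self._initial_state(q_target), 0.0, 0.0, rhs, plv0)
            if not ok:
                U = self._initial_state(0.25 * q_target)
                for frac in (0.25, 0.5, 0.75, 1.0):
                    self.inflow = InflowWaveform.constant(q_target * frac, inflow_save.period,
                                                          side=inflow_save.side)
                    U, res, ok = self._newton(U, 0.0, 0.0, rhs, plv0)
                    if not ok:
                        raise SolverError(
                            f"steady Newton failed at {frac:.0%} inflow (residual {res:.3e})"
                        )
        finally:
            self.inflow = inflow_save
        return U

    def solve_steady(self, q_in: float | None = None) -> Solution:
        """Solve the time-independent 1D-0D system at inflow ``q_in``
        (default: the cycle-mean of the configured inflow waveform)."""
        U = self._steady_state(q_in)
        nn = self.n_nodes
        A = U[0 : 2 * nn : 2].copy()
        Q = U[1 : 2 * nn : 2].copy()
        P, _ = self._pressure(A, 0.0, np.zeros(nn))
        return Solution(
            self.mesh,
            np.array([0.0]),
            P[None, :],
            Q[None, :],
            A[None, :],
            dict(self.node_offset),
            steady=True,
        )

    # ------------------------------------------------------------------
    # transient solve
    # ------------------------------------------------------------------
    def _plv_dt(self, t: float, dt: float, bdf2: bool) -> np.ndarray:
        out = np.empty(len(self.beds))
        for j, b in enumerate(self.beds):
            p0 = b.plv_at(t)
            p1 = b.plv_at(t - dt)
            if bdf2:
                p2 = b.plv_at(t - 2 * dt)
                out[j] = (3 * p0 - 4 * p1 + p2) / (2 * dt)
            else:
                out[j] = (p0 - p1) / dt
        return out

    def _step(self, U1, U2, t_new, dt, first, depth=0):
        """Advance one step to t_new; sub-step with halved dt on failure."""
        if first or U2 is None:
            ct = 1.0 / dt
            rhs = U1 / dt
            bdf2 = False
        else:
            ct = 3.0 / (2 * dt)
            rhs = (4 * U1 - U2) / (2 * dt)
            bdf2 = True
        plv_dt = self._plv_dt(t_new, dt, bdf2)
        U, res, ok = self._newton(U1, t_new, ct, rhs, plv_dt)
        if ok:
            return U
        if depth >= self.config.max_dt_halvings:
            raise SolverError(
                f"Newton failed at t={t_new:.5f}s after {depth} dt halvings "
                f"(scaled residual {res:.3e})"
            )
        log.warning("Newton stalled at t=%.5f s; halving dt (depth %d)", t_new, depth + 1)
        half = self._step(U1, None, t_new - dt / 2, dt / 2, True, depth + 1)
        return self._step(half, None, t_new, dt / 2, True, depth + 1)

    def solve(self) -> Solution:
        """Run the pulsatile simulation (or the steady problem if configured)."""
        if self.config.steady:
            return self.solve_steady()
        cfg = self.config
        period = self.inflow.period
        n_steps = max(int(round(period / cfg.dt)), 2)
        dt = period / n_steps
        U = self._steady_state(self.inflow.mean)
        U1, U2 = U.copy(), None

        nn = self.n_nodes
        t_local = np.arange(n_steps + 1) * dt
        prev_inlet: np.ndarray | None = None
        periodicity = np.nan
        root_node = self.node_offset[self.root.vessel_id]
        P_hist = np.empty((n_steps + 1, nn))
        Q_hist = np.empty((n_steps + 1, nn))
        A_hist = np.empty((n_steps + 1, nn))
        for cyc in range(cfg.n_cycles):
            A = U1[0 : 2 * nn : 2]
            P, _ = self._pressure(A, 0.0, np.zeros(nn))
            P_hist[0], Q_hist[0], A_hist[0] = P, U1[1 : 2 * nn : 2], A
            for k in range(1, n_steps + 1):
                t_new = cyc * period + k * dt
                first = cyc == 0 and k == 1
                U = self._step(U1, U2, t_new, dt, first)
                U2, U1 = U1, U
                A = U[0 : 2 * nn : 2]
                P, _ = self._pressure(A, 0.0, np.zeros(nn))
                P_hist[k], Q_hist[k], A_hist[k] = P, U[1 : 2 * nn : 2], A
            inlet = P_hist[:, root_node].copy()
            if prev_inlet is not None:
                periodicity = float(
                    np.linalg.norm(inlet - prev_inlet) / max(np.linalg.norm(prev_inlet), 1e-30)
                )
                if periodicity < cfg.periodicity_tol:
                    break
            prev_inlet = inlet
        return Solution(
            self.mesh,
            t_local,
            P_hist.copy(),
            Q_hist.copy(),
            A_hist.copy(),
            dict(self.node_offset),
            periodicity=periodicity,
        )
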