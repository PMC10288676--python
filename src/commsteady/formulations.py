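"""Algebraic steady-state systems with KKT-reformulated inner optimizations.

For a (community model, environment) pair this module assembles the full set
of steady-state conditions as one algebraic system in a flat variable vector

    chemostat:  z = [nu_1 .. nu_nX, C, X, lam1, lam2]
    batch:      z = [nu_1 .. nu_nX, x, mu_star, lam1, lam2]

The inner growth-maximization problems (per species for the rational-agent
modes, joint for the rational-community modes) are replaced by their
Karush-Kuhn-Tucker conditions.  Because the inner problems are linear in
their optimization arguments, KKT is sufficient for global optimality, which
is additionally certified — independently of any multipliers — by re-solving
the inner linear program at a candidate's outer variables
(:func:`verify_inner_optimality`).

Every equation is represented as a polynomial of degree <= 3 in z (degree 3
occurs only in batch complementarity products lam * x * nu), so residuals and
exact Jacobians are cheap and shared by the MILP stage, the
Levenberg-Marquardt refinement and the active-set oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import (
    AGENT_MODES,
    CHEMOSTAT_MODES,
    CommunityModel,
    EnvironmentSpec,
    SteadyStateSolution,
    validate_community,
)

__all__ = [
    "AlgebraicSystem",
    "ResidualReport",
    "assemble_system",
    "residual",
    "verify_inner_optimality",
    "SUPPORT_THRESHOLD",
]

#: abundance above which a species counts as present (operationalizes X_i > 0)
SUPPORT_THRESHOLD = 1e-9


# ---------------------------------------------------------------------------
# polynomial containers


class PolySet:
    """A stack of polynomial rows r_k(z) of degree <= 3 with exact Jacobian."""

    def __init__(self, n_rows: int, n_z: int):
        self.n_rows = n_rows
        self.n_z = n_z
        self.const = np.zeros(n_rows)
        self._lin: list[tuple[int, int, float]] = []
        self._quad: list[tuple[int, int, int, float]] = []
        self._cub: list[tuple[int, int, int, int, float]] = []
        self._compiled = False

    def add_const(self, row: int, c: float) -> None:
        self.const[row] += c

    def add_lin(self, row: int, col: int, c: float) -> None:
        if c != 0.0:
            self._lin.append((row, col, c))

    def add_quad(self, row: int, i: int, j: int, c: float) -> None:
        if c != 0.0:
            self._quad.append((row, i, j, c))

    def add_cub(self, row: int, i: int, j: int, k: int, c: float) -> None:
        if c != 0.0:
            self._cub.append((row, i, j, k, c))

    def compile(self) -> None:
        self.L = np.zeros((self.n_rows, self.n_z))
        for r, c, v in self._lin:
            self.L[r, c] += v
        q = self._quad
        self.q_row = np.array([t[0] for t in q], dtype=int)
        self.q_i = np.array([t[1] for t in q], dtype=int)
        self.q_j = np.array([t[2] for t in q], dtype=int)
        self.q_c = np.array([t[3] for t in q], dtype=float)
        u = self._cub
        self.u_row = np.array([t[0] for t in u], dtype=int)
        self.u_i = np.array([t[1] for t in u], dtype=int)
        self.u_j = np.array([t[2] for t in u], dtype=int)
        self.u_k = np.array([t[3] for t in u], dtype=int)
        self.u_c = np.array([t[4] for t in u], dtype=float)
        self._compiled = True

    def value(self, z: np.ndarray) -> np.ndarray:
        v = self.const + self.L @ z
        if self.q_row.size:
            np.add.at(v, self.q_row, self.q_c * z[self.q_i] * z[self.q_j])
        if self.u_row.size:
            np.add.at(v, self.u_row, self.u_c * z[self.u_i] * z[self.u_j] * z[self.u_k])
        return v

    def jacobian(self, z: np.ndarray) -> np.ndarray:
        J = self.L.copy()
        if self.q_row.size:
            np.add.at(J, (self.q_row, self.q_i), self.q_c * z[self.q_j])
            np.add.at(J, (self.q_row, self.q_j), self.q_c * z[self.q_i])
        if self.u_row.size:
            np.add.at(J, (self.u_row, self.u_i), self.u_c * z[self.u_j] * z[self.u_k])
            np.add.at(J, (self.u_row, self.u_j), self.u_c * z[self.u_i] * z[self.u_k])
            np.add.at(J, (self.u_row, self.u_k), self.u_c * z[self.u_i] * z[self.u_j])
        return J

    def substitute(self, z_fixed: np.ndarray, fixed_mask: np.ndarray, rows=None):
        """Fold fixed variables into constants; error if rows stay nonlinear.

        Returns (L, c) for the selected ``rows`` (all rows when None), with
        zero columns at fixed variables, such that the selected row values
        equal ``c + L @ z`` for any z agreeing with ``z_fixed`` on the fixed
        entries.
        """
        if rows is None:
            rows = range(self.n_rows)
        rows = list(rows)
        pos = {r: k for k, r in enumerate(rows)}
        c = self.const[rows].copy()
        L = self.L[rows].copy()
        c += L[:, fixed_mask] @ z_fixed[fixed_mask]
        L[:, fixed_mask] = 0.0
        for r, i, j, v in self._quad:
            if r not in pos:
                continue
            k = pos[r]
            fi, fj = fixed_mask[i], fixed_mask[j]
            if fi and fj:
                c[k] += v * z_fixed[i] * z_fixed[j]
            elif fi:
                L[k, j] += v * z_fixed[i]
            elif fj:
                L[k, i] += v * z_fixed[j]
            else:
                raise ValueError("row remains bilinear after substitution")
        for r, *_ in self._cub:
            if r in pos:
                raise ValueError("cubic rows cannot be linearized by fixing abundances")
        return L, c


# ---------------------------------------------------------------------------
# layout and row bookkeeping


@dataclass
class VariableLayout:
    """Named disjoint slices into the flat variable vector z."""

    nu: list[slice]
    C: slice | None
    X: slice | None
    x: slice | None
    mu_star: int | None
    lam1: slice
    lam2: slice
    n: int

    @property
    def abundance(self) -> slice:
        return self.X if self.X is not None else self.x


@dataclass
class QRow:
    """One inequality row paired with a lam1 multiplier entry.

    kind 'cap'     : one affine piece of a capacity constraint A_i nu_i <= b_i(C)
    kind 'Cnn'     : -C_c <= 0 (CC only; C >= 0 enters the inner problem there)
    kind 'culture' : sum_i x_i (T_i nu_i)_c - u_c <= 0 (BC only)
    """

    name: str
    kind: str
    species: int | None
    a_row: int | None
    piece: int | None
    compound: int | None
    intercept: float = 0.0
    gradient: np.ndarray | None = None  # over C, for 'cap' rows


@dataclass
class ResidualReport:
    """Exact constraint-violation summary of a candidate (no tolerances)."""

    residual_max: float
    residual_ssq: float
    breakdown: dict[str, float] = field(default_factory=dict)


class AlgebraicSystem:
    """Assembled steady-state system for one (model, environment) pair."""

    def __init__(self, model: CommunityModel, env: EnvironmentSpec):
        self.model = model
        self.env = env
        self.mode = env.mode
        self.objective = env.objective
        self._build_layout()
        self._build_rows()
        self._compiled: dict[tuple, tuple[PolySet, PolySet]] = {}

    # -- construction ------------------------------------------------------

    def _build_layout(self) -> None:
        model, env = self.model, self.env
        off = 0
        nu_slices = []
        for sp in model.species:
            nu_slices.append(slice(off, off + sp.n_nu))
            off += sp.n_nu
        self.n_nu_total = off
        if env.is_chemostat:
            C_sl = slice(off, off + model.n_C)
            off += model.n_C
            X_sl = slice(off, off + model.n_X)
            off += model.n_X
            x_sl, mu_idx = None, None
        else:
            C_sl = None
            x_sl = slice(off, off + model.n_X)
            off += model.n_X
            mu_idx = off
            off += 1
            X_sl = None

        # q rows: capacity pieces per species, then mode-specific extras
        q_rows: list[QRow] = []
        for i, sp in enumerate(model.species):
            for a_row, spec in enumerate(sp.b):
                for p, (alpha, grad) in enumerate(spec.pieces):
                    tag = "" if len(spec.pieces) == 1 else f".p{p}"
                    q_rows.append(
                        QRow(
                            name=f"cap[{sp.id}:a{a_row}{tag}]",
                            kind="cap",
                            species=i,
                            a_row=a_row,
                            piece=p,
                            compound=None,
                            intercept=float(alpha),
                            gradient=np.asarray(grad, dtype=float),
                        )
                    )
        if self.mode == "CC":
            for c, cid in enumerate(model.extracellular_ids):
                q_rows.append(QRow(f"nonneg[C:{cid}]", "Cnn", None, None, None, c))
        if self.mode == "BC":
            for c, cid in enumerate(model.extracellular_ids):
                q_rows.append(QRow(f"culture[{cid}]", "culture", None, None, None, c))
        self.q_rows = q_rows

        lam1_sl = slice(off, off + len(q_rows))
        off += len(q_rows)
        n_lam2 = sum(sp.n_S for sp in model.species)
        if self.mode == "CC":
            n_lam2 += model.n_C  # duals of the chemostat balance inside the inner LP
        lam2_sl = slice(off, off + n_lam2)
        off += n_lam2
        self.layout = VariableLayout(
            nu=nu_slices, C=C_sl, X=X_sl, x=x_sl, mu_star=mu_idx, lam1=lam1_sl, lam2=lam2_sl, n=off
        )
        # lam2 offsets per species (S-row duals), plus balance duals for CC
        self.lam2_S_offset = []
        o = lam2_sl.start
        for sp in model.species:
            self.lam2_S_offset.append(o)
            o += sp.n_S
        self.lam2_C_offset = o if self.mode == "CC" else None

    def _build_rows(self) -> None:
        """Fix the ordered equation/inequality name and kind lists."""
        model = self.model
        eq_names: list[str] = []
        eq_kinds: list[str] = []
        if self.env.is_chemostat:
            for cid in model.extracellular_ids:
                eq_names.append(f"balance[{cid}]")
                eq_kinds.append("balance")
            for sp in model.species:
                eq_names.append(f"dgrowth[{sp.id}]")
                eq_kinds.append("dgrowth")
        else:
            for sp in model.species:
                eq_names.append(f"mugrowth[{sp.id}]")
                eq_kinds.append("mugrowth")
            eq_names.append("sum_x")
            eq_kinds.append("sumx")
        for sp in model.species:
            for met in sp.metabolite_ids:
                eq_names.append(f"intracell[{sp.id}:{met}]")
                eq_kinds.append("intracell")
        for sp in model.species:
            for rxn in sp.reaction_ids:
                eq_names.append(f"stationarity[{sp.id}:{rxn}]")
                eq_kinds.append("stationarity")
        if self.mode == "CC":
            for cid in model.extracellular_ids:
                eq_names.append(f"stationarity[C:{cid}]")
                eq_kinds.append("stationarity_C")
        for q in self.q_rows:
            eq_names.append(f"compl[{q.name}]")
            eq_kinds.append("complementarity")
        self.eq_names, self.eq_kinds = eq_names, eq_kinds

        in_names: list[str] = []
        in_kinds: list[str] = []
        for q in self.q_rows:
            in_names.append(q.name)
            in_kinds.append("q")
        if self.mode == "CA":
            for cid in model.extracellular_ids:
                in_names.append(f"nonneg[C:{cid}]")
                in_kinds.append("nonneg_C")
        if self.mode == "BA":
            for cid in model.extracellular_ids:
                in_names.append(f"culture[{cid}]")
                in_kinds.append("culture")
        ab_tag = "X" if self.env.is_chemostat else "x"
        for sp in model.species:
            in_names.append(f"nonneg[{ab_tag}:{sp.id}]")
            in_kinds.append("nonneg_X")
        for q in self.q_rows:
            in_names.append(f"nonneg[lam1:{q.name}]")
            in_kinds.append("nonneg_lam")
        self.ineq_names, self.ineq_kinds = in_names, in_kinds

    @property
    def equation_names(self) -> list[str]:
        """Stable equality-row name list (inequalities in ``ineq_names``)."""
        return list(self.eq_names)

    # -- q-row affine/bilinear pieces over z -------------------------------

    def _q_terms(self, q: QRow):
        """Yield (const, lin[(col,coeff)], quad[(i,j,coeff)]) of one q row."""
        lay = self.layout
        lin: list[tuple[int, float]] = []
        quad: list[tuple[int, int, float]] = []
        const = 0.0
        if q.kind == "cap":
            sp = self.model.species[q.species]
            base = lay.nu[q.species].start
            for r in range(sp.n_nu):
                if sp.A[q.a_row, r] != 0.0:
                    lin.append((base + r, sp.A[q.a_row, r]))
            const -= q.intercept
            if lay.C is not None:
                for c in range(self.model.n_C):
                    if q.gradient[c] != 0.0:
                        lin.append((lay.C.start + c, -q.gradient[c]))
            elif np.any(q.gradient != 0.0):
                raise ValueError(
                    "batch environment on a model with concentration-dependent bounds"
                )
        elif q.kind == "Cnn":
            lin.append((lay.C.start + q.compound, -1.0))
        elif q.kind == "culture":
            const -= float(self.env.u[q.compound])
            for i, sp in enumerate(self.model.species):
                base = lay.nu[i].start
                xcol = lay.x.start + i
                for r in range(sp.n_nu):
                    if sp.T[q.compound, r] != 0.0:
                        quad.append((xcol, base + r, sp.T[q.compound, r]))
        else:  # pragma: no cover
            raise AssertionError(q.kind)
        return const, lin, quad

    # -- compilation -------------------------------------------------------

    def _support_key(self, support) -> tuple:
        if self.objective != "sum_growth" or support is None:
            return ("*",)
        return tuple(bool(s) for s in support)

    def compiled(self, support=None) -> tuple[PolySet, PolySet]:
        """Return (equalities, inequalities) PolySets.

        ``support`` (bool per species) is only consulted for the sum-of-growth
        community objective, where the inner-objective gradient carries the
        indicator delta(X_i > 0) instead of the abundance weight.
        """
        key = self._support_key(support)
        if key not in self._compiled:
            self._compiled[key] = self._compile(support)
        return self._compiled[key]

    def _compile(self, support) -> tuple[PolySet, PolySet]:
        model, env, lay = self.model, self.env, self.layout
        eq = PolySet(len(self.eq_names), lay.n)
        row = 0
        if env.is_chemostat:
            D = float(env.D)
            for c in range(model.n_C):
                eq.add_const(row, D * float(env.C_in[c]))
                eq.add_lin(row, lay.C.start + c, -D)
                for i, sp in enumerate(model.species):
                    base = lay.nu[i].start
                    for r in range(sp.n_nu):
                        eq.add_quad(row, base + r, lay.X.start + i, -sp.T[c, r])
                row += 1
            for i, sp in enumerate(model.species):
                eq.add_lin(row, lay.X.start + i, D)
                eq.add_quad(row, lay.X.start + i, lay.nu[i].start + sp.growth_index, -1.0)
                row += 1
        else:
            for i, sp in enumerate(model.species):
                xcol = lay.x.start + i
                eq.add_quad(row, xcol, lay.mu_star, 1.0)
                eq.add_quad(row, xcol, lay.nu[i].start + sp.growth_index, -1.0)
                row += 1
            for i in range(model.n_X):
                eq.add_lin(row, lay.x.start + i, 1.0)
            eq.add_const(row, -1.0)
            row += 1
        for i, sp in enumerate(model.species):
            base = lay.nu[i].start
            for m in range(sp.n_S):
                for r in range(sp.n_nu):
                    eq.add_lin(row, base + r, sp.S[m, r])
                row += 1
        row = self._add_stationarity(eq, row, support)
        # complementarity products lam1 (.) q
        for qi, q in enumerate(self.q_rows):
            lcol = lay.lam1.start + qi
            const, lin, quad = self._q_terms(q)
            eq.add_lin(row, lcol, const)
            for col, cf in lin:
                eq.add_quad(row, lcol, col, cf)
            for i, j, cf in quad:
                eq.add_cub(row, lcol, i, j, cf)
            row += 1
        assert row == len(self.eq_names)
        eq.compile()

        ineq = PolySet(len(self.ineq_names), lay.n)
        row = 0
        for q in self.q_rows:
            const, lin, quad = self._q_terms(q)
            ineq.add_const(row, const)
            for col, cf in lin:
                ineq.add_lin(row, col, cf)
            for i, j, cf in quad:
                ineq.add_quad(row, i, j, cf)
            row += 1
        if self.mode == "CA":
            for c in range(model.n_C):
                ineq.add_lin(row, lay.C.start + c, -1.0)
                row += 1
        if self.mode == "BA":
            for c in range(model.n_C):
                ineq.add_const(row, -float(env.u[c]))
                for i, sp in enumerate(model.species):
                    base = lay.nu[i].start
                    xcol = lay.x.start + i
                    for r in range(sp.n_nu):
                        ineq.add_quad(row, xcol, base + r, sp.T[c, r])
                row += 1
        ab = lay.abundance
        for i in range(model.n_X):
            ineq.add_lin(row, ab.start + i, -1.0)
            row += 1
        for qi in range(len(self.q_rows)):
            ineq.add_lin(row, lay.lam1.start + qi, -1.0)
            row += 1
        assert row == len(self.ineq_names)
        ineq.compile()
        return eq, ineq

    def _add_stationarity(self, eq: PolySet, row: int, support) -> int:
        model, lay = self.model, self.layout
        mode = self.mode
        deltas = None
        if self.objective == "sum_growth":
            if support is None:
                raise ValueError("sum_growth stationarity needs a support vector")
            deltas = [1.0 if s else 0.0 for s in support]
        cap_by_species: dict[int, list[tuple[int, QRow]]] = {i: [] for i in range(model.n_X)}
        for qi, q in enumerate(self.q_rows):
            if q.kind == "cap":
                cap_by_species[q.species].append((qi, q))
        for i, sp in enumerate(model.species):
            base = lay.nu[i].start
            for r in range(sp.n_nu):
                # gradient of the inner objective w.r.t. nu_{i,r}
                if r == sp.growth_index:
                    if mode in AGENT_MODES:
                        eq.add_const(row, -1.0)
                    elif self.objective == "sum_growth":
                        eq.add_const(row, -deltas[i])
                    elif mode == "CC":
                        eq.add_lin(row, lay.X.start + i, -1.0)
                    else:  # BC biomass production
                        eq.add_lin(row, lay.x.start + i, -1.0)
                for qi, q in cap_by_species[i]:
                    eq.add_lin(row, lay.lam1.start + qi, sp.A[q.a_row, r])
                for m in range(sp.n_S):
                    eq.add_lin(row, self.lam2_S_offset[i] + m, sp.S[m, r])
                if mode == "CC":
                    for c in range(model.n_C):
                        eq.add_quad(
                            row, lay.X.start + i, self.lam2_C_offset + c, -sp.T[c, r]
                        )
                if mode == "BC":
                    for qi, q in enumerate(self.q_rows):
                        if q.kind == "culture":
                            eq.add_quad(
                                row,
                                lay.x.start + i,
                                lay.lam1.start + qi,
                                sp.T[q.compound, r],
                            )
                row += 1
        if mode == "CC":
            # stationarity w.r.t. C: -sum lam1_cap db/dC - lam1_Cnn - D lam2_C = 0
            for c in range(model.n_C):
                for qi, q in enumerate(self.q_rows):
                    if q.kind == "cap":
                        eq.add_lin(row, lay.lam1.start + qi, -q.gradient[c])
                    elif q.kind == "Cnn" and q.compound == c:
                        eq.add_lin(row, lay.lam1.start + qi, -1.0)
                eq.add_lin(row, self.lam2_C_offset + c, -float(self.env.D))
                row += 1
        return row

    # -- candidate <-> flat vector ----------------------------------------

    def solution_to_z(self, sol: SteadyStateSolution) -> np.ndarray:
        lay = self.layout
        z = np.zeros(lay.n)
        for i, sl in enumerate(lay.nu):
            nu_i = np.asarray(sol.nu[i], dtype=float)
            if nu_i.shape != (sl.stop - sl.start,):
                raise ValueError(f"flux vector {i} has wrong length")
            z[sl] = nu_i
        if self.env.is_chemostat:
            if sol.C is None or sol.X is None:
                raise ValueError("chemostat candidate needs C and X")
            z[lay.C] = sol.C
            z[lay.X] = sol.X
        else:
            if sol.x is None or sol.mu_star is None:
                raise ValueError("batch candidate needs x and mu_star")
            z[lay.x] = sol.x
            z[lay.mu_star] = sol.mu_star
        if sol.lam1 is not None:
            z[lay.lam1] = sol.lam1
        if sol.lam2 is not None:
            z[lay.lam2] = sol.lam2
        return z

    def z_to_solution(self, z: np.ndarray, branch=None) -> SteadyStateSolution:
        lay = self.layout
        sol = SteadyStateSolution(
            nu=[z[sl].copy() for sl in lay.nu],
            C=z[lay.C].copy() if lay.C is not None else None,
            X=z[lay.X].copy() if lay.X is not None else None,
            x=z[lay.x].copy() if lay.x is not None else None,
            mu_star=float(z[lay.mu_star]) if lay.mu_star is not None else None,
            lam1=z[lay.lam1].copy(),
            lam2=z[lay.lam2].copy(),
            branch=branch,
        )
        rep = self.residual_report_z(z)
        sol.residual_max = rep.residual_max
        sol.residual_ssq = rep.residual_ssq
        return sol

    def support_of_z(self, z: np.ndarray) -> tuple[bool, ...]:
        ab = z[self.layout.abundance]
        return tuple(bool(a > SUPPORT_THRESHOLD) for a in ab)

    # -- residuals ---------------------------------------------------------

    def residual_report_z(self, z: np.ndarray, support=None) -> ResidualReport:
        if support is None and self.objective == "sum_growth":
            support = self.support_of_z(z)
        eq, ineq = self.compiled(support)
        ev = eq.value(z)
        iv = np.maximum(ineq.value(z), 0.0)
        breakdown = {n: float(v) for n, v in zip(self.eq_names, ev)}
        breakdown.update({n: float(v) for n, v in zip(self.ineq_names, iv)})
        rmax = float(max(np.max(np.abs(ev), initial=0.0), np.max(iv, initial=0.0)))
        ssq = float(np.sum(ev**2) + np.sum(iv**2))
        return ResidualReport(residual_max=rmax, residual_ssq=ssq, breakdown=breakdown)

    def residual_max_z(self, z: np.ndarray, support=None) -> float:
        """Maximal constraint violation only (no per-equation breakdown)."""
        if support is None and self.objective == "sum_growth":
            support = self.support_of_z(z)
        eq, ineq = self.compiled(support)
        ev = eq.value(z)
        iv = ineq.value(z)
        return float(max(np.max(np.abs(ev), initial=0.0), np.max(iv, initial=0.0), 0.0))

    def residual_vector(self, z: np.ndarray, support=None) -> np.ndarray:
        """Equalities stacked with hinge-embedded inequality violations."""
        if support is None and self.objective == "sum_growth":
            support = self.support_of_z(z)
        eq, ineq = self.compiled(support)
        return np.concatenate([eq.value(z), np.maximum(ineq.value(z), 0.0)])

    def residual_jacobian(self, z: np.ndarray, support=None) -> np.ndarray:
        if support is None and self.objective == "sum_growth":
            support = self.support_of_z(z)
        eq, ineq = self.compiled(support)
        Jeq = eq.jacobian(z)
        iv = ineq.value(z)
        Jin = ineq.jacobian(z)
        Jin[iv <= 0.0, :] = 0.0
        return np.vstack([Jeq, Jin])


def recover_multipliers(system: AlgebraicSystem, z: np.ndarray, support=None,
                        tight_tol: float = 1e-7) -> None:
    """Fill the multiplier entries of z by least squares on the KKT rows.

    Inequality multipliers are forced to zero on rows whose slack is not
    tight (within ``tight_tol``) and kept non-negative elsewhere (projected
    NNLS after eliminating the free equality duals); equality duals are
    unrestricted.  Modifies z in place.
    """
    from scipy.optimize import nnls

    eq, ineq = system.compiled(support)
    stat = [k for k, kind in enumerate(system.eq_kinds)
            if kind in ("stationarity", "stationarity_C")]
    lay = system.layout
    lam_cols = np.r_[np.arange(lay.lam1.start, lay.lam1.stop),
                     np.arange(lay.lam2.start, lay.lam2.stop)]
    z[lam_cols] = 0.0
    val0 = eq.value(z)[stat]
    if not np.all(np.isfinite(val0)):
        return
    n_q = len(system.q_rows)
    qv = ineq.value(z)[:n_q]
    free = np.r_[np.abs(qv) <= tight_tol, np.ones(lam_cols.size - n_q, dtype=bool)]
    cols = lam_cols[free]
    J = eq.jacobian(z)[np.ix_(stat, cols)]
    n_tight = int(np.sum(free[:n_q]))
    sol, *_ = np.linalg.lstsq(J, -val0, rcond=None)
    if np.any(sol[:n_tight] < -1e-11):
        A1, A2, b = J[:, :n_tight], J[:, n_tight:], -val0
        if A2.shape[1]:
            Q2, _ = np.linalg.qr(A2, mode="reduced")
            PA1 = A1 - Q2 @ (Q2.T @ A1)
            Pb = b - Q2 @ (Q2.T @ b)
        else:
            PA1, Pb = A1, b
        lam1_t, _ = nnls(PA1, Pb)
        lam2 = (np.linalg.lstsq(A2, b - A1 @ lam1_t, rcond=None)[0]
                if A2.shape[1] else np.zeros(0))
        sol = np.concatenate([lam1_t, lam2])
    z[cols] = sol


def assemble_system(model: CommunityModel, env: EnvironmentSpec) -> AlgebraicSystem:
    """Assemble the full steady-state system for a model and environment.

    Raises on invalid communities, on agent modes carrying a community
    objective, and on batch environments applied to models with
    concentration-dependent capacity bounds (batch assumes the bound kinetics
    are insensitive to the unrepresented extracellular concentrations).
    """
    diags = validate_community(model)
    if diags:
        raise ValueError("invalid community model: " + "; ".join(diags))
    if env.mode in AGENT_MODES and env.objective is not None:
        raise ValueError("rational-agent modes admit no community objective")
    if not env.is_chemostat and model.has_concentration_dependent_bounds():
        raise ValueError("batch environment on a model with concentration-dependent bounds")
    if env.is_chemostat and env.C_in.shape != (model.n_C,):
        raise ValueError("C_in length does not match the extracellular compound set")
    if not env.is_chemostat and env.u.shape != (model.n_C,):
        raise ValueError("u length does not match the extracellular compound set")
    system = AlgebraicSystem(model, env)
    # trigger compilation early so dimension errors surface here
    system.compiled(support=(True,) * model.n_X)
    return system


def residual(system: AlgebraicSystem, cand: SteadyStateSolution) -> ResidualReport:
    """Exact residual evaluation of a candidate; no tolerance applied."""
    z = system.solution_to_z(cand)
    return system.residual_report_z(z)


# ---------------------------------------------------------------------------
# independent inner-LP optimality certificate


def _cap_rows_lp(sp, C):
    """Expanded capacity pieces of one species as A_ub nu <= b_ub at fixed C."""
    rows, rhs = [], []
    for a_row, spec in enumerate(sp.b):
        for alpha, grad in spec.pieces:
            rows.append(sp.A[a_row])
            g = np.asarray(grad, dtype=float)
            rhs.append(alpha + (float(g @ C) if C is not None else 0.0))
    return np.array(rows), np.array(rhs)


def _solve_lp(c, A_ub, b_ub, A_eq, b_eq, bounds, context: str):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds,
                  method="highs")
    if res.status != 0:
        raise RuntimeError(f"inner LP failed ({context}): {res.message}")
    return res


def verify_inner_optimality(
    model: CommunityModel,
    env: EnvironmentSpec,
    cand: SteadyStateSolution,
    tol: float = 1e-6,
) -> float:
    """Re-solve the inner linear program(s) at the candidate's outer variables.

    Returns the optimality gap (inner LP optimum minus the candidate's inner
    objective value), certifying inner optimality independently of any
    multipliers when the gap is <= ``tol``.  For agent modes the gap is the
    worst gap over species; for community modes it is the gap of the joint
    program.
    """
    growth = cand.growth_rates(model)
    if env.mode == "CA" or env.mode == "BA":
        C = cand.C if env.mode == "CA" else None
        gap = 0.0
        for i, sp in enumerate(model.species):
            A_ub, b_ub = _cap_rows_lp(sp, C)
            c = np.zeros(sp.n_nu)
            c[sp.growth_index] = -1.0
            res = _solve_lp(c, A_ub, b_ub, sp.S, np.zeros(sp.n_S),
                            [(None, None)] * sp.n_nu, f"{env.mode} species {sp.id}")
            gap = max(gap, -res.fun - growth[i])
        return max(gap, 0.0)

    ab = cand.abundances
    if env.objective == "sum_growth":
        w = (ab > SUPPORT_THRESHOLD).astype(float)
    else:
        w = np.asarray(ab, dtype=float)

    if env.mode == "CC":
        # joint LP over (nu, C) at fixed X
        n_nu = sum(sp.n_nu for sp in model.species)
        n = n_nu + model.n_C
        c = np.zeros(n)
        off = 0
        eq_rows, eq_rhs = [], []
        ub_rows, ub_rhs = [], []
        for i, sp in enumerate(model.species):
            c[off + sp.growth_index] = -w[i]
            Srow = np.zeros((sp.n_S, n))
            Srow[:, off : off + sp.n_nu] = sp.S
            eq_rows.append(Srow)
            eq_rhs.append(np.zeros(sp.n_S))
            A_ub, b_ub = _cap_rows_lp(sp, np.zeros(model.n_C))
            blk = np.zeros((A_ub.shape[0], n))
            blk[:, off : off + sp.n_nu] = A_ub
            r = 0
            for a_row, spec in enumerate(sp.b):
                for alpha, grad in spec.pieces:
                    blk[r, n_nu:] = -np.asarray(grad, dtype=float)
                    b_ub[r] = alpha
                    r += 1
            ub_rows.append(blk)
            ub_rhs.append(b_ub)
            off += sp.n_nu
        bal = np.zeros((model.n_C, n))
        for i, sp in enumerate(model.species):
            sl = slice(sum(s.n_nu for s in model.species[:i]),
                       sum(s.n_nu for s in model.species[: i + 1]))
            bal[:, sl] = -sp.T * ab[i]
        bal[:, n_nu:] -= float(env.D) * np.eye(model.n_C)
        eq_rows.append(bal)
        eq_rhs.append(-float(env.D) * env.C_in)
        bounds = [(None, None)] * n_nu + [(0, None)] * model.n_C
        res = _solve_lp(c, np.vstack(ub_rows), np.concatenate(ub_rhs),
                        np.vstack(eq_rows), np.concatenate(eq_rhs), bounds, "CC joint")
        cand_val = float(w @ growth)
        return max(-res.fun - cand_val, 0.0)

    # BC: joint LP over nu at fixed x
    n = sum(sp.n_nu for sp in model.species)
    c = np.zeros(n)
    eq_rows, eq_rhs, ub_rows, ub_rhs = [], [], [], []
    off = 0
    culture = np.zeros((model.n_C, n))
    for i, sp in enumerate(model.species):
        c[off + sp.growth_index] = -w[i]
        Srow = np.zeros((sp.n_S, n))
        Srow[:, off : off + sp.n_nu] = sp.S
        eq_rows.append(Srow)
        eq_rhs.append(np.zeros(sp.n_S))
        A_ub, b_ub = _cap_rows_lp(sp, None)
        blk = np.zeros((A_ub.shape[0], n))
        blk[:, off : off + sp.n_nu] = A_ub
        ub_rows.append(blk)
        ub_rhs.append(b_ub)
        culture[:, off : off + sp.n_nu] = sp.T * ab[i]
        off += sp.n_nu
    ub_rows.append(culture)
    ub_rhs.append(np.asarray(env.u, dtype=float))
    res = _solve_lp(c, np.vstack(ub_rows), np.concatenate(ub_rhs),
                    np.vstack(eq_rows), np.concatenate(eq_rhs),
                    [(None, None)] * n, "BC joint")
    cand_val = float(w @ growth)
    return max(-res.fun - cand_val, 0.0)
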