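"""Exact enumeration of all steady-state branches for small community models.

The steady-state systems are piecewise polynomial: once one decides, for
every inequality, whether it is active (slack q = 0, multiplier free) or
inactive (multiplier zero), and, for every species, whether it is absent or
growing at the dilution rate (community growth rate in batch), the remaining
system is square-ish and polynomial.  Enumerating all
``2^(n_inequalities + n_species)`` such branches therefore finds *every*
solution branch — the numerical replacement for solving the small models
symbolically.

Each branch is solved in two stages: the equations that are linear in the
primal unknowns (intracellular steady state, growth pinning, the tight
inequality rows) are solved exactly by least squares, and the remaining
bilinear abundance/balance block is solved over the resulting affine family
by a damped Newton iteration from one deterministic plus several seeded
starts.  Multipliers are then recovered by bounded least squares on the KKT
stationarity rows, and a branch root is kept only if the *full* system
residual is virtually zero and an independent inner-LP re-solve certifies
optimality.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy.optimize import linprog

from .formulations import (
    SUPPORT_THRESHOLD,
    AlgebraicSystem,
    assemble_system,
    recover_multipliers,
)
from .milp_stage import ComplementarityPattern
from .model_core import CommunityModel, EnvironmentSpec, SteadyStateSolution
from .refine_stage import RefinementSettings, accept, dedupe

__all__ = [
    "OracleSettings",
    "PatternBudgetExceeded",
    "enumerate_patterns",
    "solve_pattern",
    "enumerate_solutions",
]

_TIGHT_TOL = 1e-7
_ROOT_TOL = 1e-10


class PatternBudgetExceeded(ValueError):
    """The model has too many complementarity branches for exhaustive search."""


@dataclass(frozen=True)
class OracleSettings:
    n_starts: int = 20
    seed: int = 0
    residual_threshold: float = 1e-8
    optimality_tol: float = 1e-6
    dedupe_tol: float = 1e-6
    max_patterns: int = 2**22


def enumerate_patterns(
    system: AlgebraicSystem, max_patterns: int = OracleSettings.max_patterns
) -> Iterator[ComplementarityPattern]:
    """Yield every complementarity x support branch of the system.

    Every inequality paired with a lam1 entry is either active (multiplier
    free) or inactive (multiplier zero), and every species is either absent
    or growth-pinned.  Raises :class:`PatternBudgetExceeded` when
    ``2^(n_lam1 + n_species)`` exceeds ``max_patterns`` — the signal to use
    the grid MILP stage instead.
    """
    n_q = len(system.q_rows)
    n_X = system.model.n_X
    if 2 ** (n_q + n_X) > max_patterns:
        raise PatternBudgetExceeded(
            f"2^({n_q}+{n_X}) patterns exceed the budget of {max_patterns}"
        )
    for support in itertools.product((False, True), repeat=n_X):
        for delta in itertools.product((False, True), repeat=n_q):
            yield ComplementarityPattern(delta=delta, support=support)


class _PatternSolver:
    """Shared per-system machinery for solving individual branches."""

    def __init__(self, system: AlgebraicSystem, settings: OracleSettings):
        self.system = system
        self.settings = settings
        self.model = system.model
        self.env = system.env
        self.chem = system.env.is_chemostat
        self.rng = np.random.default_rng(settings.seed)
        self._support_cache: dict[tuple, dict] = {}
        self._species_cache: dict[tuple, dict] = {}
        self._seen_roots: set = set()
        self._seen_families: set = set()

    # -- per-support precomputation ---------------------------------------

    def _prep(self, support: tuple[bool, ...]) -> dict:
        if support in self._support_cache:
            return self._support_cache[support]
        model = self.model
        act = [i for i, s in enumerate(support) if s]
        w_slices: dict[int, slice] = {}
        off = 0
        for i in act:
            w_slices[i] = slice(off, off + model.species[i].n_nu)
            off += model.species[i].n_nu
        tail_dim = model.n_C if self.chem else 1
        tail = slice(off, off + tail_dim)  # C (chemostat) or mu_star (batch)
        off += tail_dim
        cnn_rows: dict[int, int] = {}
        culture_compounds: dict[int, int] = {}
        for j, q in enumerate(self.system.q_rows):
            if q.kind == "Cnn":
                cnn_rows[j] = q.compound
            elif q.kind == "culture":
                culture_compounds[j] = q.compound
        prep = dict(
            act=act, w_slices=w_slices, tail=tail, tail_dim=tail_dim, n_w=off,
            cnn_rows=cnn_rows, culture_compounds=culture_compounds,
        )
        self._support_cache[support] = prep
        return prep

    def _species_block(self, i: int, tight: tuple[int, ...]) -> dict:
        """Eliminate species i's fluxes under a fixed tight-row set.

        Solves ``E nu_i = f0 + F tail`` (intracellular steady state, growth
        pinning, tight capacity rows; ``tail`` is C in chemostat, mu* in
        batch), returning the affine parametrization
        ``nu_i = P0 + PC tail + Nnu s`` together with the induced consistency
        constraints ``G tail = h`` on the shared tail variables.
        """
        key = (i, tight)
        hit = self._species_cache.get(key)
        if hit is not None:
            return hit
        sp = self.model.species[i]
        tail_dim = self.model.n_C if self.chem else 1
        rows = [sp.S]
        f0 = [np.zeros(sp.n_S)]
        F = [np.zeros((sp.n_S, tail_dim))]
        grow = np.zeros(sp.n_nu)
        grow[sp.growth_index] = 1.0
        rows.append(grow[None, :])
        if self.chem:
            f0.append(np.array([float(self.env.D)]))
            F.append(np.zeros((1, tail_dim)))
        else:
            f0.append(np.zeros(1))
            F.append(np.ones((1, 1)))  # nu_mu = mu*
        for j in tight:
            q = self.system.q_rows[j]
            rows.append(sp.A[q.a_row][None, :])
            f0.append(np.array([q.intercept]))
            F.append(q.gradient[None, :] if self.chem else np.zeros((1, 1)))
        E = np.vstack(rows)
        f0 = np.concatenate(f0)
        F = np.vstack(F)
        U, s, Vt = np.linalg.svd(E, full_matrices=True)
        r = int(np.sum(s > (s[0] if s.size else 0.0) * 1e-11))
        pinv = Vt[:r].T * (1.0 / s[:r]) @ U[:, :r].T if r else np.zeros((sp.n_nu, E.shape[0]))
        U2 = U[:, r:]
        G = U2.T @ F
        h = -U2.T @ f0
        if G.shape[0]:
            tail_sol, *_ = np.linalg.lstsq(G, h, rcond=None)
            feasible = bool(
                np.max(np.abs(G @ tail_sol - h), initial=0.0)
                <= 1e-9 * max(1.0, float(np.abs(h).max(initial=0.0)))
            )
        else:
            feasible = True
        P0 = pinv @ f0
        PC = pinv @ F
        Nnu = Vt[r:].T
        # canonical signature of the induced solution family: subsets that only
        # add redundant rows produce identical branches and are solved once
        if G.shape[0]:
            Ug, sg, Vgt = np.linalg.svd(G, full_matrices=False)
            rg = int(np.sum(sg > (sg[0] if sg.size else 0.0) * 1e-11))
            PG = Vgt[:rg].T @ Vgt[:rg]
            hmin = Vgt[:rg].T @ ((Ug[:, :rg].T @ h) / sg[:rg]) if rg else np.zeros(G.shape[1])
        else:
            PG = np.zeros((G.shape[1], G.shape[1]))
            hmin = np.zeros(G.shape[1])
        sig = (
            np.round(P0, 8).tobytes() + np.round(PC, 8).tobytes()
            + np.round(Nnu @ Nnu.T, 8).tobytes() + np.round(PG, 8).tobytes()
            + np.round(hmin, 8).tobytes() + bytes([feasible])
        )
        blk = dict(P0=P0, PC=PC, Nnu=Nnu, G=G, h=h, feasible=feasible, sig=sig)
        self._species_cache[key] = blk
        return blk

    # -- stage 2: bilinear abundance/balance block -------------------------

    def _stage2(self, prep, w0, N, tight_cultures):
        """Solve the remaining bilinear block; returns list of (w, ab) roots."""
        model, env = self.model, self.env
        act = prep["act"]
        d = N.shape[1]
        n_ab = len(act)

        # per-active-species exchange affine maps: T_i nu_i = a_i + B_i t
        # stacked: M(t) = A_mat + BT . t of shape (n_eq_rows, n_ab)
        if self.chem:
            D = float(env.D)
            n_eq = model.n_C
            A_mat = np.zeros((n_eq, n_ab))
            BT = np.zeros((n_eq, n_ab, d))
            for k, i in enumerate(act):
                sp = model.species[i]
                sl = prep["w_slices"][i]
                A_mat[:, k] = sp.T @ w0[sl]
                BT[:, k, :] = sp.T @ N[sl]
            r0 = D * (np.asarray(env.C_in) - w0[prep["tail"]])
            Et = -D * N[prep["tail"]]
            sign = -1.0  # R = r0 + Et t - M(t) ab
        else:
            rows = sorted(tight_cultures)
            comps = [self.system.q_rows[j].compound for j in rows]
            n_eq = len(rows) + 1
            A_mat = np.zeros((len(rows), n_ab))
            BT = np.zeros((len(rows), n_ab, d))
            for k, i in enumerate(act):
                sp = model.species[i]
                sl = prep["w_slices"][i]
                Texch = sp.T[comps] if comps else np.zeros((0, sp.n_nu))
                A_mat[:, k] = Texch @ w0[sl]
                BT[:, k, :] = Texch @ N[sl]
            r0 = -np.asarray([float(env.u[c]) for c in comps])
            Et = np.zeros((len(rows), d))
            sign = 1.0  # R_rows = r0 + Et t + M(t) ab ; plus sum(ab) - 1

        n_y = d + n_ab
        BT2 = BT.transpose(0, 2, 1).reshape(nrow_bt := BT.shape[0] * d, n_ab) if d else None
        BTflat = BT.reshape(BT.shape[0] * n_ab, d)
        J = np.zeros((n_eq, n_y))
        if not self.chem:
            J[-1, d:] = 1.0

        def res_jac(y):
            t = y[:d]
            ab = y[d:]
            M = A_mat + (BTflat @ t).reshape(-1, n_ab) if (d and n_ab) else A_mat
            core = r0 + Et @ t + sign * (M @ ab)
            J[: core.size, :d] = Et
            if d:
                J[: core.size, :d] += sign * (BT2 @ ab).reshape(-1, d)
            J[: core.size, d:] = sign * M
            if self.chem:
                return core
            R = np.empty(n_eq)
            R[:-1] = core
            R[-1] = ab.sum() - 1.0
            return R

        eye_reg = 1e-13 * np.eye(n_y)

        def newton(y0):
            y = y0.copy()
            R = res_jac(y)
            nrm = float(np.abs(R).max()) if R.size else 0.0
            best_hist = nrm
            for it in range(40):
                if nrm < _ROOT_TOL:
                    return y
                # small, regularized normal-equation step (Gauss-Newton)
                g = J.T @ R
                H = J.T @ J + eye_reg
                try:
                    step = -np.linalg.solve(H, g)
                except np.linalg.LinAlgError:
                    return None
                alpha = 1.0
                for _ in range(10):
                    y_n = y + alpha * step
                    R_n = res_jac(y_n)
                    nrm_n = float(np.abs(R_n).max()) if R_n.size else 0.0
                    if nrm_n < nrm:
                        y, R, nrm = y_n, R_n, nrm_n
                        break
                    alpha *= 0.5
                else:
                    return None
                if it % 5 == 4:
                    if nrm > 0.1 * best_hist:  # stalling on an infeasible branch
                        return None
                    best_hist = nrm
            return y if nrm < _ROOT_TOL else None

        def center(y, y_ref):
            """Slide along the root manifold to the point nearest y_ref.

            Canonicalizes the deterministic representative of continuum
            branches; e.g. for species-exchange-symmetric systems it yields
            the symmetric member of a solution family.
            """
            for _ in range(12):
                res_jac(y)
                U, s, Vt = np.linalg.svd(J, full_matrices=True)
                r = int(np.sum(s > (s[0] if s.size else 0.0) * 1e-9))
                Nz = Vt[r:]
                if Nz.shape[0] == 0:
                    return y
                shift = Nz.T @ (Nz @ (y_ref - y))
                if float(np.abs(shift).max(initial=0.0)) < 1e-12:
                    return y
                cand = newton(y + shift)
                if cand is None or np.linalg.norm(cand - y_ref) >= np.linalg.norm(y - y_ref) - 1e-14:
                    return y
                y = cand
            return y

        dof = n_y - n_eq
        roots = []
        y0 = np.concatenate([
            np.zeros(d), np.full(n_ab, 1.0 if self.chem else 1.0 / max(n_ab, 1))
        ])
        det = newton(y0)
        if det is not None:
            roots.append(det)
        # continuum branches get a few extra representatives; failed starts get
        # a small retry budget (isolated roots are pinned by maximal tight
        # sets, where the deterministic start converges)
        if det is not None:
            n_extra = min(2, self.settings.n_starts) if dof > 0 else 0
        else:
            n_extra = min(3, self.settings.n_starts)
        for _ in range(n_extra):
            t0 = self.rng.normal(0.0, 1.0, size=d)
            ab0 = np.abs(self.rng.normal(1.0, 1.0, size=n_ab))
            if not self.chem and n_ab:
                ab0 = ab0 / np.sum(ab0)
            r = newton(np.concatenate([t0, ab0]))
            if r is not None:
                roots.append(r)
        uniq = []
        for y in roots:
            if not any(np.max(np.abs(y - u)) <= 1e-8 for u in uniq):
                uniq.append(y)
        det_found = det is not None

        def center_to_ref(y):
            return center(y, y0)

        return uniq, center_to_ref, det_found, d

    # -- stage 3: KKT-pinned points inside underdetermined balance families --

    def _stage3(self, prep, w0, N, pattern, starts, obj_support):
        """Newton on the full branch system (balance + stationarity).

        A branch whose primal equations leave the balance block
        underdetermined can still contain isolated steady states: the KKT
        stationarity rows (which couple the multipliers to C and X) pin them.
        Unknowns are the family parameters, the active abundances, the
        branch's free inequality multipliers and all equality duals.
        """
        system, model, lay = self.system, self.model, self.system.layout
        act = prep["act"]
        d = N.shape[1]
        n_ab = len(act)
        eq, ineq = system.compiled(obj_support)

        eq_rows = []
        act_set = set(act)
        # locate stationarity rows of active species (+ C rows for CC)
        k = 0
        for kind, name in zip(system.eq_kinds, system.eq_names):
            if kind == "balance" and self.chem:
                eq_rows.append(k)
            if kind == "sumx":
                eq_rows.append(k)
            if kind == "stationarity":
                sp_id = name.split("[", 1)[1].split(":", 1)[0]
                if model.species_index(sp_id) in act_set:
                    eq_rows.append(k)
            if kind == "stationarity_C":
                eq_rows.append(k)
            k += 1
        ineq_rows = [
            j for j, on in enumerate(pattern.delta)
            if on and system.q_rows[j].kind == "culture"
        ]

        lam_cols = []
        for j, on in enumerate(pattern.delta):
            q = system.q_rows[j]
            if on and (q.kind != "cap" or q.species in act_set):
                lam_cols.append(lay.lam1.start + j)
        for i in act:
            off = self.system.lam2_S_offset[i]
            lam_cols.extend(range(off, off + model.species[i].n_S))
        if self.system.lam2_C_offset is not None:
            lam_cols.extend(
                range(self.system.lam2_C_offset, self.system.lam2_C_offset + model.n_C)
            )
        lam_cols = np.array(lam_cols, dtype=int)

        # dz/dv for v = (t, ab, lam_sel)
        n_v = d + n_ab + lam_cols.size
        Mv = np.zeros((lay.n, n_v))
        for i in act:
            Mv[lay.nu[i], :d] = N[prep["w_slices"][i]]
        if self.chem:
            Mv[lay.C, :d] = N[prep["tail"]]
            ab_rows = [lay.X.start + i for i in act]
        else:
            Mv[lay.mu_star, :d] = N[prep["tail"].start]
            ab_rows = [lay.x.start + i for i in act]
        for k2, i_row in enumerate(ab_rows):
            Mv[i_row, d + k2] = 1.0
        for k2, c in enumerate(lam_cols):
            Mv[c, d + n_ab + k2] = 1.0

        z_base = np.zeros(lay.n)

        def z_of(v):
            z = z_base.copy()
            z += Mv @ v
            for i in act:
                z[lay.nu[i]] += w0[prep["w_slices"][i]]
            if self.chem:
                z[lay.C] += w0[prep["tail"]]
            else:
                z[lay.mu_star] += w0[prep["tail"].start]
            return z

        def F_J(v):
            z = z_of(v)
            Fe = eq.value(z)[eq_rows]
            Je = eq.jacobian(z)[eq_rows]
            if ineq_rows:
                Fi = ineq.value(z)[ineq_rows]
                Ji = ineq.jacobian(z)[ineq_rows]
                Fe = np.concatenate([Fe, Fi])
                Je = np.vstack([Je, Ji])
            return Fe, Je @ Mv

        out = []
        reg = 1e-13 * np.eye(n_v)
        for y_start, lam_start in starts:
            v = np.concatenate([y_start, lam_start])
            F, J = F_J(v)
            nrm = float(np.abs(F).max(initial=0.0))
            best_hist = nrm
            for it in range(30):
                if nrm < _ROOT_TOL:
                    break
                try:
                    step = -np.linalg.solve(J.T @ J + reg, J.T @ F)
                except np.linalg.LinAlgError:
                    break
                alpha = 1.0
                improved = False
                for _ in range(10):
                    v_n = v + alpha * step
                    F_n, J_n = F_J(v_n)
                    nrm_n = float(np.abs(F_n).max(initial=0.0))
                    if nrm_n < nrm:
                        v, F, J, nrm = v_n, F_n, J_n, nrm_n
                        improved = True
                        break
                    alpha *= 0.5
                if not improved:
                    break
                if it % 5 == 4:
                    if nrm > 0.1 * best_hist:  # stalling: branch has no pinned root
                        break
                    best_hist = nrm
            if nrm < _ROOT_TOL:
                out.append(v[: d + n_ab])
        return out

    # -- flux fill-in and multiplier recovery ------------------------------

    def _argmax_fluxes(self, i: int, C) -> np.ndarray | None:
        """Per-species growth-maximal fluxes (feasible argmax) at fixed C."""
        sp = self.model.species[i]
        rows, rhs = [], []
        for a_row, spec in enumerate(sp.b):
            for alpha, grad in spec.pieces:
                rows.append(sp.A[a_row])
                rhs.append(alpha + (float(np.asarray(grad) @ C) if C is not None else 0.0))
        c = np.zeros(sp.n_nu)
        c[sp.growth_index] = -1.0
        res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), A_eq=sp.S,
                      b_eq=np.zeros(sp.n_S), bounds=[(None, None)] * sp.n_nu,
                      method="highs")
        return res.x if res.status == 0 else None

    def _recover_multipliers(self, z: np.ndarray, support) -> None:
        recover_multipliers(self.system, z, support, tight_tol=_TIGHT_TOL)

    # -- branch solve ------------------------------------------------------

    def solve(self, pattern: ComplementarityPattern) -> list[SteadyStateSolution]:
        system, model = self.system, self.model
        support = tuple(bool(s) for s in pattern.support)
        if not self.chem and not any(support):
            return []  # relative abundances must sum to one
        prep = self._prep(support)
        n_w = prep["n_w"]
        tail_dim = prep["tail_dim"]

        # sort the active rows of the pattern: per-species tight capacity
        # rows, tight C >= 0 rows, tight culture rows.  Active rows of absent
        # species impose nothing on the reduced primal; their multipliers are
        # recovered post hoc.
        per_species: dict[int, list[int]] = {i: [] for i in prep["act"]}
        tight_cnn, tight_cultures = [], set()
        for j, on in enumerate(pattern.delta):
            if not on:
                continue
            q = system.q_rows[j]
            if q.kind == "cap" and q.species in per_species:
                per_species[q.species].append(j)
            elif q.kind == "Cnn":
                tight_cnn.append(q.compound)
            elif q.kind == "culture":
                tight_cultures.add(j)

        # stage 1: eliminate each species' fluxes, then solve the induced
        # constraints on the shared tail (C, resp. mu*) — a tiny least squares
        blocks = {i: self._species_block(i, tuple(per_species[i])) for i in prep["act"]}
        if any(not blocks[i]["feasible"] for i in prep["act"]):
            return []
        Gs = [blocks[i]["G"] for i in prep["act"]]
        hs = [blocks[i]["h"] for i in prep["act"]]
        for c in tight_cnn:
            row = np.zeros((1, tail_dim))
            row[0, c] = 1.0
            Gs.append(row)
            hs.append(np.zeros(1))
        if Gs:
            G = np.vstack(Gs)
            h = np.concatenate(hs)
        else:
            G = np.zeros((0, tail_dim))
            h = np.zeros(0)
        if G.shape[0]:
            U, s, Vt = np.linalg.svd(G, full_matrices=True)
            r = int(np.sum(s > max(s[0] if s.size else 0.0, 1.0) * 1e-11))
            coef = (U[:, :r].T @ h) / s[:r] if r else np.zeros(0)
            tail0 = Vt[:r].T @ coef
            if r < G.shape[0]:
                resid = h - G @ tail0
                if float(np.abs(resid).max()) > 1e-8 * max(1.0, float(np.abs(h).max(initial=0.0))):
                    return []
            Ntail = Vt[r:].T
        else:
            tail0 = np.zeros(tail_dim)
            Ntail = np.eye(tail_dim)

        # assemble the joint affine family w = w0 + N p over parameters
        # p = (tau, s_1, ..., s_k)
        d_tau = Ntail.shape[1]
        d = d_tau + sum(blocks[i]["Nnu"].shape[1] for i in prep["act"])
        w0 = np.zeros(n_w)
        N = np.zeros((n_w, d))
        w0[prep["tail"]] = tail0
        N[prep["tail"], :d_tau] = Ntail
        off = d_tau
        for i in prep["act"]:
            blk = blocks[i]
            sl = prep["w_slices"][i]
            w0[sl] = blk["P0"] + blk["PC"] @ tail0
            N[sl, :d_tau] = blk["PC"] @ Ntail
            ds = blk["Nnu"].shape[1]
            N[sl, off : off + ds] = blk["Nnu"]
            off += ds

        # skip branches whose primal family duplicates an already-solved one
        # (patterns that only add redundant tight rows)
        cultures_key = tuple(sorted(tight_cultures))
        if d:
            Q, _ = np.linalg.qr(N, mode="reduced")
            w0c = w0 - Q @ (Q.T @ w0)
            fam_key = (support, cultures_key, np.round(w0c, 8).tobytes(),
                       np.round(Q @ Q.T, 8).tobytes())
        else:
            fam_key = (support, cultures_key, np.round(w0, 8).tobytes(), b"")
        if fam_key in self._seen_families:
            return []
        self._seen_families.add(fam_key)

        roots, center_fn, det_found, d2 = self._stage2(prep, w0, N, tight_cultures)
        lay = system.layout
        obj_support = support if system.objective == "sum_growth" else None

        def build(y):
            """Assemble and score a full candidate from a stage-2 root."""
            ab = np.where(np.abs(y[d2:]) < 1e-12, 0.0, y[d2:])
            if np.any(ab < 0):
                return None
            w = w0 + N @ y[:d2]
            # identical primal roots recur across many branches; process once
            key = (support, np.round(np.concatenate([ab, w]) * 1e8).astype(np.int64).tobytes())
            if key in self._seen_roots:
                return None
            self._seen_roots.add(key)
            z = np.zeros(lay.n)
            for i in prep["act"]:
                z[lay.nu[i]] = w[prep["w_slices"][i]]
            if self.chem:
                C = w[prep["tail"]]
                if np.any(C < -1e-9):
                    return None
                z[lay.C] = np.maximum(C, 0.0)
                z[lay.X] = 0.0
                z[lay.X.start + np.array(prep["act"], dtype=int)] = ab
            else:
                z[lay.x] = 0.0
                z[lay.x.start + np.array(prep["act"], dtype=int)] = ab
                z[lay.mu_star] = w[prep["tail"].start]
            for i in range(model.n_X):
                if i in prep["act"]:
                    continue
                if self.chem or self.env.mode == "BA":
                    fill = self._argmax_fluxes(i, z[lay.C] if self.chem else None)
                    if fill is None:
                        return None
                    z[lay.nu[i]] = fill
                else:
                    z[lay.nu[i]] = 0.0  # zero is feasible and carries zero weight
            self._recover_multipliers(z, obj_support)
            return z, system.residual_max_z(z, obj_support)

        sols = []
        thr = self.settings.residual_threshold
        any_passed = False
        for idx, y in enumerate(roots):
            out = build(y)
            if out is None:
                continue
            z, rmax = out
            if rmax < thr and idx == 0 and det_found:
                # canonicalize the deterministic representative of a continuum
                # (e.g. the symmetric member of a symmetric solution family)
                yc = center_fn(y)
                if np.max(np.abs(yc - y), initial=0.0) > 1e-10:
                    out_c = build(yc)
                    if out_c is not None and out_c[1] < thr:
                        z, rmax = out_c
            if rmax < thr:
                any_passed = True
                sols.append(system.z_to_solution(z, branch=pattern))

        # underdetermined balance families whose sampled roots all fail the
        # full system may still hide KKT-pinned isolated steady states
        n_act = len(prep["act"])
        n_eq2 = model.n_C if self.chem else len(tight_cultures) + 1
        if not any_passed and d2 + n_act - n_eq2 > 0:
            y0_det = np.concatenate([
                np.zeros(d2),
                np.full(n_act, 1.0 if self.chem else 1.0 / max(n_act, 1)),
            ])
            seeds = roots[:1] if roots else [y0_det]
            n_lam = self._stage3_n_lam(prep, pattern)
            starts = [(y, np.zeros(n_lam)) for y in seeds]
            for y in self._stage3(prep, w0, N, pattern, starts, obj_support):
                out = build(y)
                if out is not None and out[1] < thr:
                    sols.append(system.z_to_solution(out[0], branch=pattern))
        return sols

    def _stage3_n_lam(self, prep, pattern) -> int:
        act_set = set(prep["act"])
        n = 0
        for j, on in enumerate(pattern.delta):
            q = self.system.q_rows[j]
            if on and (q.kind != "cap" or q.species in act_set):
                n += 1
        n += sum(self.model.species[i].n_S for i in prep["act"])
        if self.system.lam2_C_offset is not None:
            n += self.model.n_C
        return n


def solve_pattern(
    system: AlgebraicSystem,
    pattern: ComplementarityPattern,
    n_starts: int = OracleSettings.n_starts,
    seed: int = 0,
) -> list[SteadyStateSolution]:
    """Solve one complementarity/support branch; empty list = infeasible branch."""
    solver = _PatternSolver(system, OracleSettings(n_starts=n_starts, seed=seed))
    return solver.solve(pattern)


def _growth_row_prunable(system: AlgebraicSystem, j: int) -> bool:
    """Capacity rows that pin the growth flux to a value != D can never be tight."""
    q = system.q_rows[j]
    if q.kind != "cap" or not system.env.is_chemostat:
        return False
    sp = system.model.species[q.species]
    row = sp.A[q.a_row]
    nz = np.nonzero(row)[0]
    if len(nz) != 1 or nz[0] != sp.growth_index:
        return False
    if np.any(q.gradient != 0.0):
        return False
    return abs(row[nz[0]] * float(system.env.D) - q.intercept) > 1e-12


def enumerate_solutions(
    model: CommunityModel,
    env: EnvironmentSpec,
    settings: OracleSettings = OracleSettings(),
) -> list[SteadyStateSolution]:
    """All steady-state branches of a small model, verified and deduplicated.

    Unions :func:`solve_pattern` over every complementarity/support branch,
    then applies the acceptance checks (residual below threshold, independent
    inner-LP optimality) and deduplication.  The trivial (washout) solution is
    always included for chemostat environments.  Raises
    :class:`PatternBudgetExceeded` when the branch count exceeds the budget.
    """
    system = assemble_system(model, env)
    n_q = len(system.q_rows)
    n_X = model.n_X
    if 2 ** (n_q + n_X) > settings.max_patterns:
        raise PatternBudgetExceeded(
            f"2^({n_q}+{n_X}) patterns exceed the budget of {settings.max_patterns}"
        )
    solver = _PatternSolver(system, settings)
    cands: list[SteadyStateSolution] = []
    for support in itertools.product((False, True), repeat=n_X):
        if not env.is_chemostat and not any(support):
            continue
        # per-species tight-row subsets, pre-filtered: subsets whose
        # species-level equations are infeasible for every C (mu*) value
        # cannot occur in any joint branch
        species_subsets: list[list[tuple[int, ...]]] = []
        active_ids = [i for i, s in enumerate(support) if s]
        for i in active_ids:
            rows_i = [
                j for j, q in enumerate(system.q_rows)
                if q.kind == "cap" and q.species == i and not _growth_row_prunable(system, j)
            ]
            feas, seen_sigs = [], set()
            for bits in itertools.product((False, True), repeat=len(rows_i)):
                subset = tuple(j for j, on in zip(rows_i, bits) if on)
                blk = solver._species_block(i, subset)
                if blk["feasible"] and blk["sig"] not in seen_sigs:
                    seen_sigs.add(blk["sig"])
                    feas.append(subset)
            species_subsets.append(feas)
        global_rows = [j for j, q in enumerate(system.q_rows) if q.kind != "cap"]
        for combo in itertools.product(*species_subsets):
            for gbits in itertools.product((False, True), repeat=len(global_rows)):
                delta = [False] * n_q
                for subset in combo:
                    for j in subset:
                        delta[j] = True
                for j, on in zip(global_rows, gbits):
                    delta[j] = on
                cands.extend(
                    solver.solve(ComplementarityPattern(tuple(delta), support))
                )
    uniq = dedupe(cands, settings.dedupe_tol)
    ref = RefinementSettings(
        threshold=settings.residual_threshold,
        optimality_tol=settings.optimality_tol,
        dedupe_tol=settings.dedupe_tol,
    )
    kept = accept(uniq, ref, model, env)
    kept.sort(key=lambda s: tuple(np.round(np.asarray(s.abundances), 9)))
    return kept
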