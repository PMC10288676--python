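"""Grid-of-abundances MILP stage for the chemostat steady-state systems.

Fixing the abundance vector X to a grid point makes every steady-state
equation linear except the complementary slackness products, which are
linearized with a binary vector Delta and a big-M constant Omega:

    0 <= lam_1 <= Omega * Delta,     -Omega * (1 - Delta) <= q <= 0

where q is the slack of the paired inequality (capacity row or -C).  The
equalities that contain the fixed X (chemostat mass balance and D-growth)
may be infeasible at an off-manifold grid point, so each receives a pair of
non-negative slack variables; the MILP minimizes the L1 sum of these slacks.
Grid points with (near-)zero minimal slack are steady-state candidates and
seed the Levenberg-Marquardt refinement stage.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.sparse import csr_matrix, hstack as sp_hstack

from .formulations import SUPPORT_THRESHOLD, AlgebraicSystem
from .model_core import CommunityModel, EnvironmentSpec, SteadyStateSolution

__all__ = [
    "ComplementarityPattern",
    "GridSpec",
    "GridResult",
    "MixedIntegerComplementarity",
    "choose_omega",
    "linearize_complementarity",
    "solve_at_point",
    "map_grid",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ComplementarityPattern:
    """One complementarity/support branch.

    ``delta[j]`` is True when inequality j is active (its multiplier may be
    positive and its slack q_j is zero); ``support[i]`` is True when species i
    is present (D-growth, resp. mu*-growth, instead of zero abundance).
    """

    delta: tuple[bool, ...]
    support: tuple[bool, ...]


@dataclass(frozen=True)
class GridSpec:
    """Linearly spaced abundance grid, ``points`` values per species axis."""

    lower: tuple[float, ...]
    upper: tuple[float, ...]
    points: int

    def __post_init__(self):
        if self.points < 1:
            raise ValueError("points per axis must be >= 1")
        lo, up = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != up.shape or not np.all(np.isfinite(lo)) or not np.all(np.isfinite(up)):
            raise ValueError("grid bounds must be finite and of equal length")
        if np.any(lo > up):
            raise ValueError("grid lower bounds must not exceed upper bounds")

    def axes(self) -> list[np.ndarray]:
        return [
            np.linspace(l, u, self.points)
            for l, u in zip(self.lower, self.upper)
        ]


@dataclass
class GridResult:
    point: np.ndarray
    slack: float
    candidate: SteadyStateSolution | None
    status: str  # optimal | time_limit | infeasible


@dataclass
class MixedIntegerComplementarity:
    """Linearized complementarity constraints over the stacked [z, Delta] vector.

    Per (lam1_j, q_j) pair exactly the four big-M inequalities are emitted;
    rows are expressed as ``lb <= A [z, Delta] <= ub``.  lam1 >= 0 lives in
    the variable bounds.
    """

    omega: float
    n_binary: int
    A: csr_matrix
    lb: np.ndarray
    ub: np.ndarray


def choose_omega(model: CommunityModel, env: EnvironmentSpec) -> float:
    """Conservative big-M constant for the linearized complementarity.

    Omega = 10 * max(max C_in, max |constant bound piece|, D * n_C * max C_in, 1),
    with a floor of 10.  Post-hoc: any accepted MILP solution with a
    multiplier or slack above 0.99 * Omega triggers a re-solve at 10 * Omega.
    """
    if not env.is_chemostat:
        raise ValueError("the grid MILP stage applies to chemostat modes only")
    cin_max = float(np.max(env.C_in)) if env.C_in.size else 0.0
    piece_max = 0.0
    for sp in model.species:
        for spec in sp.b:
            for alpha, _ in spec.pieces:
                piece_max = max(piece_max, abs(alpha))
    omega = 10.0 * max(cin_max, piece_max, float(env.D) * model.n_C * cin_max, 1.0)
    logger.info("big-M constant Omega = %g", omega)
    return omega


def linearize_complementarity(
    system: AlgebraicSystem, omega: float
) -> MixedIntegerComplementarity:
    """Emit the big-M rows for every (lam1, q) pair of a chemostat system."""
    if not system.env.is_chemostat:
        raise ValueError("complementarity linearization applies to chemostat systems")
    n_q = len(system.q_rows)
    n_z = system.layout.n
    eq, ineq = system.compiled((True,) * system.model.n_X)
    rows, lbs, ubs = [], [], []
    for j in range(n_q):
        qlin = ineq.L[j]  # q_j = c_j + L_j z  (affine for chemostat systems)
        qc = ineq.const[j]
        # q_j <= 0
        r = np.zeros(n_z + n_q)
        r[:n_z] = qlin
        rows.append(r)
        lbs.append(-np.inf)
        ubs.append(-qc)
        # q_j >= -Omega (1 - Delta_j)
        r = np.zeros(n_z + n_q)
        r[:n_z] = qlin
        r[n_z + j] = -omega
        rows.append(r)
        lbs.append(-qc - omega)
        ubs.append(np.inf)
        # lam_j <= Omega Delta_j   (lam_j >= 0 is a variable bound)
        r = np.zeros(n_z + n_q)
        r[system.layout.lam1.start + j] = 1.0
        r[n_z + j] = -omega
        rows.append(r)
        lbs.append(-np.inf)
        ubs.append(0.0)
    return MixedIntegerComplementarity(
        omega=omega,
        n_binary=n_q,
        A=csr_matrix(np.array(rows)),
        lb=np.array(lbs),
        ub=np.array(ubs),
    )


_STATUS = {0: "optimal", 1: "time_limit", 2: "infeasible", 3: "infeasible", 4: "infeasible"}


def solve_at_point(
    system: AlgebraicSystem,
    omega: float,
    fixed_abundances,
    time_limit: float = 60.0,
    _escalation: int = 0,
) -> GridResult:
    """Minimum-L1-slack MILP at one fixed abundance vector."""
    X = np.asarray(fixed_abundances, dtype=float)
    model = system.model
    if X.shape != (model.n_X,) or np.any(X < 0):
        raise ValueError("fixed_abundances must be a non-negative vector, one per species")
    lay = system.layout
    support = tuple(bool(v > SUPPORT_THRESHOLD) for v in X)
    eqset, ineqset = system.compiled(support)

    z_fix = np.zeros(lay.n)
    z_fix[lay.X] = X
    fixed_mask = np.zeros(lay.n, dtype=bool)
    fixed_mask[lay.X] = True

    keep = [k for k, kind in enumerate(system.eq_kinds) if kind != "complementarity"]
    slack_rows = [
        k for k, kind in enumerate(system.eq_kinds) if kind in ("balance", "dgrowth")
    ]
    Leq, ceq = eqset.substitute(z_fix, fixed_mask, rows=keep)

    n_z = lay.n
    n_q = len(system.q_rows)
    n_s = len(slack_rows)
    n_v = n_z + n_q + 2 * n_s

    cons = []
    # equalities (with +- slacks on the abundance-coupled rows)
    Aeq = np.zeros((len(keep), n_v))
    Aeq[:, :n_z] = Leq
    for s_idx, k in enumerate(slack_rows):
        pos = keep.index(k)
        Aeq[pos, n_z + n_q + s_idx] = 1.0
        Aeq[pos, n_z + n_q + n_s + s_idx] = -1.0
    beq = -ceq
    cons.append(LinearConstraint(csr_matrix(Aeq), beq, beq))

    mic = linearize_complementarity(system, omega)
    Amic = sp_hstack([mic.A, csr_matrix((mic.A.shape[0], 2 * n_s))]).tocsr()
    cons.append(LinearConstraint(Amic, mic.lb, mic.ub))

    lb = np.full(n_v, -np.inf)
    ub = np.full(n_v, np.inf)
    lb[lay.C] = 0.0
    lb[lay.X] = X
    ub[lay.X] = X
    lb[lay.lam1] = 0.0
    lb[n_z : n_z + n_q] = 0.0
    ub[n_z : n_z + n_q] = 1.0
    lb[n_z + n_q :] = 0.0
    integrality = np.zeros(n_v)
    integrality[n_z : n_z + n_q] = 1.0

    c = np.zeros(n_v)
    c[n_z + n_q :] = 1.0

    res = milp(
        c,
        constraints=cons,
        integrality=integrality,
        bounds=Bounds(lb, ub),
        options={"time_limit": float(time_limit), "disp": False},
    )
    status = _STATUS.get(res.status, "infeasible")
    if res.x is None:
        return GridResult(point=X, slack=np.inf, candidate=None, status=status)

    z = res.x[:n_z].copy()
    z[lay.X] = X
    delta = tuple(bool(d > 0.5) for d in np.round(res.x[n_z : n_z + n_q]))
    lam_mag = float(np.max(np.abs(z[lay.lam1]), initial=0.0))
    q_mag = float(np.max(np.abs(ineqset.value(z)[:n_q]), initial=0.0))
    if max(lam_mag, q_mag) > 0.99 * omega and _escalation < 3:
        logger.info(
            "multiplier/slack magnitude %.3g near Omega=%g; re-solving with 10x Omega",
            max(lam_mag, q_mag), omega,
        )
        return solve_at_point(system, 10.0 * omega, X, time_limit, _escalation + 1)
    cand = system.z_to_solution(z, branch=ComplementarityPattern(delta, support))
    return GridResult(point=X, slack=float(res.fun), candidate=cand, status=status)


def map_grid(
    system: AlgebraicSystem,
    omega: float,
    grid: GridSpec,
    time_limit: float = 60.0,
) -> list[GridResult]:
    """Solve the slack-minimization MILP at every grid point, row-major order."""
    axes = grid.axes()
    if len(axes) != system.model.n_X:
        raise ValueError("grid dimensionality must equal the number of species")
    results = []
    for point in itertools.product(*axes):
        results.append(solve_at_point(system, omega, np.array(point), time_limit))
    tallies: dict[str, int] = {}
    for r in results:
        tallies[r.status] = tallies.get(r.status, 0) + 1
    logger.info(
        "grid map: %d points (%d per axis), solver status tallies: %s",
        len(results), grid.points, tallies,
    )
    if tallies.get("time_limit"):
        logger.info(
            "%d grid points hit the MILP time limit; their incumbents are retained",
            tallies["time_limit"],
        )
    return results
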