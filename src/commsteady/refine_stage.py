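"""Least-squares refinement, acceptance filtering and deduplication.

Grid candidates are refined by minimizing the sum of squares of all
steady-state constraint violations with the Levenberg-Marquardt algorithm,
with the abundance variables released (candidates migrate off the grid).
The residual vector stacks all equality residuals, hinge terms
``max(0, violation)`` for the inequalities, and the multiplicative
complementarity products.  A candidate is accepted as a steady state when its
maximal constraint violation is virtually zero (< 1e-8 by default) *and* an
independent re-solve of the inner linear program certifies inner optimality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .formulations import AlgebraicSystem, recover_multipliers, verify_inner_optimality
from .model_core import CommunityModel, EnvironmentSpec, SteadyStateSolution

__all__ = ["RefinementSettings", "refine", "accept", "dedupe"]


@dataclass(frozen=True)
class RefinementSettings:
    """Numerical knobs of the refinement/acceptance pipeline."""

    threshold: float = 1e-8  # max constraint violation for feasibility
    max_nfev: int = 400
    ftol: float = 1e-15
    xtol: float = 1e-15
    gtol: float = 1e-15
    dedupe_tol: float = 1e-6
    optimality_tol: float = 1e-6

    def __post_init__(self):
        for name in ("threshold", "max_nfev", "ftol", "xtol", "gtol",
                     "dedupe_tol", "optimality_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def refine(
    system: AlgebraicSystem,
    start: SteadyStateSolution,
    settings: RefinementSettings = RefinementSettings(),
) -> SteadyStateSolution:
    """Levenberg-Marquardt refinement of one candidate; never increases ssq.

    All variables — fluxes, concentrations, abundances and multipliers — are
    free.  For the sum-of-growth objective the species support is frozen to
    the start candidate's support (branches are refined within their support).
    """
    z0 = system.solution_to_z(start)
    support = system.support_of_z(z0)
    if start.lam1 is None or not np.any(z0[system.layout.lam1] != 0.0):
        # a bare primal start (e.g. hand-entered values) gets its multipliers
        # initialized by least squares on the KKT stationarity rows
        recover_multipliers(system, z0, support if system.objective == "sum_growth" else None)
    r0 = system.residual_vector(z0, support)
    if not np.all(np.isfinite(r0)):
        raise ValueError("non-finite residual at the refinement start")

    method = "lm" if len(r0) >= len(z0) else "trf"
    res = least_squares(
        lambda z: system.residual_vector(z, support),
        z0,
        jac=lambda z: system.residual_jacobian(z, support),
        method=method,
        ftol=settings.ftol,
        xtol=settings.xtol,
        gtol=settings.gtol,
        max_nfev=settings.max_nfev,
    )
    ssq0 = float(r0 @ r0)
    z = res.x if float(res.fun @ res.fun) <= ssq0 else z0
    out = system.z_to_solution(z, branch=start.branch)
    return out


def accept(
    cands: list[SteadyStateSolution],
    settings: RefinementSettings,
    model: CommunityModel,
    env: EnvironmentSpec,
) -> list[SteadyStateSolution]:
    """Keep candidates that are feasible and certified inner-optimal.

    Feasibility: residual_max below ``settings.threshold``.  Optimality: the
    independently solved inner LP leaves a gap below
    ``settings.optimality_tol`` at the candidate's outer variables.
    """
    kept = []
    for cand in cands:
        if not np.isfinite(cand.residual_max) or cand.residual_max >= settings.threshold:
            continue
        gap = verify_inner_optimality(model, env, cand, tol=settings.optimality_tol)
        if gap < settings.optimality_tol:
            kept.append(cand)
    return kept


def _dedupe_key(sol: SteadyStateSolution) -> np.ndarray:
    parts = [np.atleast_1d(np.asarray(sol.abundances, dtype=float))]
    if sol.C is not None:
        parts.append(np.asarray(sol.C, dtype=float))
    if sol.mu_star is not None:
        parts.append(np.array([sol.mu_star]))
    return np.concatenate(parts)


def dedupe(sols: list[SteadyStateSolution], tol: float = 1e-6) -> list[SteadyStateSolution]:
    """Representatives of equivalence classes under inf-norm distance <= tol.

    Distances are measured in concatenated (abundance, C) space (abundance,
    mu* for batch); the representative of a class is its lowest-residual
    member.  Classes are formed greedily from the lowest-residual candidate
    outward, so near-duplicates always collapse onto the best root.
    """
    order = sorted(sols, key=lambda s: (s.residual_max, tuple(_dedupe_key(s))))
    kept: list[SteadyStateSolution] = []
    keys: list[np.ndarray] = []
    for sol in order:
        key = _dedupe_key(sol)
        if any(np.max(np.abs(key - k)) <= tol for k in keys):
            continue
        kept.append(sol)
        keys.append(key)
    return kept
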