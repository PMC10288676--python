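"""Domain types for microbial community steady-state models.

A community is a set of species-level constraint-based metabolic networks
that share one pool of extracellular compounds.  Each species ``i`` carries

* a stoichiometric matrix ``S_i`` (intracellular steady state ``S_i nu_i = 0``),
* capacity constraints ``A_i nu_i <= b_i(C)`` whose right-hand sides may be
  piecewise-linear concave functions of the extracellular concentrations ``C``
  (uptake kinetics), and
* an exchange map ``T_i`` such that ``(T_i nu_i)_c`` is the *net uptake* of
  extracellular compound ``c`` per unit biomass.

Environments come in four flavours, combining chemostat vs. steady-state
batch with rational-agent vs. rational-community decision making (modes
``CA``, ``CC``, ``BA``, ``BC``).  All quantities are in consistent arbitrary
units; no unit conversion is ever performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "MODES",
    "CHEMOSTAT_MODES",
    "BATCH_MODES",
    "AGENT_MODES",
    "COMMUNITY_MODES",
    "OBJECTIVES",
    "BoundSpec",
    "SpeciesNetwork",
    "CommunityModel",
    "EnvironmentSpec",
    "SteadyStateSolution",
    "validate_community",
    "evaluate_bounds",
    "net_exchange",
    "community_to_json",
    "community_from_json",
]

MODES = ("CA", "CC", "BA", "BC")
CHEMOSTAT_MODES = ("CA", "CC")
BATCH_MODES = ("BA", "BC")
AGENT_MODES = ("CA", "BA")
COMMUNITY_MODES = ("CC", "BC")
OBJECTIVES = ("biomass_production", "sum_growth")


@dataclass(frozen=True)
class BoundSpec:
    """Right-hand side of one capacity constraint row.

    The effective bound is ``min_p (intercept_p + gradient_p . C)`` over the
    pieces, i.e. a piecewise-linear concave function of the extracellular
    concentration vector.  A constant bound is a single piece with zero
    gradient.
    """

    pieces: tuple[tuple[float, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if len(self.pieces) == 0:
            raise ValueError("BoundSpec needs at least one affine piece")

    @staticmethod
    def constant(value: float, n_C: int) -> "BoundSpec":
        return BoundSpec(((float(value), (0.0,) * n_C),))

    @staticmethod
    def linear(gradient: Sequence[float], intercept: float = 0.0) -> "BoundSpec":
        return BoundSpec(((float(intercept), tuple(float(g) for g in gradient)),))

    @staticmethod
    def from_pieces(pieces: Iterable[tuple[float, Sequence[float]]]) -> "BoundSpec":
        return BoundSpec(tuple((float(a), tuple(float(g) for g in grad)) for a, grad in pieces))

    @property
    def is_constant(self) -> bool:
        return all(all(g == 0.0 for g in grad) for _, grad in self.pieces)

    @property
    def n_C(self) -> int:
        return len(self.pieces[0][1])

    def value(self, C: np.ndarray) -> float:
        C = np.asarray(C, dtype=float)
        vals = []
        for intercept, grad in self.pieces:
            g = np.asarray(grad, dtype=float)
            if g.shape != C.shape:
                raise ValueError(
                    f"BoundSpec gradient has length {g.size}, C has length {C.size}"
                )
            vals.append(intercept + float(g @ C))
        return min(vals)


@dataclass
class SpeciesNetwork:
    """One organism's metabolic network and its coupling to the environment."""

    id: str
    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray  # n_S x n_nu
    A: np.ndarray  # n_A x n_nu
    b: list[BoundSpec]  # length n_A
    T: np.ndarray  # n_C x n_nu, positive T @ nu = net uptake
    growth_index: int
    uptake_rows: tuple[int, ...] = ()  # rows of A allowed concentration-dependent bounds

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.uptake_rows = tuple(int(r) for r in self.uptake_rows)

    @property
    def n_nu(self) -> int:
        return self.S.shape[1]

    @property
    def n_S(self) -> int:
        return self.S.shape[0]

    @property
    def n_A(self) -> int:
        return self.A.shape[0]

    @property
    def n_C(self) -> int:
        return self.T.shape[0]


@dataclass
class CommunityModel:
    """Species sharing one extracellular compound index set."""

    species: list[SpeciesNetwork]
    extracellular_ids: list[str]

    @property
    def n_X(self) -> int:
        return len(self.species)

    @property
    def n_C(self) -> int:
        return len(self.extracellular_ids)

    def species_index(self, species_id: str) -> int:
        for i, sp in enumerate(self.species):
            if sp.id == species_id:
                return i
        raise KeyError(species_id)

    def has_concentration_dependent_bounds(self) -> bool:
        return any(not spec.is_constant for sp in self.species for spec in sp.b)


@dataclass
class EnvironmentSpec:
    """Cultivation environment and decision-making mode.

    Chemostat modes (CA, CC) carry a dilution rate ``D`` and inflow
    concentrations ``C_in``; batch modes (BA, BC) carry culture uptake bounds
    ``u``.  Community modes (CC, BC) additionally carry the inner objective:
    total biomass production ``sum_i nu_mu,i X_i`` (default) or the sum of
    growth rates over the supported species.
    """

    mode: str
    D: float | None = None
    C_in: np.ndarray | None = None
    u: np.ndarray | None = None
    objective: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.C_in is not None:
            self.C_in = np.asarray(self.C_in, dtype=float)
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
        if self.mode in CHEMOSTAT_MODES:
            if self.D is None or self.C_in is None:
                raise ValueError(f"{self.mode} requires D and C_in")
            if self.u is not None:
                raise ValueError(f"{self.mode} must not carry culture uptake bounds u")
            if self.D <= 0:
                raise ValueError("dilution rate D must be positive")
            if np.any(self.C_in < 0):
                raise ValueError("inflow concentrations C_in must be non-negative")
        else:
            if self.u is None:
                raise ValueError(f"{self.mode} requires culture uptake bounds u")
            if self.D is not None or self.C_in is not None:
                raise ValueError(f"{self.mode} must not carry D or C_in")
        if self.mode in AGENT_MODES:
            if self.objective is not None:
                raise ValueError(f"agent mode {self.mode} admits no community objective")
        else:
            if self.objective is None:
                self.objective = "biomass_production"
            if self.objective not in OBJECTIVES:
                raise ValueError(f"objective must be one of {OBJECTIVES}")

    @property
    def is_chemostat(self) -> bool:
        return self.mode in CHEMOSTAT_MODES

    def replace(self, **kw) -> "EnvironmentSpec":
        base = dict(
            mode=self.mode,
            D=self.D,
            C_in=None if self.C_in is None else self.C_in.copy(),
            u=None if self.u is None else self.u.copy(),
            objective=self.objective,
        )
        base.update(kw)
        return EnvironmentSpec(**base)


@dataclass
class SteadyStateSolution:
    """One candidate steady state with residual diagnostics.

    ``nu`` holds one flux vector per species.  Chemostat solutions carry
    absolute abundances ``X`` and concentrations ``C``; batch solutions carry
    relative abundances ``x`` and the community growth rate ``mu_star``.
    ``branch`` optionally records the complementarity pattern that produced
    the candidate.
    """

    nu: list[np.ndarray]
    C: np.ndarray | None = None
    X: np.ndarray | None = None
    x: np.ndarray | None = None
    mu_star: float | None = None
    lam1: np.ndarray | None = None
    lam2: np.ndarray | None = None
    residual_max: float = np.inf
    residual_ssq: float = np.inf
    branch: object | None = None

    @property
    def abundances(self) -> np.ndarray:
        ab = self.X if self.X is not None else self.x
        if ab is None:
            raise ValueError("solution carries no abundance vector")
        return ab

    def growth_rates(self, model: CommunityModel) -> np.ndarray:
        return np.array(
            [self.nu[i][sp.growth_index] for i, sp in enumerate(model.species)]
        )


# ---------------------------------------------------------------------------
# operations


def validate_community(model: CommunityModel) -> list[str]:
    """Check all type invariants; returns one diagnostic string per violation."""
    diags: list[str] = []
    n_C = model.n_C
    seen: set[str] = set()
    for sp in model.species:
        if sp.id in seen:
            diags.append(f"duplicate species id {sp.id!r}")
        seen.add(sp.id)
        n_nu = len(sp.reaction_ids)
        if sp.S.shape != (len(sp.metabolite_ids), n_nu):
            diags.append(
                f"species {sp.id}: S has shape {sp.S.shape}, expected "
                f"({len(sp.metabolite_ids)}, {n_nu})"
            )
        if sp.A.shape[1] != n_nu:
            diags.append(f"species {sp.id}: A has {sp.A.shape[1]} columns, expected {n_nu}")
        if len(sp.b) != sp.A.shape[0]:
            diags.append(
                f"species {sp.id}: {len(sp.b)} BoundSpecs for {sp.A.shape[0]} rows of A"
            )
        if sp.T.shape != (n_C, n_nu):
            diags.append(
                f"species {sp.id}: T has shape {sp.T.shape}, expected ({n_C}, {n_nu}) "
                "(row count must match the shared extracellular set)"
            )
        if not (0 <= sp.growth_index < n_nu):
            diags.append(
                f"species {sp.id}: growth_index {sp.growth_index} outside [0, {n_nu})"
            )
        for j, spec in enumerate(sp.b):
            if spec.n_C != n_C:
                diags.append(
                    f"species {sp.id}: BoundSpec {j} gradients have length {spec.n_C}, "
                    f"expected {n_C}"
                )
            if not spec.is_constant and j not in sp.uptake_rows:
                diags.append(
                    f"species {sp.id}: row {j} of A has a concentration-dependent bound "
                    "but is not flagged as an uptake constraint"
                )
        for r in sp.uptake_rows:
            if not (0 <= r < sp.A.shape[0]):
                diags.append(f"species {sp.id}: uptake row {r} outside [0, {sp.A.shape[0]})")
    return diags


def evaluate_bounds(b: Sequence[BoundSpec], C: np.ndarray) -> np.ndarray:
    """Evaluate piecewise-linear concave bounds at concentrations ``C``."""
    C = np.asarray(C, dtype=float)
    return np.array([spec.value(C) for spec in b])


def net_exchange(model: CommunityModel, sol: SteadyStateSolution) -> np.ndarray:
    """Per-species net metabolite exchange, secretion-positive, abundance-scaled.

    Entry ``(i, c)`` is ``-(T_i nu_i)_c * X_i`` (``x_i`` in batch): positive
    values are net secretion into the shared pool, negative values net uptake.
    Summing over species and adding ``D (C_in - C)`` recovers the chemostat
    stationarity residual of each compound.
    """
    ab = sol.abundances
    out = np.zeros((model.n_X, model.n_C))
    for i, sp in enumerate(model.species):
        nu_i = np.asarray(sol.nu[i], dtype=float)
        if nu_i.shape != (sp.n_nu,):
            raise ValueError(
                f"flux vector for species {sp.id} has shape {nu_i.shape}, expected ({sp.n_nu},)"
            )
        out[i] = -(sp.T @ nu_i) * ab[i]
    return out


# ---------------------------------------------------------------------------
# JSON serialization (schema: species[], dense row-major matrices, bound piece
# lists, extracellular_ids[])


def _species_to_dict(sp: SpeciesNetwork) -> dict:
    return {
        "id": sp.id,
        "metabolite_ids": list(sp.metabolite_ids),
        "reaction_ids": list(sp.reaction_ids),
        "S": sp.S.tolist(),
        "A": sp.A.tolist(),
        "b": [[[a, list(g)] for a, g in spec.pieces] for spec in sp.b],
        "T": sp.T.tolist(),
        "growth_index": sp.growth_index,
        "uptake_rows": list(sp.uptake_rows),
    }


def _species_from_dict(d: dict) -> SpeciesNetwork:
    return SpeciesNetwork(
        id=d["id"],
        metabolite_ids=list(d["metabolite_ids"]),
        reaction_ids=list(d["reaction_ids"]),
        S=np.asarray(d["S"], dtype=float),
        A=np.asarray(d["A"], dtype=float),
        b=[BoundSpec.from_pieces(pieces) for pieces in d["b"]],
        T=np.asarray(d["T"], dtype=float),
        growth_index=int(d["growth_index"]),
        uptake_rows=tuple(d.get("uptake_rows", ())),
    )


def community_to_json(model: CommunityModel, path=None) -> str:
    doc = {
        "extracellular_ids": list(model.extracellular_ids),
        "species": [_species_to_dict(sp) for sp in model.species],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def community_from_json(source) -> CommunityModel:
    if isinstance(source, str) and source.lstrip().startswith("{"):
        doc = json.loads(source)
    else:
        with open(source) as fh:
            doc = json.load(fh)
    return CommunityModel(
        species=[_species_from_dict(d) for d in doc["species"]],
        extracellular_ids=list(doc["extracellular_ids"]),
    )
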