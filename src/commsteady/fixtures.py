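"""Built-in example communities and environment sweep generators.

Two small hand-built consortia cover the qualitative regimes of interest:

* :func:`pd_network` — a metabolic prisoner's dilemma: two species share one
  energy source S and both need two biomass precursors A and B, but each
  species produces one of them at half the yield of the other.  Mutual
  crossfeeding maximizes community yield, refusing to secrete maximizes the
  individual's yield.
* :func:`coexistence_network` — two species competing for two supplied
  nutrients with mirrored stoichiometric demands; coexistence by differential
  nutrient limitation, with no capability to crossfeed at all.

:func:`auxotroph_pair_toy` is a small synthetic stand-in for an amino-acid
auxotrophic syntrophic pair (each strain lacks the synthesis route for one
required compound but can overproduce the partner's).  :func:`random_community`
provides seeded property-test inputs, and :func:`sweep_environments` builds
linear environment series.
"""

from __future__ import annotations

import numpy as np

from .model_core import BoundSpec, CommunityModel, EnvironmentSpec, SpeciesNetwork

__all__ = [
    "pd_network",
    "coexistence_network",
    "auxotroph_pair_toy",
    "random_community",
    "sweep_environments",
    "syntrophic_pair",
    "SyntrophicDataMissing",
]


def _unit_rows(entries, n_nu):
    """Rows of A with a single +-1 entry: (sign, reaction index) pairs."""
    A = np.zeros((len(entries), n_nu))
    for k, (sign, r) in enumerate(entries):
        A[k, r] = sign
    return A


def pd_network(uptake_bounds: str = "kinetic") -> CommunityModel:
    """Two-species prisoner's dilemma community.

    Each species has reactions (t_S, t_A, t_B, r_A, r_B, mu) over intracellular
    metabolites (S_c, A_c, B_c) and extracellular compounds (S, A, B).  Growth
    consumes one unit of A_c and one of B_c.  Species 1 makes A at low yield
    (r_A: 2 S_c -> A_c) and B at high yield (r_B: S_c -> B_c); species 2 is
    mirrored.  t_S is uptake-only; t_A and t_B are bidirectional so the
    species *can* crossfeed A and B.

    ``uptake_bounds``:
      * ``"kinetic"`` (default): uptake fluxes bounded by the matching
        extracellular concentration (nu_tS <= C_S etc.), the chemostat setting.
      * ``"unbounded"``: no uptake capacity rows, for steady-state batch where
        the culture uptake bounds u do the limiting.
    """
    if uptake_bounds not in ("kinetic", "unbounded"):
        raise ValueError("uptake_bounds must be 'kinetic' or 'unbounded'")
    reactions = ["t_S", "t_A", "t_B", "r_A", "r_B", "mu"]
    mets = ["S_c", "A_c", "B_c"]
    ext = ["S", "A", "B"]
    n_nu = len(reactions)
    T = np.zeros((3, n_nu))
    T[0, 0] = 1.0  # t_S
    T[1, 1] = 1.0  # t_A
    T[2, 2] = 1.0  # t_B

    def species(sid: str, yield_A: float, yield_B: float) -> SpeciesNetwork:
        S = np.zeros((3, n_nu))
        S[0, 0] = 1.0  # t_S -> S_c
        S[1, 1] = 1.0  # t_A -> A_c
        S[2, 2] = 1.0  # t_B -> B_c
        S[0, 3], S[1, 3] = -yield_A, 1.0  # r_A: yield_A S_c -> A_c
        S[0, 4], S[2, 4] = -yield_B, 1.0  # r_B: yield_B S_c -> B_c
        S[1, 5], S[2, 5] = -1.0, -1.0  # mu: A_c + B_c -> biomass
        irrev = [(-1.0, 0), (-1.0, 3), (-1.0, 4), (-1.0, 5)]  # t_S, r_A, r_B, mu >= 0
        if uptake_bounds == "kinetic":
            A = np.vstack([_unit_rows([(1.0, 0), (1.0, 1), (1.0, 2)], n_nu),
                           _unit_rows(irrev, n_nu)])
            b = [
                BoundSpec.linear([1.0, 0.0, 0.0]),  # nu_tS <= C_S
                BoundSpec.linear([0.0, 1.0, 0.0]),  # nu_tA <= C_A
                BoundSpec.linear([0.0, 0.0, 1.0]),  # nu_tB <= C_B
            ] + [BoundSpec.constant(0.0, 3)] * 4
            uptake_rows = (0, 1, 2)
        else:
            A = _unit_rows(irrev, n_nu)
            b = [BoundSpec.constant(0.0, 3)] * 4
            uptake_rows = ()
        return SpeciesNetwork(
            id=sid, metabolite_ids=list(mets), reaction_ids=list(reactions),
            S=S, A=A, b=b, T=T.copy(), growth_index=5, uptake_rows=uptake_rows,
        )

    return CommunityModel(
        species=[species("sp1", 2.0, 1.0), species("sp2", 1.0, 2.0)],
        extracellular_ids=list(ext),
    )


def coexistence_network(
    a1: float = 2.0,
    b1: float = 1.0,
    a2: float = 1.0,
    b2: float = 2.0,
    uptake_bounds: str = "kinetic",
    kinetic_slope: float = 2.0,
    constant_cap: float = 2.0,
) -> CommunityModel:
    """Two species needing both supplied compounds A and B, in mirrored ratios.

    Growth of species i consumes ``a_i`` units of A_c and ``b_i`` of B_c;
    species 1 needs more A (a1 > b1) and species 2 more B (b2 > a2).  Both
    transports are uptake-only, so crossfeeding is impossible.  Kinetic
    bounds are ``nu_t <= kinetic_slope * C`` (chemostat); ``"constant"``
    bounds cap each uptake at ``constant_cap`` (steady-state batch).
    """
    if not (a1 > b1 >= 0 and b2 > a2 >= 0):
        raise ValueError("need a1 > b1 >= 0 and b2 > a2 >= 0")
    if uptake_bounds not in ("kinetic", "constant"):
        raise ValueError("uptake_bounds must be 'kinetic' or 'constant'")
    reactions = ["t_A", "t_B", "mu"]
    n_nu = 3
    T = np.zeros((2, n_nu))
    T[0, 0] = 1.0
    T[1, 1] = 1.0

    def species(sid: str, a: float, b: float) -> SpeciesNetwork:
        S = np.zeros((2, n_nu))
        S[0, 0] = 1.0
        S[1, 1] = 1.0
        S[0, 2], S[1, 2] = -a, -b
        A = np.vstack([
            _unit_rows([(1.0, 0), (1.0, 1)], n_nu),
            _unit_rows([(-1.0, 0), (-1.0, 1), (-1.0, 2)], n_nu),
        ])
        if uptake_bounds == "kinetic":
            caps = [BoundSpec.linear([kinetic_slope, 0.0]),
                    BoundSpec.linear([0.0, kinetic_slope])]
            uptake_rows = (0, 1)
        else:
            caps = [BoundSpec.constant(constant_cap, 2)] * 2
            uptake_rows = ()
        b_specs = caps + [BoundSpec.constant(0.0, 2)] * 3
        return SpeciesNetwork(
            id=sid, metabolite_ids=["A_c", "B_c"], reaction_ids=list(reactions),
            S=S, A=A, b=b_specs, T=T.copy(), growth_index=2, uptake_rows=uptake_rows,
        )

    return CommunityModel(
        species=[species("sp1", a1, b1), species("sp2", a2, b2)],
        extracellular_ids=["A", "B"],
    )


def auxotroph_pair_toy(
    D: float = 0.5,
    C_in_energy: float = 10.0,
    C_in_amino: float = 2.0,
) -> tuple[CommunityModel, EnvironmentSpec]:
    """Synthetic auxotrophic pair: mutual amino-acid dependence, energy excess.

    A deliberately small, hand-built community (not derived from any published
    genome-scale model) with the structure of an amino-acid syntrophic pair:
    strain ``aux_A`` cannot synthesize compound A and must take it up, but can
    overproduce B from the energy source G; strain ``aux_B`` is mirrored.
    Growth consumes one unit each of G_c, A_c, B_c.  With G supplied in
    excess, growth is limited by the crossfed compounds, which leaves the
    strains free degrees of freedom in allocating G — the setting in which a
    band of rational-agent coexistence states appears.
    """
    reactions_1 = ["t_G", "t_A", "t_B", "r_B", "mu"]
    reactions_2 = ["t_G", "t_A", "t_B", "r_A", "mu"]
    ext = ["G", "A", "B"]
    n_nu = 5
    T = np.zeros((3, n_nu))
    T[0, 0] = 1.0
    T[1, 1] = 1.0
    T[2, 2] = 1.0

    def species(sid: str, makes: str) -> SpeciesNetwork:
        S = np.zeros((3, n_nu))
        S[0, 0] = 1.0  # t_G -> G_c
        S[1, 1] = 1.0  # t_A -> A_c
        S[2, 2] = 1.0  # t_B -> B_c
        if makes == "B":
            S[0, 3], S[2, 3] = -1.0, 1.0  # r_B: G_c -> B_c
        else:
            S[0, 3], S[1, 3] = -1.0, 1.0  # r_A: G_c -> A_c
        S[0, 4], S[1, 4], S[2, 4] = -1.0, -1.0, -1.0  # mu: G_c + A_c + B_c
        A = np.vstack([
            _unit_rows([(1.0, 0), (1.0, 1), (1.0, 2)], n_nu),
            _unit_rows([(-1.0, 0), (-1.0, 3), (-1.0, 4)], n_nu),
        ])
        b = [
            BoundSpec.linear([1.0, 0.0, 0.0]),
            BoundSpec.linear([0.0, 1.0, 0.0]),
            BoundSpec.linear([0.0, 0.0, 1.0]),
        ] + [BoundSpec.constant(0.0, 3)] * 3
        return SpeciesNetwork(
            id=sid,
            metabolite_ids=["G_c", "A_c", "B_c"],
            reaction_ids=list(reactions_1 if makes == "B" else reactions_2),
            S=S, A=A, b=b, T=T.copy(), growth_index=4, uptake_rows=(0, 1, 2),
        )

    model = CommunityModel(
        species=[species("aux_A", "B"), species("aux_B", "A")],
        extracellular_ids=list(ext),
    )
    env = EnvironmentSpec(
        mode="CA", D=D, C_in=np.array([C_in_energy, C_in_amino, C_in_amino])
    )
    return model, env


def random_community(
    seed: int, n_species: int = 2, n_internal: int = 3, n_exchange: int = 2
) -> CommunityModel:
    """Seeded random community for property tests.

    Every species gets one uptake transport per exchanged compound, a chain
    of conversion reactions across its internal metabolites, and a growth
    reaction consuming the end of the chain, so growth is always reachable
    from the exchanged compounds (S nu = 0 has a nonzero feasible cone).
    Uptake bounds are kinetic (nu_t <= C).
    """
    if min(n_species, n_internal, n_exchange) < 1:
        raise ValueError("all sizes must be >= 1")
    rng = np.random.default_rng(seed)
    ext = [f"E{c}" for c in range(n_exchange)]

    def species(si: int) -> SpeciesNetwork:
        mets = [f"M{k}" for k in range(n_internal)]
        rxns = [f"t{c}" for c in range(n_exchange)]
        rxns += [f"conv{k}" for k in range(n_internal - 1)]
        rxns += ["mu"]
        n_nu = len(rxns)
        S = np.zeros((n_internal, n_nu))
        T = np.zeros((n_exchange, n_nu))
        for c in range(n_exchange):
            S[c % n_internal, c] = 1.0
            T[c, c] = 1.0
        for k in range(n_internal - 1):
            r = n_exchange + k
            S[k, r] = -float(rng.integers(1, 3))
            S[k + 1, r] += 1.0
        g = n_nu - 1
        S[n_internal - 1, g] = -float(rng.integers(1, 3))
        if n_internal > 1 and rng.random() < 0.5:
            S[0, g] -= 1.0
        A = np.vstack([
            _unit_rows([(1.0, c) for c in range(n_exchange)], n_nu),
            _unit_rows([(-1.0, r) for r in range(n_nu)], n_nu),
        ])
        b = [BoundSpec.linear(np.eye(n_exchange)[c]) for c in range(n_exchange)]
        b += [BoundSpec.constant(0.0, n_exchange)] * n_nu
        return SpeciesNetwork(
            id=f"sp{si}", metabolite_ids=mets, reaction_ids=rxns,
            S=S, A=A, b=b, T=T, growth_index=g,
            uptake_rows=tuple(range(n_exchange)),
        )

    return CommunityModel(
        species=[species(i) for i in range(n_species)], extracellular_ids=ext
    )


def sweep_environments(
    base_env: EnvironmentSpec,
    start_vector,
    end_vector,
    n: int,
) -> list[EnvironmentSpec]:
    """Linearly interpolate the environment's supply vector, endpoints inclusive.

    For chemostat environments the inflow concentrations ``C_in`` are swept,
    for batch environments the culture uptake bounds ``u``; all other fields
    are copied unchanged.
    """
    if n < 2:
        raise ValueError("need n >= 2 sweep points")
    start = np.asarray(start_vector, dtype=float)
    end = np.asarray(end_vector, dtype=float)
    ref = base_env.C_in if base_env.is_chemostat else base_env.u
    if start.shape != ref.shape or end.shape != ref.shape:
        raise ValueError("sweep endpoints must match the environment vector length")
    out = []
    for t in np.linspace(0.0, 1.0, n):
        vec = (1.0 - t) * start + t * end
        if base_env.is_chemostat:
            out.append(base_env.replace(C_in=vec))
        else:
            out.append(base_env.replace(u=vec))
    return out


class SyntrophicDataMissing(FileNotFoundError):
    """Raised when the genome-scale SBML input for the syntrophic pair is absent."""


_SYNTROPHIC_REQUIRED = (
    "alanine_synthesis",
    "knockouts",
    "C_in",
    "uptake_kinetics",
    "D",
)


def syntrophic_pair(sbml_path, params: dict) -> tuple[CommunityModel, EnvironmentSpec]:
    """Two amino-acid auxotrophic strains derived from one SBML core model.

    Builds an alanine/glutamine syntrophic pair from a core *E. coli* SBML
    model: alanine and its synthesis from glutamate are added, then one strain
    loses the alanine route (``ala-aux``) and the other the glutamine route
    (``gln-aux``).  ``params`` must supply:

    * ``alanine_synthesis`` — stoichiometry dict for the added reaction,
    * ``knockouts`` — mapping strain id -> list of reaction ids to remove,
    * ``C_in`` — inflow concentration per extracellular compound id,
    * ``uptake_kinetics`` — mapping exchange compound id -> list of affine
      pieces ``(intercept, slope)`` for the concave uptake bound,
    * ``D`` — dilution rate (0.1 in the chemostat case study).

    Raises :class:`SyntrophicDataMissing` when the SBML file is unavailable
    (an explicit skip signal: nothing is downloaded) and ``KeyError`` naming
    the first missing parameter field.
    """
    import os

    for key in _SYNTROPHIC_REQUIRED:
        if key not in params:
            raise KeyError(f"syntrophic_pair params missing required field {key!r}")
    if not os.path.exists(str(sbml_path)):
        raise SyntrophicDataMissing(
            f"SBML model not found at {sbml_path!r}; the syntrophic case study "
            "requires a locally provided core-model file"
        )
    from .io_cli import build_syntrophic_community

    return build_syntrophic_community(sbml_path, params)
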