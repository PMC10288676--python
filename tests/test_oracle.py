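import numpy as np
import pytest

import commsteady as cs
from commsteady.active_set_oracle import PatternBudgetExceeded, enumerate_patterns, solve_pattern
from commsteady.milp_stage import ComplementarityPattern
from commsteady.model_core import BoundSpec, CommunityModel, SpeciesNetwork

from conftest import nearest

SQRT15 = np.sqrt(15.0)


def _unconstrained_single_species():
    """One species, no capacity rows: branch space is the support alone."""
    S = np.array([[1.0, -1.0]])
    sp = SpeciesNetwork(
        id="solo", metabolite_ids=["M"], reaction_ids=["t", "mu"],
        S=S, A=np.zeros((0, 2)), b=[], T=np.array([[1.0, 0.0]]), growth_index=1,
    )
    return CommunityModel(species=[sp], extracellular_ids=["E"])


class TestPatternEnumeration:
    def test_species_without_inequalities_have_two_branches(self):
        m = _unconstrained_single_species()
        env = cs.EnvironmentSpec(mode="CA", D=0.5, C_in=np.array([1.0]))
        system = cs.AlgebraicSystem(m, env)
        assert len(list(enumerate_patterns(system))) == 2

    def test_pd_ca_branch_count(self, pd_model, pd_env_ca):
        system = cs.assemble_system(pd_model, pd_env_ca)
        n = sum(1 for _ in enumerate_patterns(system))
        assert n == 2 ** (14 + 2)

    def test_budget_overflow_raises(self, pd_model, pd_env_ca):
        system = cs.assemble_system(pd_model, pd_env_ca)
        with pytest.raises(PatternBudgetExceeded):
            list(enumerate_patterns(system, max_patterns=1))
        with pytest.raises(PatternBudgetExceeded):
            cs.enumerate_solutions(pd_model, pd_env_ca, cs.OracleSettings(max_patterns=1))


class TestSolvePattern:
    def test_symmetric_non_crossfeeding_branch(self, pd_model, pd_env_ca):
        # both species at D-growth with all three uptake caps tight pins the
        # symmetric state X = (17/12, 17/12), C_S = 3 D = 1.5
        system = cs.assemble_system(pd_model, pd_env_ca)
        delta = [False] * 14
        for j in (0, 1, 2, 7, 8, 9):
            delta[j] = True
        sols = solve_pattern(system, ComplementarityPattern(tuple(delta), (True, True)), seed=0)
        assert sols
        best = nearest(sols, [17 / 12, 17 / 12])
        assert np.allclose(best.X, 17 / 12, atol=1e-8)
        assert best.C[0] == pytest.approx(1.5, abs=1e-9)

    def test_single_strain_branch(self, pd_model, pd_env_ca):
        system = cs.assemble_system(pd_model, pd_env_ca)
        delta = [False] * 14
        for j in (0, 1, 2):
            delta[j] = True
        sols = solve_pattern(system, ComplementarityPattern(tuple(delta), (True, False)), seed=0)
        assert sols
        assert sols[0].X[0] == pytest.approx(17 / 6, abs=1e-8)  # D (C_in,S - 3D) / (3D)
        assert sols[0].X[1] == 0.0

    def test_contradictory_branch_is_empty(self, pd_model, pd_env_ca):
        # growth pinned to D while the energy uptake is forced to zero
        system = cs.assemble_system(pd_model, pd_env_ca)
        delta = [False] * 14
        delta[3] = True  # -nu_tS <= 0 tight: no substrate uptake
        delta[0] = True  # nu_tS <= C_S tight as well -> C_S = 0
        delta[1] = True
        delta[2] = True
        sols = solve_pattern(system, ComplementarityPattern(tuple(delta), (True, True)), seed=0)
        assert sols == []


class TestSolutionSets:
    def test_ca_contains_all_printed_states(self, pd_ca_solutions):
        # trivial, both single-strain states, and the symmetric point of the
        # non-crossfeeding continuum, all at C_S = 3D; no crossfeeding anywhere
        X = np.array([np.asarray(s.X) for s in pd_ca_solutions])
        assert any(np.allclose(x, [0, 0], atol=1e-8) for x in X)
        assert any(np.allclose(x, [17 / 6, 0], atol=1e-6) for x in X)
        assert any(np.allclose(x, [0, 17 / 6], atol=1e-6) for x in X)
        assert any(np.allclose(x, [17 / 12, 17 / 12], atol=1e-6) for x in X)
        for s in pd_ca_solutions:
            if np.max(s.X) > 1e-9:
                assert s.C[0] == pytest.approx(1.5, abs=1e-8)
                # transports of A and B stay off: rational agents do not crossfeed
                assert abs(s.nu[0][1]) < 1e-8 and abs(s.nu[0][2]) < 1e-8

    def test_cc_crossfeeding_state_matches_the_closed_form(self, pd_cc_symmetric):
        X = 1 + SQRT15 / 4  # root of 4 X^2 + (4D-10) X + D^2 at D = 0.5
        assert np.allclose(pd_cc_symmetric.X, X, atol=1e-9)
        assert pd_cc_symmetric.C[0] == pytest.approx(5 - SQRT15, abs=1e-9)  # 1.127
        assert pd_cc_symmetric.C[1] == pytest.approx(0.5, abs=1e-9)
        assert pd_cc_symmetric.C[2] == pytest.approx(0.5, abs=1e-9)
        nu1 = pd_cc_symmetric.nu[0]
        assert nu1[2] == pytest.approx(SQRT15 - 4.5, abs=1e-9)  # secretes B: -0.627
        assert nu1[1] == pytest.approx(0.5, abs=1e-9)  # takes up A

    def test_higher_flow_rate_abolishes_crossfeeding(self, pd_cc_fast_solutions):
        # at D = 1.2 the community switches to the non-crossfeeding state
        sym = nearest(pd_cc_fast_solutions, [16 / 15, 16 / 15])
        assert np.allclose(sym.X, 16 / 15, atol=1e-6)
        assert sym.C[0] == pytest.approx(3.6, abs=1e-8)
        assert abs(sym.nu[0][1]) < 1e-8 and abs(sym.nu[0][2]) < 1e-8

    def test_bc_community_steady_state_with_full_crossfeeding(self, pd_bc_solutions):
        sym = nearest(pd_bc_solutions, [0.5, 0.5])
        assert np.allclose(sym.x, 0.5, atol=1e-8)
        assert sym.mu_star == pytest.approx(5.0, abs=1e-8)
        nu1 = sym.nu[0]
        assert nu1[0] == pytest.approx(10.0, abs=1e-7)  # t_S at the culture bound
        assert nu1[1] == pytest.approx(5.0, abs=1e-7)  # all secreted A is taken up
        assert nu1[2] == pytest.approx(-5.0, abs=1e-7)

    def test_washout_at_unattainable_dilution_rate(self, pd_model):
        # max attainable growth is C_in,S / 3 = 10/3 < D = 10
        env = cs.EnvironmentSpec(mode="CA", D=10.0, C_in=np.array([10.0, 0.0, 0.0]))
        sols = cs.enumerate_solutions(pd_model, env, cs.OracleSettings(seed=0))
        assert len(sols) == 1
        assert np.all(sols[0].X == 0.0)

    def test_solution_set_is_symmetric_under_species_exchange(self, pd_cc_solutions):
        keys = {tuple(np.round(np.r_[s.X, s.C], 6)) for s in pd_cc_solutions}
        flipped = {
            tuple(np.round(np.r_[s.X[::-1], s.C[0], s.C[2], s.C[1]], 6))
            for s in pd_cc_solutions
        }
        assert keys == flipped

    def test_every_accepted_solution_is_certified(
        self, pd_model, pd_env_cc, pd_cc_solutions
    ):
        for s in pd_cc_solutions:
            assert s.residual_max < 1e-8
            assert cs.verify_inner_optimality(pd_model, pd_env_cc, s) < 1e-6

    def test_batch_agents_coexist_only_with_equal_maximal_growth(self):
        # agents in batch ignore the culture bounds; a community steady state
        # needs all present species to share their individually maximal
        # growth rate, which fails for generically different stoichiometries
        env = cs.EnvironmentSpec(mode="BA", u=np.array([3.0, 3.0]))
        asym = cs.coexistence_network(3, 1, 1, 2, uptake_bounds="constant")
        sols = cs.enumerate_solutions(asym, env, cs.OracleSettings(seed=0))
        assert {tuple(np.round(s.x, 6)) for s in sols} == {(0.0, 1.0), (1.0, 0.0)}
        assert {round(s.mu_star, 6) for s in sols} == {1.0, round(2 / 3, 6)}
        # the mirrored fixture has equal maximal rates by symmetry, so
        # coexistence states appear as well
        sym = cs.coexistence_network(uptake_bounds="constant")
        sols = cs.enumerate_solutions(sym, env, cs.OracleSettings(seed=0))
        assert any(min(s.x) > 1e-6 for s in sols)
        assert all(abs(s.mu_star - 1.0) < 1e-8 for s in sols)

    def test_enumeration_is_deterministic(self, pd_model):
        env = cs.EnvironmentSpec(mode="CA", D=1.2, C_in=np.array([10.0, 0.0, 0.0]))
        a = cs.enumerate_solutions(pd_model, env, cs.OracleSettings(seed=3))
        b = cs.enumerate_solutions(pd_model, env, cs.OracleSettings(seed=3))
        ka = [tuple(np.round(np.r_[s.X, s.C], 10)) for s in a]
        kb = [tuple(np.round(np.r_[s.X, s.C], 10)) for s in b]
        assert ka == kb
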