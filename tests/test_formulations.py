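import copy

import numpy as np
import pytest

import commsteady as cs
from commsteady.model_core import BoundSpec, SteadyStateSolution


class TestAssembly:
    def test_pd_ca_layout_dimensions(self, pd_model, pd_env_ca):
        system = cs.assemble_system(pd_model, pd_env_ca)
        lay = system.layout
        assert sum(sl.stop - sl.start for sl in lay.nu) == 12
        assert lay.C.stop - lay.C.start == 3
        assert lay.X.stop - lay.X.start == 2
        # per-species KKT blocks: one stationarity row per reaction
        stat = [n for n, k in zip(system.eq_names, system.eq_kinds) if k == "stationarity"]
        assert len(stat) == 12
        # one complementarity product per capacity piece row
        assert sum(k == "complementarity" for k in system.eq_kinds) == 14

    def test_batch_layout_has_no_concentration_slice(self, pd_batch_model, pd_env_bc):
        system = cs.assemble_system(pd_batch_model, pd_env_bc)
        assert system.layout.C is None
        assert system.layout.mu_star is not None

    def test_cc_couples_concentrations_into_the_inner_problem(self, pd_model, pd_env_cc):
        system = cs.assemble_system(pd_model, pd_env_cc)
        # C >= 0 carries multipliers and the balance carries equality duals
        assert sum(q.kind == "Cnn" for q in system.q_rows) == 3
        assert any(k == "stationarity_C" for k in system.eq_kinds)

    def test_agent_mode_rejects_community_objective(self, pd_model):
        with pytest.raises(ValueError):
            cs.EnvironmentSpec(mode="CA", D=0.5, C_in=np.zeros(3), objective="sum_growth")

    def test_batch_rejects_concentration_dependent_bounds(self, pd_model):
        env = cs.EnvironmentSpec(mode="BC", u=np.array([10.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="concentration-dependent"):
            cs.assemble_system(pd_model, env)

    def test_equation_names_are_stable_and_unique(self, pd_model, pd_env_cc):
        system = cs.assemble_system(pd_model, pd_env_cc)
        names = system.equation_names
        assert len(names) == len(set(names))
        assert names == cs.assemble_system(pd_model, pd_env_cc).equation_names


class TestResidual:
    def test_printed_precision_candidate_has_small_residual(
        self, pd_model, pd_env_ca, pd_ca_symmetric
    ):
        # the symmetric non-crossfeeding state rounded to the precision used
        # in print (2-3 significant figures) violates the balances only by
        # the rounding error
        system = cs.assemble_system(pd_model, pd_env_ca)
        cand = copy.deepcopy(pd_ca_symmetric)
        cand.X = np.round(cand.X, 2)
        cand.C = np.round(cand.C, 2)
        cand.nu = [np.round(v, 2) for v in cand.nu]
        rep = cs.residual(system, cand)
        assert 0 < rep.residual_max <= 0.02

    def test_doubling_one_abundance_breaks_the_substrate_balance(
        self, pd_model, pd_env_ca, pd_ca_symmetric
    ):
        system = cs.assemble_system(pd_model, pd_env_ca)
        cand = copy.deepcopy(pd_ca_symmetric)
        cand.X = np.array([2 * 17 / 12, 17 / 12])
        rep = cs.residual(system, cand)
        # extra uptake 1.5 * 17/12 ~ 2.125 appears in the S balance
        assert abs(rep.breakdown["balance[S]"]) == pytest.approx(1.5 * 17 / 12, abs=1e-9)

    def test_residual_is_exact_zero_for_oracle_solutions(
        self, pd_model, pd_env_cc, pd_cc_solutions
    ):
        system = cs.assemble_system(pd_model, pd_env_cc)
        for sol in pd_cc_solutions:
            assert cs.residual(system, sol).residual_max < 1e-8

    def test_dimension_mismatch_raises(self, pd_model, pd_env_ca):
        system = cs.assemble_system(pd_model, pd_env_ca)
        bad = SteadyStateSolution(nu=[np.zeros(5), np.zeros(6)], C=np.zeros(3), X=np.zeros(2))
        with pytest.raises(ValueError):
            cs.residual(system, bad)


class TestInnerOptimality:
    def test_cc_candidate_attains_the_joint_optimum(
        self, pd_model, pd_env_cc, pd_cc_symmetric
    ):
        gap = cs.verify_inner_optimality(pd_model, pd_env_cc, pd_cc_symmetric)
        assert gap < 1e-9

    def test_ca_agents_attain_their_individual_optima(
        self, pd_model, pd_env_ca, pd_ca_symmetric
    ):
        assert pd_ca_symmetric.nu[0][5] == pytest.approx(0.5)
        gap = cs.verify_inner_optimality(pd_model, pd_env_ca, pd_ca_symmetric)
        assert gap < 1e-9

    def test_feasible_but_suboptimal_growth_is_detected(
        self, pd_model, pd_env_ca, pd_ca_symmetric
    ):
        cand = copy.deepcopy(pd_ca_symmetric)
        # reallocate species 1: nu = (t_S, t_A, t_B, r_A, r_B, mu), growing at
        # 0.4 instead of the attainable 0.5
        cand.nu[0] = np.array([1.2, 0.0, 0.0, 0.4, 0.4, 0.4])
        gap = cs.verify_inner_optimality(pd_model, pd_env_ca, cand)
        assert gap == pytest.approx(0.1, abs=1e-8)


class TestModeInvariants:
    def test_d_growth_holds_for_every_supported_species(
        self, pd_model, pd_env_cc, pd_cc_solutions
    ):
        for sol in pd_cc_solutions:
            growth = sol.growth_rates(pd_model)
            for i in range(2):
                if sol.X[i] > 1e-9:
                    assert abs(growth[i] - pd_env_cc.D) < 1e-8

    def test_batch_abundances_are_normalized(self, pd_bc_solutions):
        for sol in pd_bc_solutions:
            assert abs(np.sum(sol.x) - 1.0) < 1e-8

    def test_constant_bounds_admit_only_washout_under_ca(self):
        # without concentration feedback the agents' optima cannot depend on
        # the chemostat state, so no non-trivial state matches a generic D
        m = cs.pd_network()
        for sp in m.species:
            sp.b = [BoundSpec.constant(2.0, 3) if i < 3 else b for i, b in enumerate(sp.b)]
            sp.uptake_rows = ()
        env = cs.EnvironmentSpec(mode="CA", D=0.37, C_in=np.array([10.0, 0.0, 0.0]))
        sols = cs.enumerate_solutions(m, env, cs.OracleSettings(seed=0))
        assert len(sols) == 1
        assert np.all(sols[0].X == 0.0)
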