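import numpy as np
import pytest

import commsteady as cs
from commsteady.fixtures import SyntrophicDataMissing


class TestDilemmaNetwork:
    def test_growth_consumes_one_unit_of_each_precursor(self, pd_model):
        sp1 = pd_model.species[0]
        g = sp1.S[:, sp1.growth_index]
        assert g[sp1.metabolite_ids.index("A_c")] == -1.0
        assert g[sp1.metabolite_ids.index("B_c")] == -1.0

    def test_species1_makes_A_at_half_yield(self, pd_model):
        sp1 = pd_model.species[0]
        rA = sp1.S[:, sp1.reaction_ids.index("r_A")]
        rB = sp1.S[:, sp1.reaction_ids.index("r_B")]
        assert rA[0] == -2.0 and rA[1] == 1.0  # 2 S_c -> A_c
        assert rB[0] == -1.0 and rB[2] == 1.0  # 1 S_c -> B_c

    def test_species_exchange_symmetry(self, pd_model):
        # relabeling (A <-> B, species 1 <-> 2) maps the model onto itself
        sp1, sp2 = pd_model.species
        perm_r = [0, 2, 1, 4, 3, 5]  # swap t_A/t_B and r_A/r_B
        perm_m = [0, 2, 1]  # swap A_c/B_c
        assert np.array_equal(sp1.S[np.ix_(perm_m, perm_r)], sp2.S)
        assert np.array_equal(sp1.T[np.ix_(perm_m, perm_r)], sp2.T)

    def test_batch_variant_drops_kinetic_caps_only(self):
        m = cs.pd_network(uptake_bounds="unbounded")
        assert not m.has_concentration_dependent_bounds()
        assert m.species[0].n_A == 4  # irreversibility rows remain


class TestCoexistenceNetwork:
    def test_default_demands_are_mirrored(self):
        m = cs.coexistence_network()
        g1 = m.species[0].S[:, 2]
        g2 = m.species[1].S[:, 2]
        assert np.array_equal(g1, [-2.0, -1.0])
        assert np.array_equal(g2, [-1.0, -2.0])

    def test_swapping_demands_and_labels_is_the_identity(self):
        m = cs.coexistence_network(2, 1, 1, 2)
        swapped = cs.coexistence_network(2, 1, 1, 2)
        sp1 = m.species[0]
        sp2s = swapped.species[1]
        assert np.array_equal(sp1.S[np.ix_([1, 0], [1, 0, 2])], sp2s.S)

    def test_parameter_ordering_is_enforced(self):
        with pytest.raises(ValueError):
            cs.coexistence_network(1, 2, 1, 2)

    def test_no_secretion_capability(self):
        # transports are uptake-only: crossfeeding is structurally impossible
        m = cs.coexistence_network()
        for sp in m.species:
            assert any(np.array_equal(row, [-1.0, 0.0, 0.0]) for row in sp.A)
            assert any(np.array_equal(row, [0.0, -1.0, 0.0]) for row in sp.A)


class TestRandomCommunity:
    def test_seeded_reproducibility(self):
        a, b = cs.random_community(1), cs.random_community(1)
        assert all(np.array_equal(x.S, y.S) for x, y in zip(a.species, b.species))

    def test_different_seeds_differ(self):
        a, b = cs.random_community(1), cs.random_community(2)
        assert any(not np.array_equal(x.S, y.S) for x, y in zip(a.species, b.species))

    @pytest.mark.parametrize("seed", [1, 5, 11])
    def test_generated_communities_are_valid_and_admit_washout(self, seed):
        m = cs.random_community(seed)
        assert cs.validate_community(m) == []
        env = cs.EnvironmentSpec(mode="CA", D=0.4, C_in=np.full(m.n_C, 3.0))
        sols = cs.enumerate_solutions(m, env, cs.OracleSettings(seed=0))
        trivial = [s for s in sols if np.all(s.X == 0.0)]
        assert trivial and trivial[0].residual_max < 1e-8


class TestSweeps:
    def test_midpoint_and_endpoints(self):
        base = cs.EnvironmentSpec(mode="CA", D=1.0, C_in=np.array([0.0, 10.0]))
        envs = cs.sweep_environments(base, (0.0, 10.0), (10.0, 0.0), 3)
        assert np.allclose(envs[0].C_in, [0, 10])
        assert np.allclose(envs[1].C_in, [5, 5])
        assert np.allclose(envs[2].C_in, [10, 0])
        assert all(e.D == 1.0 for e in envs)

    def test_batch_sweeps_interpolate_the_culture_bounds(self):
        base = cs.EnvironmentSpec(mode="BC", u=np.array([0.0, 1.0]))
        envs = cs.sweep_environments(base, (0.0, 1.0), (1.0, 0.0), 5)
        assert np.allclose(envs[2].u, [0.5, 0.5])

    def test_too_few_points_rejected(self):
        base = cs.EnvironmentSpec(mode="CA", D=1.0, C_in=np.array([0.0, 10.0]))
        with pytest.raises(ValueError):
            cs.sweep_environments(base, (0.0, 10.0), (10.0, 0.0), 1)


class TestSyntrophicPair:
    PARAMS = {
        "alanine_synthesis": {"id": "ALA_SYN", "stoichiometry": {"glu__L_c": -1, "ala__L_c": 1}},
        "knockouts": {"ala_aux": ["ALA_SYN"], "gln_aux": ["GLNS"]},
        "C_in": {"glc__D_e": 10.0},
        "uptake_kinetics": {"glc__D_e": [(0.0, 1.0)]},
        "D": 0.1,
    }

    def test_missing_file_raises_the_skip_signal(self, tmp_path):
        with pytest.raises(SyntrophicDataMissing):
            cs.syntrophic_pair(tmp_path / "absent.xml", self.PARAMS)

    def test_incomplete_params_name_the_missing_field(self, tmp_path):
        params = dict(self.PARAMS)
        del params["D"]
        with pytest.raises(KeyError, match="D"):
            cs.syntrophic_pair(tmp_path / "absent.xml", params)

    def test_auxotroph_toy_growth_requires_the_missing_amino_acids(self):
        # with plentiful glucose but neither amino acid supplied, neither
        # strain can grow at all (zero fluxes are already agent-optimal);
        # adding the amino acids unlocks growth
        model, _ = cs.auxotroph_pair_toy()
        zero = cs.SteadyStateSolution(nu=[np.zeros(5), np.zeros(5)], X=np.zeros(2))
        env0 = cs.EnvironmentSpec(mode="CA", D=0.5, C_in=np.array([10.0, 0.0, 0.0]))
        zero.C = env0.C_in.copy()
        assert cs.verify_inner_optimality(model, env0, zero) < 1e-9
        env1 = cs.EnvironmentSpec(mode="CA", D=0.5, C_in=np.array([10.0, 2.0, 2.0]))
        zero.C = env1.C_in.copy()
        assert cs.verify_inner_optimality(model, env1, zero) > 0.1
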