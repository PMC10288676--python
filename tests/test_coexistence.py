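"""Regime structure of the two-nutrient coexistence consortium.

Over a linear sweep of the inflow mixture at D = 1 the accepted solution
sets show the expected sequence per species: washout, a single-strain branch
rising and then falling, and a contiguous central window with a coexistence
state in which each species is limited by a different nutrient.  Because the
fixture cannot crossfeed, the rational-agent and rational-community chemostat
models must agree exactly.
"""

import numpy as np
import pytest

import commsteady as cs

ORACLE = cs.OracleSettings(seed=0)


def _key(sol):
    return tuple(np.round(np.r_[sol.X, sol.C], 6))


@pytest.fixture(scope="module")
def sweep_solutions():
    model = cs.coexistence_network()
    base = cs.EnvironmentSpec(mode="CA", D=1.0, C_in=np.array([0.0, 10.0]))
    envs = cs.sweep_environments(base, (0.0, 10.0), (10.0, 0.0), 11)
    out = []
    for env in envs:
        ca = cs.enumerate_solutions(model, env, ORACLE)
        cc_env = cs.EnvironmentSpec(mode="CC", D=1.0, C_in=env.C_in)
        cc = cs.enumerate_solutions(model, cc_env, ORACLE)
        out.append((env, ca, cc))
    return out


class TestChemostatSweep:
    def test_agent_and_community_models_agree_without_crossfeeding(self, sweep_solutions):
        for _, ca, cc in sweep_solutions:
            ka = sorted(_key(s) for s in ca)
            kc = sorted(_key(s) for s in cc)
            assert len(ka) == len(kc)
            for a, c in zip(ka, kc):
                assert np.max(np.abs(np.array(a) - np.array(c))) < 1e-6

    def test_single_strain_branches_are_mirror_images(self, sweep_solutions):
        def strain_level(sols, i):
            ss = [s for s in sols if s.X[i] > 1e-6 and s.X[1 - i] < 1e-9]
            return max((s.X[i] for s in ss), default=0.0)

        lv1 = [strain_level(ca, 0) for _, ca, _ in sweep_solutions]
        lv2 = [strain_level(ca, 1) for _, ca, _ in sweep_solutions]
        assert np.allclose(lv1, lv2[::-1], atol=1e-6)
        # rise-then-fall shape with a leading washout regime
        assert lv1[0] == 0.0 and lv1[1] == 0.0
        peak = int(np.argmax(lv1))
        assert 0 < peak < 10

    def test_coexistence_window_is_central_and_contiguous(self, sweep_solutions):
        has_co = [
            any(min(s.X) > 1e-6 for s in ca) for _, ca, _ in sweep_solutions
        ]
        idx = [k for k, h in enumerate(has_co) if h]
        assert idx, "no coexistence state found anywhere in the sweep"
        assert idx == list(range(idx[0], idx[-1] + 1))  # contiguous
        assert idx[0] > 0 and idx[-1] < 10  # strictly interior

    def test_coexistence_matches_differential_limitation_closed_form(self, sweep_solutions):
        # species 1 A-limited (C_A = 1), species 2 B-limited (C_B = 1):
        # X1 = (2(C_inA - 1) - (C_inB - 1)) / 3 and mirrored for X2
        for env, ca, _ in sweep_solutions:
            co = [s for s in ca if min(s.X) > 1e-6]
            for s in co:
                cinA, cinB = env.C_in
                x1 = (2 * (cinA - 1) - (cinB - 1)) / 3
                x2 = (2 * (cinB - 1) - (cinA - 1)) / 3
                assert np.allclose(s.X, [x1, x2], atol=1e-6)
                assert np.allclose(s.C, [1.0, 1.0], atol=1e-6)


@pytest.fixture(scope="module")
def bc_sweep():
    model = cs.coexistence_network(uptake_bounds="constant")
    base = cs.EnvironmentSpec(mode="BC", u=np.array([0.0, 1.0]))
    envs = cs.sweep_environments(base, (0.0, 1.0), (1.0, 0.0), 11)
    return [(env, cs.enumerate_solutions(model, env, ORACLE)) for env in envs[1:-1]]


class TestBatchSweep:
    def test_single_strain_relative_concentrations_are_one(self, bc_sweep):
        for _, sols in bc_sweep:
            ss = [s for s in sols if max(s.x) > 1 - 1e-9]
            assert ss, "single-strain state missing"
            for s in ss:
                assert max(s.x) == pytest.approx(1.0, abs=1e-9)

    def test_coexistence_uptakes_stay_below_the_individual_caps(self, bc_sweep):
        found = 0
        for env, sols in bc_sweep:
            for s in sols:
                if min(s.x) > 1e-6:
                    found += 1
                    # individual uptakes strictly below the cap of 2 while the
                    # culture bounds are tight
                    assert s.nu[0][0] < 2 - 1e-6
                    assert s.nu[1][1] < 2 - 1e-6
                    total_A = sum(s.x[i] * s.nu[i][0] for i in range(2))
                    total_B = sum(s.x[i] * s.nu[i][1] for i in range(2))
                    assert total_A == pytest.approx(env.u[0], abs=1e-7)
                    assert total_B == pytest.approx(env.u[1], abs=1e-7)
                    assert s.mu_star == pytest.approx(np.sum(env.u) / 3, abs=1e-7)
        assert found >= 3


class TestObjectiveChoice:
    def test_sum_of_growth_objective_changes_the_coexistence_set(self):
        model = cs.coexistence_network()
        diff = False
        for cin in [(3.0, 7.0), (5.0, 5.0), (7.0, 3.0)]:
            e_bio = cs.EnvironmentSpec(mode="CC", D=1.0, C_in=np.array(cin))
            e_sum = cs.EnvironmentSpec(
                mode="CC", D=1.0, C_in=np.array(cin), objective="sum_growth"
            )
            k_bio = sorted(_key(s) for s in cs.enumerate_solutions(model, e_bio, ORACLE))
            k_sum = sorted(_key(s) for s in cs.enumerate_solutions(model, e_sum, ORACLE))
            if k_bio != k_sum:
                diff = True
        assert diff
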