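"""Shared fixtures: models, environments and (expensive) oracle solution sets.

Exhaustive branch enumerations are session-scoped so the prisoner's-dilemma
solution sets are computed once and shared across test modules.
"""

import numpy as np
import pytest
from hypothesis import settings

import commsteady as cs

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("suite")

ORACLE = cs.OracleSettings(seed=0)


@pytest.fixture(scope="session")
def pd_model():
    return cs.pd_network()


@pytest.fixture(scope="session")
def pd_batch_model():
    return cs.pd_network(uptake_bounds="unbounded")


@pytest.fixture(scope="session")
def pd_env_ca():
    return cs.EnvironmentSpec(mode="CA", D=0.5, C_in=np.array([10.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def pd_env_cc():
    return cs.EnvironmentSpec(mode="CC", D=0.5, C_in=np.array([10.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def pd_env_cc_fast():
    return cs.EnvironmentSpec(mode="CC", D=1.2, C_in=np.array([10.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def pd_env_bc():
    return cs.EnvironmentSpec(mode="BC", u=np.array([10.0, 0.0, 0.0]))


@pytest.fixture(scope="session")
def pd_ca_solutions(pd_model, pd_env_ca):
    return cs.enumerate_solutions(pd_model, pd_env_ca, ORACLE)


@pytest.fixture(scope="session")
def pd_cc_solutions(pd_model, pd_env_cc):
    return cs.enumerate_solutions(pd_model, pd_env_cc, ORACLE)


@pytest.fixture(scope="session")
def pd_cc_fast_solutions(pd_model, pd_env_cc_fast):
    return cs.enumerate_solutions(pd_model, pd_env_cc_fast, ORACLE)


@pytest.fixture(scope="session")
def pd_bc_solutions(pd_batch_model, pd_env_bc):
    return cs.enumerate_solutions(pd_batch_model, pd_env_bc, ORACLE)


def nearest(sols, X):
    """Solution whose abundance vector is closest to X (inf-norm)."""
    X = np.asarray(X, float)
    return min(sols, key=lambda s: np.max(np.abs(np.asarray(s.abundances) - X)))


@pytest.fixture(scope="session")
def pd_ca_symmetric(pd_ca_solutions):
    return nearest(pd_ca_solutions, [17 / 12, 17 / 12])


@pytest.fixture(scope="session")
def pd_cc_symmetric(pd_cc_solutions):
    sym = [s for s in pd_cc_solutions
           if abs(s.X[0] - s.X[1]) < 1e-6 and s.X[0] > 1.5]
    assert sym, "symmetric crossfeeding steady state not found"
    return sym[0]
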