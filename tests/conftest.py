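"""Shared fixtures: one simulated experiment and the heavy recovery runs.

The expensive Monte-Carlo recovery experiments are session-scoped so the
acceptance tests and the module tests that look at different facets of the
same runs compute them only once.
"""

import pytest

import virdecomp as vd


@pytest.fixture(scope="session")
def sim_tables():
    """One full simulated experiment (survival, load, dead-fly tables)."""
    cfg = vd.SimulationConfig(seed=7)
    survival, loads, dead = vd.simulate_experiment(cfg)
    return {"config": cfg, "survival": survival, "loads": loads, "dead": dead}


@pytest.fixture(scope="session")
def decomposition(sim_tables):
    """Hazards, summaries and the three decomposition fits on the fixture."""
    return vd.decomposition_pipeline(sim_tables["survival"],
                                     sim_tables["loads"])


@pytest.fixture(scope="session")
def ppp_recovery():
    """100 study-scale simulations refitting the PPP reaction norms."""
    return vd.ppp_ordering_recovery(n_sims=100, seed=17)


@pytest.fixture(scope="session")
def ppp_recovery_flat_low():
    """As ppp_recovery but with a flat (zero-PPP) low species."""
    return vd.ppp_ordering_recovery(n_sims=100, seed=23,
                                    ppp_true=(0.0, 0.5, 0.5))


@pytest.fixture(scope="session")
def sign_recovery():
    """200 full-pipeline simulations refitting the clearance model."""
    return vd.exploitation_sign_recovery(n_sims=200, seed=29)
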