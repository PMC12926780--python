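"""Shared fixtures: toy models, LPs, and the two-group planted-effect data."""

import numpy as np
import pytest

from fluxscape import ToySpec, build_lp, make_toy_model, make_twogroup_fixture
from fluxscape.fixtures import make_branched_model


@pytest.fixture
def chain_model():
    """EX_A(lb -10) -> P1R1(A->B) -> EX_B (objective); P1R1 carries a GPR."""
    return make_toy_model(ToySpec(gpr_assignment={"P1R1": "g1 and g2"}))


@pytest.fixture
def chain_lp(chain_model):
    return build_lp(chain_model)


@pytest.fixture
def parallel_model():
    """Two interchangeable single-reaction routes A->B, shared uptake."""
    return make_toy_model(
        ToySpec(
            n_parallel_paths=2,
            path_lengths=(1, 1),
            gpr_assignment={"P1R1": "g1 and g2", "P2R1": "g3 or g4"},
        )
    )


@pytest.fixture
def parallel_lp(parallel_model):
    return build_lp(parallel_model)


@pytest.fixture
def two_length_model():
    """One direct route and one two-step route A->B (pFBA prefers the short one)."""
    return make_toy_model(ToySpec(n_parallel_paths=2, path_lengths=(1, 2)))


@pytest.fixture
def branched_model():
    return make_branched_model(n_branches=3)


@pytest.fixture(scope="session")
def twogroup():
    """Planted-effect fixture: branch 1 genes 3x up in 'tumor', 25/group."""
    return make_twogroup_fixture(seed=11, n_samples_per_group=25)


def random_lp_fixtures(seed=0, count=5):
    """Small random-bound LPs on the parallel topology for oracle checks."""
    rng = np.random.default_rng(seed)
    fixtures = []
    for _ in range(count):
        model = make_toy_model(
            ToySpec(n_parallel_paths=2, path_lengths=(1, 2), uptake_limit=10.0)
        )
        lp = build_lp(model)
        # randomize internal upper bounds into [2, 12] to vary the optimum
        for j, rid in enumerate(lp.reaction_ids):
            if not rid.startswith("EX_"):
                lp.upper[j] = rng.uniform(2.0, 12.0)
        lp.upper = np.minimum(lp.upper, 40.0)
        fixtures.append(lp)
    return fixtures
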