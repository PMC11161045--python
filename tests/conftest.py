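import numpy as np
import pytest

from ecoassembly.metacommunity import MetacommunitySpec, generate_metacommunity
from ecoassembly.workbench import desk_config, make_fixtures, run_batch


@pytest.fixture(scope="session")
def meta_small():
    """100-species regional pool shared across tests."""
    return generate_metacommunity(MetacommunitySpec(n_species=100, seed=1))


@pytest.fixture(scope="session")
def fixture_table():
    """Tiny deterministic batch: 5 models x 20 sims at J=200."""
    return make_fixtures(seed=1, n_per_model=20)


@pytest.fixture(scope="session")
def desk_table():
    """Desk-scale training batch: 500 sims per model, J in [500, 1000].

    This is the reproduction-scale dataset behind the classification
    checks; built once per session.
    """
    return run_batch(desk_config(seed=1, n_per_model=500))


def random_community(rng, S=None, J=None):
    """Random valid LocalCommunity for property tests."""
    from ecoassembly.assembly import LocalCommunity

    S = S or int(rng.integers(2, 30))
    J = J or int(rng.integers(S + 1, 300))
    # every species gets at least one individual
    species_of = np.concatenate([np.arange(S), rng.integers(0, S, J - S)])
    rng.shuffle(species_of)
    return LocalCommunity(
        species_of=species_of,
        species_uid=np.arange(S),
        trait=rng.normal(0, 1.5, S),
        colonist_flag=rng.random(J) < 0.5,
        meta_index=np.full(S, -1),
        colonization_gen=np.zeros(S),
    )
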