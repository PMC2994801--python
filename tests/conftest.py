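import numpy as np
import pytest

from betaturn.synthetic import FixtureSpec, make_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small but non-trivial fixture set shared by fast tests."""
    spec = FixtureSpec(
        n_chains=12, length_range=(60, 70), turns_per_chain=3, seed=42
    )
    return make_dataset(spec)


@pytest.fixture(scope="session")
def small_tracks(small_dataset):
    from betaturn.features import first_layer_track

    return {
        f.chain_id: first_layer_track(f.profile, f.struct) for f in small_dataset
    }


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    return {f.chain_id: f.annotation.in_turn for f in small_dataset}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
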