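import numpy as np
import pytest

from ensemblerange import synthetic as syn


def random_rigid_motion(rng: np.random.Generator):
    """A uniformly random proper rotation and a random translation."""
    rot = syn._random_rotation(rng)
    shift = rng.normal(0.0, 10.0, size=3)
    return rot, shift


@pytest.fixture(scope="session")
def rigid_bundle():
    """Exactly congruent conformers under random per-conformer rigid motions."""
    return syn.make_bundle(syn.rigid_spec(n_residues=40, n_conformers=10, seed=1))


@pytest.fixture(scope="session")
def helix_tails_bundle():
    return syn.make_bundle(syn.helix_with_tails_spec(seed=3))


@pytest.fixture(scope="session")
def two_domain_bundle():
    return syn.make_bundle(syn.two_domain_spec(seed=5))


@pytest.fixture(scope="session")
def loop_bundle():
    return syn.make_bundle(syn.interior_loop_spec(seed=7))
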