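import numpy as np
import pytest

from acr3kit.synthetic_data import (BundleSpec, generate_helix_bundle,
                                    perturb_structure)


@pytest.fixture(scope="session")
def small_bundle():
    """A compact 3-helix bundle used across structural tests."""
    spec = BundleSpec(n_helices=3, residues_per_helix=18, loop_length=4,
                      ring_radius=10.0, seed=11)
    return generate_helix_bundle(spec)


@pytest.fixture(scope="session")
def single_helix():
    spec = BundleSpec(n_helices=1, residues_per_helix=18, ring_radius=10.0,
                      loop_length=0, seed=0)
    return generate_helix_bundle(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_structure_pair(seed, n_helices=2, residues=12, sigma=0.3):
    """Two noisy siblings of one bundle parent, for contact-map comparisons."""
    spec = BundleSpec(n_helices=n_helices, residues_per_helix=residues,
                      loop_length=3, ring_radius=9.0, seed=seed)
    parent = generate_helix_bundle(spec)
    a = perturb_structure(parent, sigma=sigma, seed=seed * 2 + 1)
    b = perturb_structure(parent, sigma=sigma, seed=seed * 2 + 2)
    return a, b
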