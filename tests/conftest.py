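import numpy as np
import pytest

from protdyn.structure import extract_coarse_grain, make_toy_structure


@pytest.fixture(scope="session")
def helix20():
    return make_toy_structure("ideal_helix", 20, sequence="AVLKDEAVLKDEAVLKDEAV")


@pytest.fixture(scope="session")
def cluster30():
    return make_toy_structure("cluster", 30, sequence="AVLKDE" * 5, seed=1)


@pytest.fixture(scope="session")
def helix20_cg(helix20):
    return extract_coarse_grain(helix20)


@pytest.fixture(scope="session")
def cluster30_cg(cluster30):
    return extract_coarse_grain(cluster30)


def rigid_transform(structure, seed=0, translation=(10.0, -5.0, 3.0)):
    """Apply a random (seeded) proper rotation plus translation."""
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    moved = structure.copy()
    t = np.asarray(translation)
    for a in moved.atoms:
        a.coords = q @ a.coords + t
    return moved
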