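import numpy as np
import pytest

from quanvnet.complexes import make_dataset


@pytest.fixture(scope="session")
def tiny_grids():
    """Six small blurred synthetic complexes (16 A box) for fast tests."""
    return make_dataset(6, seed=7, box_size=16.0, n_protein_range=(15, 25),
                        n_ligand_range=(4, 8))


@pytest.fixture(scope="session")
def random_state():
    def _make(q: int, seed: int = 0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        psi = rng.normal(size=1 << q) + 1j * rng.normal(size=1 << q)
        return psi / np.linalg.norm(psi)

    return _make
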