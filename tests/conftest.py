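import numpy as np
import pytest

from riboflex.synthetic_data import ToyComplexSpec, make_toy_complex


@pytest.fixture(scope="session")
def toy_complex():
    """Six-residue / four-nucleotide complex with two true contacts and one near-miss."""
    spec = ToyComplexSpec(
        n_protein_res=6,
        n_rna_nt=4,
        protein_sequence="KRDSGH",
        planted_contacts=frozenset({(1, 0, 3.4), (2, 1, 3.0), (4, 2, 3.8)}),
        seed=11,
    )
    return make_toy_complex(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_rotation(seed: int) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    return Rotation.random(rng=np.random.default_rng(seed)).as_matrix()
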