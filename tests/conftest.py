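import numpy as np
import pytest

from termipep import Catalog, GeneRecord, build_index, make_catalog, uniform_program

_RNG_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_cds(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return _RNG_BASES[rng.integers(0, 4, size=length)].tobytes().decode()


@pytest.fixture(scope="session")
def full_catalog():
    return make_catalog(seed=1)


@pytest.fixture(scope="session")
def full_index(full_catalog):
    return build_index(full_catalog)


@pytest.fixture(scope="session")
def np_catalog(full_catalog):
    """Catalog restricted to neuropeptide + ilp genes (short CDS)."""
    return Catalog([g for g in full_catalog
                    if g.category in ("neuropeptide", "ilp")])


@pytest.fixture(scope="session")
def mini_catalog():
    """Five short dissimilar genes for brute-force comparisons."""
    genes = [
        GeneRecord(f"g{i}", f"gene {i}", random_cds(100 + i, 210),
                   "neuropeptide", False, 60)
        for i in range(5)
    ]
    return Catalog(genes)


@pytest.fixture()
def basic_program(mini_catalog):
    return uniform_program(mini_catalog, ["w"])
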