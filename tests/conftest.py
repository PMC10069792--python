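import numpy as np
import pytest

from polphen.synth import (DEFAULT_WT_SEQ, SyntheticSpec,
                           generate_fitness_dataset, random_mutant_library)


@pytest.fixture(scope="session")
def wt_seq() -> str:
    return DEFAULT_WT_SEQ


@pytest.fixture(scope="session")
def small_fitness_dataset():
    """Low-noise 40-mutant fitness dataset with ground truth."""
    spec = SyntheticSpec(n_mutants=40, sigma_rep=0.05, missingness=0.1, seed=11)
    return generate_fitness_dataset(spec)


@pytest.fixture(scope="session")
def mutant_library():
    rng = np.random.default_rng(21)
    return random_mutant_library(50, rng)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_toy_frame(rng, n_residues=5, atoms_per_residue=4, spread=8.0):
    """Small random structure for brute-force oracle comparisons."""
    from polphen.mdfeat import StructureFrame

    n = n_residues * atoms_per_residue
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    return StructureFrame(
        names=[f"X{i}" for i in range(n)],
        elements=elements,
        residue_ids=np.repeat(np.arange(1, n_residues + 1), atoms_per_residue),
        coords=rng.uniform(-spread, spread, size=(n, 3)),
    )
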