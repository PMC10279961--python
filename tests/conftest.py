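import numpy as np
import pytest

from plastibar.simulate import SimulationParams, generate_study_like_dataset
from plastibar.structure import CircularGenome, revcomp

BASES = "ACGT"


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def planted_ir_genome(rng, lsc=1000, ir=300, ssc=200, genome_id="planted"):
    """L + R + S + revcomp(R): quadripartite toy genome with known truth."""
    L = random_seq(rng, lsc)
    R = random_seq(rng, ir)
    S = random_seq(rng, ssc)
    return CircularGenome(id=genome_id, residues=L + R + S + revcomp(R)), (lsc, ir, ssc)


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def study_dataset():
    """One cibotium-like synthetic dataset (seed 1) shared across tests."""
    params = SimulationParams(seed=1)
    genomes, aln, groups, truth = generate_study_like_dataset(params)
    return params, genomes, aln, groups, truth
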