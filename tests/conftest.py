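import numpy as np
import pytest

from gsurveyminer import PlantedRepeat, SimConfig, simulate_library

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int, n_prob: float = 0.0) -> str:
    if n_prob > 0:
        alphabet = np.array(list("ACGTN"))
        p = [(1 - n_prob) / 4] * 4 + [n_prob]
        return "".join(alphabet[rng.choice(5, size=length, p=p)])
    return "".join(BASES[rng.choice(4, size=length)])


@pytest.fixture(scope="session")
def planted_library():
    """Library with 50 clean perfect repeat loci on single-read contigs."""
    plants = (
        tuple(PlantedRepeat(motif="AC", n_units=15) for _ in range(20))
        + tuple(PlantedRepeat(motif="AAG", n_units=10) for _ in range(20))
        + tuple(PlantedRepeat(motif="AGAT", n_units=8) for _ in range(10))
    )
    cfg = SimConfig(seed=123, n_contigs=150, planted_repeats=plants)
    return simulate_library(cfg)
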