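import numpy as np
import pytest

from introscan import simulate as sim


@pytest.fixture
def toy_genome():
    """Small two-chromosome genome for fast simulation tests."""
    return sim.GenomeModel(
        chrom_lengths={"X": 3_000_000, "2L": 2_000_000},
        divergent_density=0.5,
    )


@pytest.fixture
def toy_sterility():
    """Sterility loci placed inside the toy genome."""
    return sim.SterilityModel(loci=[("X", 1_500_000), ("2L", 1_200_000)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
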