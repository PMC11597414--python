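import numpy as np
import pytest

from duimito.genome_io import GeneFeature, MitoGenome
from duimito.synthetic_data import SimConfig, simulate_pair


@pytest.fixture(scope="session")
def small_pair():
    """One moderately diverged F/M pair at desk scale, with truth."""
    cfg = SimConfig(seed=42, scale=0.3, nt_divergence=0.15)
    return simulate_pair(cfg)


@pytest.fixture
def toy_genome():
    """Hand-built 120-nt circular genome with two genes and two URs."""
    seq = ("ATGAAATTTGGGTAA" + "ACGT" * 5        # cox1 0..15, UR 15..35
           + "ATGCCCAAATAA" + "A" * 40           # nad2 35..47, UR 47..87
           + "ATGTTTGGGCCCTAA" + "TTGGCCAACCTGGAAAAT")  # cob 87..102, UR 102..120
    feats = [
        GeneFeature("cox1", "PCG", 0, 15),
        GeneFeature("nad2", "PCG", 35, 47),
        GeneFeature("cob", "PCG", 87, 102),
    ]
    return MitoGenome("toy", "Toy species", "F", "circular", seq, feats)


@pytest.fixture
def rng():
    return np.random.default_rng(20240)
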