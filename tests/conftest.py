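import numpy as np
import pytest

from resectquant.core import Genome
from resectquant.sim import BackgroundPeak, GenomeSpec, LibraryParams, ResectionModel


@pytest.fixture
def genome():
    return Genome({"chrSim": 200_000})


@pytest.fixture
def spec(genome):
    return GenomeSpec(genome=genome, dsb_chrom="chrSim", dsb_pos=100_000)


@pytest.fixture
def spec_with_peaks(genome):
    peaks = [
        BackgroundPeak("chrSim", center, 300, 20.0)
        for center in (20_000, 40_000, 170_000)
    ]
    return GenomeSpec(
        genome=genome, dsb_chrom="chrSim", dsb_pos=100_000, background_peaks=peaks
    )


@pytest.fixture
def model():
    return ResectionModel(cut_efficiency=0.9, speed_mean=4000.0, speed_cv=0.3)


@pytest.fixture
def noiseless_lib():
    return LibraryParams(mean_depth=50.0, noise="none", seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
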