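import numpy as np
import pytest

from zfintegrate.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


@pytest.fixture
def small_cfg():
    """A scaled-down simulation for fast unit tests."""
    return SimulationConfig(
        seed=11,
        n_genes=60,
        n_peaks=300,
        chrom_length=5_000_000,
        n_replicates=3,
        spikein_n=80,
        loop_n=12,
        map_n_bins=500,
        loop_min_sep_bins=60,
        loop_max_sep_bins=200,
    )
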