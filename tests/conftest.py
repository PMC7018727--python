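import numpy as np
import pytest

from cinpipe.genome import GenomeBinning, toy_genome
from cinpipe.matrices import CopyNumberMatrix
from cinpipe.simulate import archetype_presets, simulate_karyotypes


@pytest.fixture(scope="session")
def toy():
    return toy_genome()


@pytest.fixture(scope="session")
def presets():
    return archetype_presets()


@pytest.fixture(scope="session")
def preset_truths(toy, presets):
    """Ground-truth matrices for the four archetypes, 50 cells, fixed seed."""
    return {name: simulate_karyotypes(toy, spec["clones"], n_cells=50,
                                      missegregation_rate=spec["missegregation_rate"],
                                      seed=1)
            for name, spec in presets.items()}


def make_cn(states, chrom_lengths, bin_size=1_000_000, max_state=10):
    """Build a CopyNumberMatrix from a raw array and chromosome lengths."""
    states = np.asarray(states)
    binning = GenomeBinning(chromosomes=tuple(chrom_lengths), bin_size=bin_size)
    return CopyNumberMatrix(
        binning=binning, states=states,
        cell_ids=[f"c{i}" for i in range(states.shape[0])],
        max_state=max_state)
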