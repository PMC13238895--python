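import numpy as np
import pytest

import cnvassay as ca


@pytest.fixture(scope="session")
def toy():
    return ca.toy_genome(seed=1)


@pytest.fixture(scope="session")
def grch38():
    return ca.grch38_genome(seed=11)


@pytest.fixture(scope="session")
def cell_line_truth(grch38):
    return ca.make_karyotype_profile(grch38, ca.CELL_LINE_KARYOTYPE, sample="cell_line")


@pytest.fixture(scope="session")
def cell_line_norm(cell_line_truth):
    """Normalized counts for the cell-line karyotype at depth 500, NB size 50."""
    counts = ca.simulate_bin_counts(
        cell_line_truth, mean_depth_per_diploid_bin=500, dispersion=50, seed=12)
    return ca.normalize_counts(counts, cell_line_truth.genome)


@pytest.fixture
def flat_gc_genome():
    """One 50 Mb chromosome with a constant GC track (no GC structure)."""
    g = ca.make_genome({"chrA": 50_000_000}, bin_width=500_000,
                       gc_model={"amplitude": 0.0, "noise_sd": 0.0, "base": 0.5}, seed=0)
    return g


def make_uniform_norm(genome, value=500.0):
    """NormalizedBins-like object built from constant values (helper)."""
    counts = ca.BinCounts(np.full(genome.n_bins, value), genome, sample="u")
    return ca.normalize_counts(counts, genome, target=value)
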