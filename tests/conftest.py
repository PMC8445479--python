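import numpy as np
import pytest

from islescan.sim import SimConfig, simulate_dataset
from islescan.types import GenotypeMatrix, make_marker_map


@pytest.fixture(scope="session")
def small_dataset():
    """Two populations, 4 chromosomes, 6k markers, planted locus + relatives."""
    cfg = SimConfig(
        n_pop1=50, n_pop2=50, n_chromosomes=4, markers_per_chromosome=1500,
        chrom_length_bp=60_000_000, fst_background=0.05,
        selected_loci=[("2", 30_000_000, 0.4)], missing_rate=0.01,
        n_planted_relative_pairs=3, seed=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def neutral_dataset():
    """No planted loci, no relatives, no missingness."""
    cfg = SimConfig(
        n_pop1=60, n_pop2=60, n_chromosomes=4, markers_per_chromosome=1250,
        chrom_length_bp=50_000_000, fst_background=0.05, selected_loci=[],
        missing_rate=0.0, n_planted_relative_pairs=0, seed=9,
    )
    return simulate_dataset(cfg)


def tiny_matrix(values, chrom=None, pos=None, allele_a="A", allele_b="B"):
    """Hand-built GenotypeMatrix with sequential marker positions."""
    values = np.asarray(values, dtype=np.int8)
    n, m = values.shape
    chrom = chrom if chrom is not None else ["1"] * m
    pos = pos if pos is not None else list(range(1, m + 1))
    markers = make_marker_map(
        [f"mk{j}" for j in range(m)], chrom, pos, allele_a, allele_b
    )
    return GenotypeMatrix(values, [f"s{i}" for i in range(n)], markers)
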