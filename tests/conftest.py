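import numpy as np
import pytest

from rostrum.seqio import MISSING, SnpMatrix
from rostrum.simulate import SimConfig, simulate_two_clade_alignment


@pytest.fixture
def small_noise_free():
    """Factory for small noise-free two-clade simulations."""

    def make(seed=1, n_west=4, n_east=4, n_diagnostic=5, n_private=3):
        cfg = SimConfig(
            genome_length=2000, n_west=n_west, n_east=n_east,
            n_diagnostic=n_diagnostic, n_private_per_clade=n_private,
            outgroup_divergence=20, miscall_rate=0.0, missing_rate=0.0,
            seed=seed,
        )
        return simulate_two_clade_alignment(cfg)

    return make


def make_matrix(genotypes, positions=None, outgroup_row=None, alleles=None):
    """Small biallelic SnpMatrix from a plain 0/1/-1 genotype list."""
    g = np.asarray(genotypes, dtype=int)
    n, s = g.shape
    if positions is None:
        positions = list(range(1, s + 1))
    if outgroup_row is None:
        outgroup_row = [0] * s
    if alleles is None:
        alleles = [["A", "G"] for _ in range(s)]
    return SnpMatrix(
        positions=np.asarray(positions),
        alleles=alleles,
        genotypes=g,
        specimen_ids=[f"s{i}" for i in range(n)],
        outgroup_id="og",
        outgroup_row=np.asarray(outgroup_row),
    )
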