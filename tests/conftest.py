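import numpy as np
import pandas as pd
import pytest

from scellcn import (
    Clone,
    CnEvent,
    ReadSimSpec,
    SimGenomeSpec,
    simulate_cell_reads,
    simulate_genome,
    simulate_tumor_truth,
)


@pytest.fixture(scope="session")
def dup_genome():
    """60 kb single-chromosome genome with a planted exact 5 kb duplication."""
    spec = SimGenomeSpec(
        n_chroms=1,
        chrom_length=60_000,
        planted_duplications=[("chr1", 10_000, 15_000, "chr1", 40_000)],
        seed=3,
    )
    genome, gc_truth = simulate_genome(spec)
    return genome, gc_truth, spec


@pytest.fixture(scope="session")
def small_cell():
    """A 2 x 1 Mb diploid-plus-gain cell with 20k simulated WGA reads."""
    spec = SimGenomeSpec(n_chroms=2, chrom_length=1_000_000, seed=1)
    genome, _ = simulate_genome(spec)
    lengths = {c: len(s) for c, s in genome.items()}
    truth = simulate_tumor_truth(
        lengths,
        [Clone("cell", 1.0, [CnEvent("chr1", 500_000, 1_000_000, "A", +1, "arm")])],
        seed=2,
    )
    reads, true_aln = simulate_cell_reads(
        genome, truth, "cell", ReadSimSpec(n_reads=20_000, seed=5)
    )
    return genome, truth, reads, true_aln
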