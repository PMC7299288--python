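import pytest

import homeoquant as hq


@pytest.fixture(scope="session")
def tiny_sim():
    """A small allotetraploid dataset with known read origins."""
    config = hq.SimConfig(
        n_genes=12, gene_length_range=(800, 1200), fragments_per_sample=4000,
        seed=7,
    )
    sim = hq.simulate_subgenomes(config)
    reads = hq.simulate_reads(sim)
    alignments = hq.project_alignments(reads, sim)
    return {
        "config": config,
        "sim": sim,
        "reads": reads,
        "alignments": alignments,
        "truth": reads.truth(sim),
        "catalog": sim.truth_catalog(),
    }


@pytest.fixture(scope="session")
def tiny_hex_sim():
    """A small allohexaploid dataset (three subgenomes)."""
    config = hq.SimConfig(
        n_genes=10, gene_length_range=(800, 1200), ploidy=3,
        fragments_per_sample=3000, seed=5,
    )
    sim = hq.simulate_subgenomes(config)
    reads = hq.simulate_reads(sim)
    alignments = hq.project_alignments(reads, sim)
    return {
        "config": config,
        "sim": sim,
        "reads": reads,
        "alignments": alignments,
        "truth": reads.truth(sim),
        "catalog": sim.truth_catalog(),
    }
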