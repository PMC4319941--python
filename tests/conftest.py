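import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from bactopan.align import ScoringScheme
from bactopan.io import GeneRecord
from bactopan.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def protein_scoring():
    return ScoringScheme.protein()


@pytest.fixture(scope="session")
def nuc_scoring():
    return ScoringScheme.nucleotide()


@pytest.fixture(scope="session")
def small_simulation():
    """Six genomes, moderate gain/loss, low divergence; shared by many tests."""
    config = SimulationConfig(
        n_genomes=6,
        ancestral_family_count=20,
        gain_rate=1.0,
        loss_rate=0.3,
        substitution_rate=0.03,
        mean_gene_length_aa=80,
        branch_scale=0.5,
        seed=3,
    )
    return simulate_dataset(config)


def simulation_genes(result) -> list[GeneRecord]:
    return [
        GeneRecord(gene_id, genome_id, genome.proteins[gene_id], genome.cds[gene_id])
        for genome_id, genome in sorted(result.genomes.items())
        for gene_id in sorted(genome.proteins)
    ]


@pytest.fixture(scope="session")
def small_simulation_genes(small_simulation):
    return simulation_genes(small_simulation)
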