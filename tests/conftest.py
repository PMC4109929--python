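import numpy as np
import pytest

from ecotypekit.genome_io import GeneFeature, GenomeRecord, assign_ranks, extract_proteome
from ecotypekit.homology import reciprocal_best_hits
from ecotypekit.simulate import (
    IslandSpec,
    SimulationConfig,
    evolve_pair,
    simulate_ancestor,
)


def make_genome(genome_id, contigs, features):
    """Tiny hand-built genome with ranks assigned."""
    g = GenomeRecord(genome_id, contigs, features)
    assign_ranks(g)
    return g


def cds(tag, contig, start, end, strand="+", product="hypothetical protein", protein=None):
    return GeneFeature(tag, contig, start, end, strand, "CDS", product, protein)


@pytest.fixture(scope="session")
def sim_pair():
    """Moderately diverged 150-gene pair with two planted islands and its
    truth; shared across test modules to amortize simulation cost."""
    cfg = SimulationConfig(
        seed=11,
        n_genes=150,
        divergence=0.05,
        islands=[
            IslandSpec(n_genes=6, delta_gc=-0.08, descendant="a"),
            IslandSpec(n_genes=5, delta_gc=0.08, descendant="b"),
        ],
        loss_events=2,
    )
    anc = simulate_ancestor(cfg)
    ga, gb, truth = evolve_pair(anc, cfg)
    return ga, gb, truth


@pytest.fixture(scope="session")
def sim_proteomes(sim_pair):
    ga, gb, _ = sim_pair
    return extract_proteome(ga), extract_proteome(gb)


@pytest.fixture(scope="session")
def sim_rbh(sim_proteomes):
    pa, pb = sim_proteomes
    return reciprocal_best_hits(pa, pb)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
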