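import numpy as np
import pytest

from ecotypekit.genome_io import GeneFeature, extract_proteome, gc_fraction
from ecotypekit.homology import RBHPair, reciprocal_best_hits
from ecotypekit.islands import (
    IslandConfig,
    build_synteny_map,
    call_islands,
    find_hotspots,
    gc_profile,
    unique_segments,
)
from ecotypekit.simulate import (
    IslandSpec,
    SimulationConfig,
    evolve_pair,
    simulate_ancestor,
)
from .conftest import cds, make_genome


def swap_rbh(rbh):
    return [RBHPair(p.locus_b, p.locus_a, p.pct_identity, p.min_cov, p.score) for p in rbh]


# ---------------------------------------------------------------------------
# gc_profile

def test_homogeneous_sequence_small_z(rng):
    seq = "".join(rng.choice(list("ACGT"), size=100_000))
    g = make_genome("g", [("c1", seq)], [])
    wins = gc_profile(g)
    assert max(abs(w.z) for w in wins) < 4.0


def test_planted_low_gc_segment_found(rng):
    host = "".join(rng.choice(list("ACGT"), size=100_000))
    p = [0.31, 0.19, 0.19, 0.31]  # GC 0.38
    insert = "".join(rng.choice(list("ACGT"), size=10_000, p=p))
    seq = host[:45_000] + insert + host[55_000:]
    g = make_genome("g", [("c1", seq)], [])
    wins = gc_profile(g)
    lowest = min(wins, key=lambda w: w.z)
    assert 45_000 - 5000 < lowest.start and lowest.end < 55_000 + 5000


def test_constant_composition_z_zero():
    g = make_genome("g", [("c1", "ACGT" * 5000)], [])
    wins = gc_profile(g)
    assert all(w.z == 0.0 for w in wins)


def test_short_contig_single_window():
    g = make_genome("g", [("c1", "ACGTACGT" * 100)], [])
    wins = gc_profile(g, window=5000)
    assert len(wins) == 1
    assert (wins[0].start, wins[0].end) == (0, 800)


def test_window_z_matches_direct_recomputation(rng):
    seq = "".join(rng.choice(list("ACGT"), size=60_000, p=[0.3, 0.2, 0.2, 0.3]))
    g = make_genome("g", [("c1", seq)], [])
    wins = gc_profile(g, window=5000, step=1000)
    gcs = np.array([gc_fraction(seq[w.start:w.end]) for w in wins])
    mean, sd = gcs.mean(), gcs.std(ddof=0)
    idx = rng.choice(len(wins), size=min(100, len(wins)), replace=False)
    for i in idx:
        w = wins[i]
        assert w.gc == pytest.approx(gcs[i])
        assert w.z == pytest.approx((gcs[i] - mean) / sd)


# ---------------------------------------------------------------------------
# unique segments

def test_identical_genomes_no_unique_segments(sim_pair, sim_proteomes):
    ga, _, _ = sim_pair
    pa, _ = sim_proteomes
    rbh = reciprocal_best_hits(pa, pa)
    assert unique_segments(ga, ga, rbh) == []


def test_inserted_cassette_is_single_run(rng):
    # host genes present in both genomes; 8-gene cassette only in A
    seqs = {}
    feats_a, feats_b = [], []
    pos_a = pos_b = 0
    prot = lambda: "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=49))
    rbh = []
    n_host = 10
    host_prots = [prot() for _ in range(n_host)]
    cassette = [prot() for _ in range(8)]
    contig_a, contig_b = [], []
    for i, p in enumerate(host_prots[:5]):
        feats_a.append(cds(f"a{i}", "ca", pos_a, pos_a + 150, protein=p))
        pos_a += 200
    for j, p in enumerate(cassette):
        feats_a.append(cds(f"ins{j}", "ca", pos_a, pos_a + 150, protein=p))
        pos_a += 200
    for i, p in enumerate(host_prots[5:], start=5):
        feats_a.append(cds(f"a{i}", "ca", pos_a, pos_a + 150, protein=p))
        pos_a += 200
    for i, p in enumerate(host_prots):
        feats_b.append(cds(f"b{i}", "cb", pos_b, pos_b + 150, protein=p))
        pos_b += 200
    ga = make_genome("A", [("ca", "A" * pos_a)], feats_a)
    gb = make_genome("B", [("cb", "A" * pos_b)], feats_b)
    rbh = [RBHPair(f"a{i}", f"b{i}", 100.0, 1.0) for i in range(n_host)]
    runs = unique_segments(ga, gb, rbh)
    assert len(runs) == 1
    assert runs[0] == [f"ins{j}" for j in range(8)]


def test_short_unique_runs_discarded(rng):
    feats_a = []
    prots = ["M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=30)) for _ in range(5)]
    for i, p in enumerate(prots):
        feats_a.append(cds(f"a{i}", "ca", i * 200, i * 200 + 150, protein=p))
    ga = make_genome("A", [("ca", "A" * 1200)], feats_a)
    gb = make_genome("B", [("cb", "A" * 1200)],
                     [cds(f"b{i}", "cb", i * 200, i * 200 + 150, protein=prots[i])
                      for i in (0, 2, 3, 4)])
    rbh = [RBHPair(f"a{i}", f"b{i}", 100.0, 1.0) for i in (0, 2, 3, 4)]
    assert unique_segments(ga, gb, rbh, min_island_genes=3) == []
    assert len(unique_segments(ga, gb, rbh, min_island_genes=1)) == 1


def test_simulated_insert_recall():
    specs = [
        IslandSpec(n_genes=n, delta_gc=-0.08, descendant="a")
        for n in (4, 7, 12, 18, 25, 30)
    ]
    cfg = SimulationConfig(seed=41, n_genes=200, divergence=0.03, islands=specs,
                           loss_events=4, trna_every=20)
    anc = simulate_ancestor(cfg)
    ga, gb, truth = evolve_pair(anc, cfg)
    pa, pb = extract_proteome(ga), extract_proteome(gb)
    rbh = reciprocal_best_hits(pa, pb)
    runs = unique_segments(ga, gb, rbh)
    true_sets = [set(t.gene_loci) for t in truth.islands if t.genome_id == ga.genome_id]
    recovered = sum(
        1 for ts in true_sets
        if any(len(ts & set(r)) / max(len(ts), len(r)) >= 0.5 for r in runs)
    )
    assert recovered >= 5  # recall >= 5/6 against truth


# ---------------------------------------------------------------------------
# synteny map

def test_synteny_single_block_for_identical_order():
    feats_a = [cds(f"a{i}", "ca", i * 200, i * 200 + 150) for i in range(6)]
    feats_b = [cds(f"b{i}", "cb", i * 200, i * 200 + 150) for i in range(6)]
    ga = make_genome("A", [("ca", "A" * 1200)], feats_a)
    gb = make_genome("B", [("cb", "A" * 1200)], feats_b)
    rbh = [RBHPair(f"a{i}", f"b{i}", 100.0, 1.0) for i in range(6)]
    sm = build_synteny_map(ga, gb, rbh)
    assert len(sm.blocks) == 1
    assert sm.n_breaks == 0


def test_synteny_break_on_translocation():
    feats_a = [cds(f"a{i}", "ca", i * 200, i * 200 + 150) for i in range(8)]
    feats_b = [cds(f"b{i}", "cb", i * 200, i * 200 + 150) for i in range(8)]
    ga = make_genome("A", [("ca", "A" * 1700)], feats_a)
    gb = make_genome("B", [("cb", "A" * 1700)], feats_b)
    # A ranks 0..7 map to B ranks 0,1,2,3, then jump to 7,6,5,4 (inversion)
    mapping = [0, 1, 2, 3, 7, 6, 5, 4]
    rbh = [RBHPair(f"a{i}", f"b{mapping[i]}", 100.0, 1.0) for i in range(8)]
    sm = build_synteny_map(ga, gb, rbh)
    assert sm.n_breaks >= 1


# ---------------------------------------------------------------------------
# call_islands

@pytest.fixture(scope="module")
def planted_pair():
    specs = [
        IslandSpec(n_genes=8, delta_gc=-0.10, with_trna_flank=True,
                   with_recombinase=True, descendant="a"),
    ]
    cfg = SimulationConfig(seed=42, n_genes=120, divergence=0.02, islands=specs)
    anc = simulate_ancestor(cfg)
    ga, gb, truth = evolve_pair(anc, cfg)
    pa, pb = extract_proteome(ga), extract_proteome(gb)
    rbh = reciprocal_best_hits(pa, pb)
    return ga, gb, truth, rbh


def test_planted_island_reported_with_signatures(planted_pair):
    ga, gb, truth, rbh = planted_pair
    islands = call_islands(ga, gb, rbh)
    assert len(islands) == 1
    isl = islands[0]
    true_isl = truth.islands[0]
    assert set(isl.gene_loci) == set(true_isl.gene_loci)
    assert isl.trna_flank in ("left", "both")
    assert isl.has_recombinase
    assert isl.gc_z < 0  # planted at delta -0.10


def test_uncorroborated_segment_suppressed(rng):
    # unique segment with neutral GC, no tRNA anywhere, no recombinase
    prot = lambda: "M" + "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=49))
    host = [prot() for _ in range(10)]
    cassette = [prot() for _ in range(4)]
    seq_a = "".join(rng.choice(list("ACGT"), size=(10 + 4) * 200))
    feats_a = []
    idx = 0
    tags_host = []
    for k, p in enumerate(host[:5]):
        feats_a.append(cds(f"h{k}", "ca", idx, idx + 150, protein=p)); idx += 200
        tags_host.append(f"h{k}")
    for k, p in enumerate(cassette):
        feats_a.append(cds(f"u{k}", "ca", idx, idx + 150, protein=p)); idx += 200
    for k, p in enumerate(host[5:], start=5):
        feats_a.append(cds(f"h{k}", "ca", idx, idx + 150, protein=p)); idx += 200
        tags_host.append(f"h{k}")
    ga = make_genome("A", [("ca", seq_a)], feats_a)
    gb = make_genome(
        "B", [("cb", seq_a)],
        [cds(f"p{k}", "cb", k * 200, k * 200 + 150, protein=host[k]) for k in range(10)],
    )
    rbh = [RBHPair(f"h{k}", f"p{k}", 100.0, 1.0) for k in range(10)]
    cfg = IslandConfig(z_min=2.0)
    assert call_islands(ga, gb, rbh, config=cfg) == []
    relaxed = IslandConfig(require_corroboration=False)
    assert len(call_islands(ga, gb, rbh, config=relaxed)) == 1


def test_islands_disjoint_and_partnerless(planted_pair):
    ga, gb, truth, rbh = planted_pair
    islands = call_islands(ga, gb, rbh)
    partnered = {p.locus_a for p in rbh}
    seen = set()
    for isl in islands:
        for tag in isl.gene_loci:
            assert tag not in partnered
            assert tag not in seen
            seen.add(tag)


def test_island_machinery_symmetric(sim_pair, sim_proteomes, sim_rbh):
    ga, gb, _ = sim_pair
    isl_ab = call_islands(ga, gb, sim_rbh)
    isl_ba = call_islands(gb, ga, swap_rbh(sim_rbh))
    # swapping roles swaps the lists
    isl_ab2 = call_islands(gb, ga, swap_rbh(sim_rbh))
    isl_ba2 = call_islands(ga, gb, sim_rbh)
    assert [i.gene_loci for i in isl_ab] == [i.gene_loci for i in isl_ba2]
    assert [i.gene_loci for i in isl_ba] == [i.gene_loci for i in isl_ab2]
    spots1 = find_hotspots(isl_ab, isl_ba)
    spots2 = find_hotspots(isl_ba, isl_ab)
    assert len(spots1) == len(spots2)
    assert sum(s.both_occupied for s in spots1) == sum(s.both_occupied for s in spots2)


# ---------------------------------------------------------------------------
# hot spots

def test_no_islands_no_hotspots():
    assert find_hotspots([], []) == []


def test_hotspot_from_shared_gap():
    cfg = SimulationConfig(seed=43, n_genes=150, divergence=0.02, hotspot_pairs=1)
    anc = simulate_ancestor(cfg)
    ga, gb, truth = evolve_pair(anc, cfg)
    pa, pb = extract_proteome(ga), extract_proteome(gb)
    rbh = reciprocal_best_hits(pa, pb)
    isl_a = call_islands(ga, gb, rbh)
    isl_b = call_islands(gb, ga, swap_rbh(rbh))
    spots = find_hotspots(isl_a, isl_b)
    occupied = [s for s in spots if s.both_occupied]
    assert len(occupied) == 1
    # non-orthologous inserts: no gene of one island pairs with the other
    partnered = {p.locus_a for p in rbh} | {p.locus_b for p in rbh}
    assert not (set(occupied[0].island_a.gene_loci) & partnered)
    assert not (set(occupied[0].island_b.gene_loci) & partnered)


def test_shared_cassette_is_not_an_island(rng):
    # same cassette in both genomes => orthologous => no unique segment
    cfg = SimulationConfig(seed=44, n_genes=100, divergence=0.02)
    anc = simulate_ancestor(cfg)
    ga, gb, _ = evolve_pair(anc, cfg)
    pa, pb = extract_proteome(ga), extract_proteome(gb)
    rbh = reciprocal_best_hits(pa, pb)
    assert call_islands(ga, gb, rbh) == []
    assert call_islands(gb, ga, swap_rbh(rbh)) == []
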