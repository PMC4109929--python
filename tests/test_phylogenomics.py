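import math

import numpy as np
import pytest

from ecotypekit.genome_io import Proteome
from ecotypekit.phylogenomics import (
    MSA,
    ConcatenatedAlignment,
    NoSCGOError,
    PhylogenomicsError,
    align_group,
    bootstrap_support,
    build_ortholog_groups,
    concatenate,
    distance_matrix,
    neighbor_joining_from_array,
    select_scgo,
)
from ._oracles import distances_from_tree

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_protein(rng, n):
    return "".join(rng.choice(list(AA), size=n))


def mutate(rng, s, rate):
    return "".join(c if rng.random() > rate else AA[int(rng.integers(20))] for c in s)


# ---------------------------------------------------------------------------
# ortholog groups / SCGO

def _family_proteomes(rng, n_genomes=3, n_families=2, rate=0.05):
    base = [random_protein(rng, 60) for _ in range(n_families)]
    proteomes = []
    for g in range(n_genomes):
        entries = [
            (f"g{g}_f{f}", mutate(rng, base[f], rate)) for f in range(n_families)
        ]
        proteomes.append(Proteome(f"g{g}", entries))
    return proteomes


def test_two_families_three_genomes(rng):
    proteomes = _family_proteomes(rng)
    groups = build_ortholog_groups(proteomes)
    assert len(groups) == 2
    assert all(g.single_copy for g in groups)


def test_duplication_breaks_single_copy(rng):
    proteomes = _family_proteomes(rng)
    dup_entries = proteomes[0].entries + [("g0_dup", mutate(rng, proteomes[0].entries[0][1], 0.02))]
    proteomes[0] = Proteome("g0", dup_entries)
    groups = build_ortholog_groups(proteomes)
    by_size = sorted(groups, key=lambda g: -sum(map(len, g.members.values())))
    assert not by_size[0].single_copy
    assert by_size[1].single_copy


def test_groups_match_simulator_family_truth():
    from ecotypekit.genome_io import extract_proteome
    from ecotypekit.simulate import SimulationConfig, evolve_set, simulate_ancestor

    cfg = SimulationConfig(seed=31, n_genes=50, divergence=0.04, family_duplications=5)
    anc = simulate_ancestor(cfg)
    genomes, family_maps = evolve_set(anc, 4)
    proteomes = [extract_proteome(g) for g in genomes]
    groups = build_ortholog_groups(proteomes)
    # every group's members must map to a single ancestor family
    for g in groups:
        fams = {
            family_maps[gid][tag] for gid, tags in g.members.items() for tag in tags
        }
        assert len(fams) == 1
    assert len(groups) == 50
    n_single = sum(1 for g in groups if g.single_copy)
    assert n_single == 45  # 5 duplicated families are multi-copy


def test_select_scgo_all_single(rng):
    proteomes = _family_proteomes(rng)
    groups = build_ortholog_groups(proteomes)
    assert select_scgo(groups, {p.genome_id for p in proteomes}) == groups


def test_select_scgo_excludes_missing_genome(rng):
    proteomes = _family_proteomes(rng, n_genomes=3, n_families=3)
    # remove family 2 from genome 2
    proteomes[2] = Proteome("g2", proteomes[2].entries[:2])
    groups = build_ortholog_groups(proteomes)
    kept = select_scgo(groups, {"g0", "g1", "g2"})
    assert len(kept) == 2


def test_select_scgo_empty_raises(rng):
    proteomes = _family_proteomes(rng, n_genomes=2, n_families=1)
    groups = build_ortholog_groups(proteomes)
    with pytest.raises(NoSCGOError):
        select_scgo(groups, {"g0", "g1", "g_absent"})


def test_scgo_count_monotone_in_genome_set():
    from ecotypekit.genome_io import extract_proteome
    from ecotypekit.simulate import SimulationConfig, evolve_set, simulate_ancestor

    cfg = SimulationConfig(seed=32, n_genes=40, divergence=0.05, loss_events=3)
    anc = simulate_ancestor(cfg)
    genomes, _ = evolve_set(anc, 4)
    proteomes = [extract_proteome(g) for g in genomes]
    counts = []
    for k in (2, 3, 4):
        sub = proteomes[:k]
        groups = build_ortholog_groups(sub)
        counts.append(sum(1 for g in groups if g.is_single_copy({p.genome_id for p in sub})))
    assert counts[0] >= counts[1] >= counts[2]


# ---------------------------------------------------------------------------
# alignment

def test_identical_sequences_align_gap_free(rng):
    s = random_protein(rng, 40)
    msa = align_group({"a": s, "b": s, "c": s})
    assert msa.ncols == 40
    assert all(row == s for row in msa.rows.values())


def test_two_sequence_alignment_matches_pairwise_dp(rng):
    a = random_protein(rng, 50)
    b = mutate(rng, a, 0.1)
    msa = align_group({"x": a, "y": b})
    assert msa.ungapped("x") == a
    assert msa.ungapped("y") == b
    assert msa.ncols == 50  # equal-length mutated copies align column-wise


def test_internal_deletion_yields_single_gap_run(rng):
    a = random_protein(rng, 60)
    b = a[:30] + a[33:]  # 3-aa internal deletion
    msa = align_group({"full": a, "del": b})
    row = msa.rows["del"]
    assert row.count("-") == 3
    gap_start = row.index("-")
    assert row[gap_start:gap_start + 3] == "---"
    assert "-" not in row[:gap_start] and "-" not in row[gap_start + 3:]


def test_single_sequence_msa():
    msa = align_group({"only": "MKLV"})
    assert msa.rows == {"only": "MKLV"}


def test_ungap_round_trip(rng):
    seqs = {f"s{i}": mutate(rng, random_protein(rng, 45), 0.15) for i in range(5)}
    msa = align_group(seqs)
    for sid, s in seqs.items():
        assert msa.ungapped(sid) == s


# ---------------------------------------------------------------------------
# concatenation

def test_concatenate_two_groups():
    msas = {
        "g1": MSA({"x1": "A" * 10, "y1": "C" * 10}, 10),
        "g2": MSA({"x2": "D" * 20, "y2": "E" * 20}, 20),
    }
    locus_map = {"x1": "GA", "y1": "GB", "x2": "GA", "y2": "GB"}
    concat = concatenate(msas, locus_map)
    assert concat.ncols == 30
    assert concat.partitions == [("g1", 0, 10), ("g2", 10, 30)]
    assert concat.rows["GA"] == "A" * 10 + "D" * 20


def test_concatenate_single_group_is_identity():
    msa = MSA({"x": "MK-L", "y": "MKAL"}, 4)
    concat = concatenate({"g1": msa}, {"x": "GX", "y": "GY"})
    assert concat.rows == {"GX": "MK-L", "GY": "MKAL"}


def test_concatenate_missing_genome_errors():
    msas = {
        "g1": MSA({"x1": "AA", "y1": "CC"}, 2),
        "g2": MSA({"x2": "DD"}, 2),
    }
    with pytest.raises(PhylogenomicsError, match="g2"):
        concatenate(msas, {"x1": "GA", "y1": "GB", "x2": "GA"})


def test_partition_slice_reproduces_group_msa(rng):
    msas = {}
    locus_map = {}
    for k in range(4):
        a = random_protein(rng, 20)
        b = mutate(rng, a, 0.1)
        msas[f"og{k}"] = align_group({f"xa{k}": a, f"xb{k}": b})
        locus_map[f"xa{k}"] = "GA"
        locus_map[f"xb{k}"] = "GB"
    concat = concatenate(msas, locus_map)
    for k in range(4):
        sl = concat.slice(f"og{k}")
        src = msas[f"og{k}"]
        assert sl.rows["GA"] == src.rows[f"xa{k}"]
        assert sl.rows["GB"] == src.rows[f"xb{k}"]


# ---------------------------------------------------------------------------
# distances

def test_identical_rows_distance_zero():
    aln = ConcatenatedAlignment({"a": "MKLV", "b": "MKLV"}, [("g", 0, 4)])
    _, dm = distance_matrix(aln, "p_distance")
    assert dm[0, 1] == 0.0


def test_p_distance_forced_value():
    row_a = "A" * 90 + "C" * 10
    row_b = "A" * 90 + "D" * 10
    aln = ConcatenatedAlignment({"a": row_a, "b": row_b}, [("g", 0, 100)])
    _, dm = distance_matrix(aln, "p_distance")
    assert dm[0, 1] == pytest.approx(0.10)


def test_poisson_correction_closed_form():
    row_a = "A" * 90 + "C" * 10
    row_b = "A" * 90 + "D" * 10
    aln = ConcatenatedAlignment({"a": row_a, "b": row_b}, [("g", 0, 100)])
    _, dm = distance_matrix(aln, "poisson_corrected")
    assert dm[0, 1] == pytest.approx(-math.log(0.9), abs=1e-9)
    assert dm[0, 1] == pytest.approx(0.10536, abs=1e-4)


def test_saturated_distance_capped_with_warning():
    aln = ConcatenatedAlignment({"a": "AAAA", "b": "CCCC"}, [("g", 0, 4)])
    with pytest.warns(UserWarning, match="saturated"):
        _, dm = distance_matrix(aln, "poisson_corrected")
    assert dm[0, 1] == 10.0


def test_gap_columns_excluded():
    aln = ConcatenatedAlignment({"a": "MK--AV", "b": "MKLLAV"}, [("g", 0, 6)])
    _, dm = distance_matrix(aln, "p_distance")
    assert dm[0, 1] == 0.0


# ---------------------------------------------------------------------------
# neighbor joining

def test_nj_three_taxa_closed_form():
    # d(ab)=3, d(ac)=5, d(bc)=6 => la=1, lb=2, lc=4
    dm = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    tree = neighbor_joining_from_array(dm, ["a", "b", "c"])
    lengths = {l.name: l.length for l in tree.root.leaves()}
    assert lengths == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})


def test_nj_additive_four_taxa_exact():
    # tree ((a:1,b:2):3,(c:4,d:5)) with internal edge 3
    edges = [("r", "u", 3.0), ("u", "a", 1.0), ("u", "b", 2.0),
             ("r", "c", 4.0), ("r", "d", 5.0)]
    leaves = ["a", "b", "c", "d"]
    dist = distances_from_tree(edges, leaves)
    dm = np.array([[dist[(x, y)] for y in leaves] for x in leaves])
    tree = neighbor_joining_from_array(dm, leaves)
    assert frozenset({"a", "b"}) in tree.splits() or frozenset({"c", "d"}) in tree.splits()
    # branch lengths recovered: leaf path lengths reproduce the matrix
    recovered = _tree_distances(tree)
    for x in leaves:
        for y in leaves:
            assert recovered[(x, y)] == pytest.approx(dist[(x, y)], abs=1e-9)


def _tree_distances(tree):
    edges = []
    counter = [0]

    def walk(node, name):
        for c in node.children:
            if c.children:
                counter[0] += 1
                cname = f"__i{counter[0]}"
            else:
                cname = c.name
            edges.append((name, cname, c.length))
            walk(c, cname)

    walk(tree.root, "__root")
    leaves = [l.name for l in tree.root.leaves()]
    return distances_from_tree(edges, leaves)


def test_nj_recovers_random_additive_six_taxon_trees(rng):
    leaves = [f"t{i}" for i in range(6)]
    for trial in range(10):
        # random binary topology by sequential attachment
        edges = [("n0", "t0", 0), ("n0", "t1", 0), ("n0", "t2", 0)]
        internal = ["n0"]
        for k in range(3, 6):
            # split a random existing edge with a new internal node
            ei = int(rng.integers(len(edges)))
            p, c, _ = edges.pop(ei)
            nn = f"n{k - 2}"
            internal.append(nn)
            edges.extend([(p, nn, 0), (nn, c, 0), (nn, f"t{k}", 0)])
        edges = [(p, c, float(rng.uniform(0.05, 1.0))) for p, c, _ in edges]
        dist = distances_from_tree(edges, leaves)
        dm = np.array([[dist[(x, y)] for y in leaves] for x in leaves])
        tree = neighbor_joining_from_array(dm, leaves)
        true_splits = _splits_from_edges(edges, leaves)
        assert tree.splits() == true_splits, f"trial {trial}"


def _splits_from_edges(edges, leaves):
    import collections

    adj = collections.defaultdict(list)
    for p, c, _ in edges:
        adj[p].append(c)
        adj[c].append(p)
    ref = min(leaves)
    splits = set()
    for p, c, _ in edges:
        # leaves on the c side of edge (p, c)
        seen = {p, c}
        stack = [c]
        side = set()
        while stack:
            node = stack.pop()
            if node in leaves:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        if 1 < len(side) < len(leaves) - 1:
            side = frozenset(side) if ref not in side else frozenset(set(leaves) - side)
            splits.add(frozenset(side))
    return splits


def test_nj_too_few_taxa():
    with pytest.raises(PhylogenomicsError):
        neighbor_joining_from_array(np.zeros((2, 2)), ["a", "b"])


def test_nj_clade_split_from_simulated_divergence():
    # two 4-clades: tiny within-clade distance, huge between
    ids = [f"x{i}" for i in range(4)] + [f"y{i}" for i in range(4)]
    dm = np.zeros((8, 8))
    for i in range(8):
        for j in range(8):
            if i == j:
                continue
            same = (i < 4) == (j < 4)
            dm[i, j] = 0.05 + 0.01 * abs(i - j) if same else 2.0 + 0.01 * abs(i - j)
    tree = neighbor_joining_from_array(dm, ids)
    assert frozenset({"y0", "y1", "y2", "y3"}) in tree.splits()


# ---------------------------------------------------------------------------
# bootstrap

def _two_clade_alignment(rng, n_per_clade=4, ncols=200, within=0.02, between=0.4):
    base = "".join(rng.choice(list(AA), size=ncols))
    other = "".join(
        c if rng.random() > between else AA[int(rng.integers(20))] for c in base
    )
    rows = {}
    for i in range(n_per_clade):
        rows[f"x{i}"] = "".join(
            c if rng.random() > within else AA[int(rng.integers(20))] for c in base
        )
        rows[f"y{i}"] = "".join(
            c if rng.random() > within else AA[int(rng.integers(20))] for c in other
        )
    return ConcatenatedAlignment(rows, [("all", 0, ncols)])


def test_bootstrap_central_split_support_100(rng):
    concat = _two_clade_alignment(rng)
    tree = bootstrap_support(concat, n_reps=100, seed=5)
    supports = {}

    def collect(node):
        for c in node.children:
            if c.children and c.support is not None:
                leafset = frozenset(l.name for l in c.leaves())
                supports[leafset] = c.support
            collect(c)

    collect(tree.root)
    central = [
        s for ls, s in supports.items()
        if {n[0] for n in ls} in ({"x"}, {"y"}) and len(ls) == 4
    ]
    assert central and all(s == 100.0 for s in central)


def test_bootstrap_seed_stability(rng):
    concat = _two_clade_alignment(rng, ncols=120)
    t1 = bootstrap_support(concat, n_reps=100, seed=1)
    t2 = bootstrap_support(concat, n_reps=100, seed=1)
    assert t1.to_newick() == t2.to_newick()  # same seed => identical


def test_bootstrap_supports_stable_across_seeds(rng):
    # moderate signal so supports are informative but not saturated
    concat = _two_clade_alignment(rng, n_per_clade=3, ncols=100,
                                  within=0.12, between=0.25)

    def supports(seed):
        tree = bootstrap_support(concat, n_reps=500, seed=seed)
        out = {}

        def collect(node):
            for c in node.children:
                if c.children and c.support is not None:
                    out[frozenset(l.name for l in c.leaves())] = c.support
                collect(c)

        collect(tree.root)
        return out

    s1, s2 = supports(1), supports(2)
    assert s1.keys() == s2.keys()
    for k in s1:
        assert abs(s1[k] - s2[k]) <= 5.0


def test_star_alignment_supports_below_100(rng):
    # all rows independently random: no phylogenetic signal
    rows = {
        f"t{i}": "".join(rng.choice(list(AA), size=150)) for i in range(6)
    }
    concat = ConcatenatedAlignment(rows, [("all", 0, 150)])
    tree = bootstrap_support(concat, n_reps=100, seed=2)
    sup = []

    def collect(node):
        for c in node.children:
            if c.children and c.support is not None:
                sup.append(c.support)
            collect(c)

    collect(tree.root)
    assert sup and all(s < 100.0 for s in sup)
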