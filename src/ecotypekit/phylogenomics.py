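"""Ortholog grouping, single-copy ortholog selection, progressive multiple
alignment, concatenation with partitions, distance trees and bootstrap.

Markov clustering of a BLAST graph is replaced by connected components of
the thresholded cross-genome RBH graph; maximum-likelihood tree search is
replaced by neighbor joining on Poisson-corrected distances, with relaxed
PHYLIP + partition export for external ML.
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from collections import Counter, defaultdict

import numpy as np

from ._kernels import AA_INDEX, BLOSUM62, encode_protein, nw_profile
from .genome_io import Proteome
from .homology import GAP_EXTEND, GAP_OPEN, reciprocal_best_hits


class PhylogenomicsError(ValueError):
    pass


class NoSCGOError(PhylogenomicsError):
    """No single-copy-per-genome ortholog group: a tree cannot be built."""


# ---------------------------------------------------------------------------
# ortholog groups

@dataclasses.dataclass
class OrthologGroup:
    group_id: str
    members: dict[str, list[str]]  # genome_id -> locus_tags

    def is_single_copy(self, genome_set: set[str]) -> bool:
        return set(self.members) == set(genome_set) and all(
            len(v) == 1 for v in self.members.values()
        )

    @property
    def single_copy(self) -> bool:
        # relative to the genomes recorded at construction time
        return getattr(self, "_single_copy", False)


def build_ortholog_groups(
    proteomes: list[Proteome],
    min_identity: float = 50.0,
    min_cov: float = 0.70,
    search: str = "auto",
) -> list[OrthologGroup]:
    """Connected components of the thresholded homology graph.

    Edges are cross-genome RBH pairs plus within-genome pairs that meet the
    same identity/coverage thresholds (so recent in-paralogs join their
    family's group and mark it multi-copy). Deterministic: group ids follow
    the sorted order of each component's member list.
    """
    if len(proteomes) < 2:
        raise PhylogenomicsError("need at least two proteomes")
    genome_ids = [p.genome_id for p in proteomes]
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x, y):
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    for p in proteomes:
        for tag, _ in p.entries:
            node = (p.genome_id, tag)
            parent[node] = node
    for pa, pb in itertools.combinations(proteomes, 2):
        for pair in reciprocal_best_hits(pa, pb, min_identity, min_cov, search):
            union((pa.genome_id, pair.locus_a), (pb.genome_id, pair.locus_b))
    for p in proteomes:
        for la, lb in _within_genome_pairs(p, min_identity, min_cov, search):
            union((p.genome_id, la), (p.genome_id, lb))

    comps: dict[tuple[str, str], list[tuple[str, str]]] = defaultdict(list)
    for node in parent:
        comps[find(node)].append(node)
    # drop singletons (genes with no cross-genome partner)
    comp_lists = sorted(
        (sorted(nodes) for nodes in comps.values() if len(nodes) > 1)
    )
    groups = []
    width = max(5, len(str(len(comp_lists))))
    gset = set(genome_ids)
    for i, nodes in enumerate(comp_lists, 1):
        members: dict[str, list[str]] = defaultdict(list)
        for gid, tag in nodes:
            members[gid].append(tag)
        g = OrthologGroup(f"OG{i:0{width}d}", dict(members))
        g._single_copy = g.is_single_copy(gset)
        groups.append(g)
    return groups


def _within_genome_pairs(proteome, min_identity, min_cov, search):
    """Locus pairs inside one genome passing the thresholds (in-paralogs)."""
    from .homology import _pair_scores
    from ._kernels import sw_traceback
    import numpy as np

    tags, seqs, _tags2, _seqs2, scores = _pair_scores(proteome, proteome, search)
    # cheap prefilter: a pair at >= 50% identity over >= 70% coverage scores
    # a large fraction of the smaller self-score; random pairs score ~3%
    selfs = [int(BLOSUM62[s, s].sum()) for s in seqs]
    out = []
    for (ia, jb), sc in scores.items():
        if ia >= jb or sc <= 0:
            continue
        if sc < 0.25 * min(selfs[ia], selfs[jb]):
            continue
        r = sw_traceback(seqs[ia], seqs[jb], BLOSUM62, GAP_OPEN, GAP_EXTEND)
        cols = r[6]
        if cols == 0:
            continue
        ident = 100.0 * r[5] / cols
        cov = min(
            int(np.sum(r[7] >= 0)) / len(seqs[ia]),
            int(np.sum(r[8] >= 0)) / len(seqs[jb]),
        )
        if ident >= min_identity and cov >= min_cov:
            out.append((tags[ia], tags[jb]))
    return out


def select_scgo(groups: list[OrthologGroup], genome_set: set[str]) -> list[OrthologGroup]:
    """Groups with exactly one member in every genome of ``genome_set``."""
    out = [g for g in groups if g.is_single_copy(set(genome_set))]
    if not out:
        raise NoSCGOError("no single-copy-per-genome ortholog groups found")
    return out


# ---------------------------------------------------------------------------
# multiple alignment

@dataclasses.dataclass
class MSA:
    rows: dict[str, str]
    ncols: int

    def __post_init__(self) -> None:
        for sid, row in self.rows.items():
            if len(row) != self.ncols:
                raise PhylogenomicsError(f"row {sid} has length {len(row)} != {self.ncols}")

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")


def _kmer_distance(seqs: list[str], k: int = 3) -> np.ndarray:
    """1 - fraction of shared k-mers (over the smaller k-mer multiset)."""
    counters = [Counter(s[i:i + k] for i in range(len(s) - k + 1)) for s in seqs]
    n = len(seqs)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = sum((counters[i] & counters[j]).values())
            denom = min(sum(counters[i].values()), sum(counters[j].values()))
            d = 1.0 - shared / denom if denom else 1.0
            dm[i, j] = dm[j, i] = d
    return dm


def _profile(rows: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Residue-frequency profile of gapped int-coded rows (-1 = gap).
    Returns (freq (ncols, 22) over non-gap residues, occupancy (ncols,))."""
    arr = np.stack(rows)
    ncols = arr.shape[1]
    freq = np.zeros((ncols, 22))
    for c in range(ncols):
        col = arr[:, c]
        res = col[col >= 0]
        if res.size:
            counts = np.bincount(res, minlength=22)
            freq[c] = counts / res.size
    occ = (arr >= 0).mean(axis=0)
    return freq, occ


def _merge(rows_a: list[np.ndarray], rows_b: list[np.ndarray]):
    fa, oa = _profile(rows_a)
    fb, ob = _profile(rows_b)
    M = (fa @ BLOSUM62.astype(float) @ fb.T) * np.outer(oa, ob)
    _score, pa, pb = nw_profile(M, float(GAP_OPEN), float(GAP_EXTEND))
    out_a = []
    for row in rows_a:
        out_a.append(np.array([row[i] if i >= 0 else -1 for i in pa], dtype=np.int8))
    out_b = []
    for row in rows_b:
        out_b.append(np.array([row[j] if j >= 0 else -1 for j in pb], dtype=np.int8))
    return out_a + out_b


_IDX_TO_AA = {v: k for k, v in AA_INDEX.items()}


def align_group(sequences: dict[str, str]) -> MSA:
    """Progressive alignment along an NJ guide tree built from 3-mer
    distances; profile-profile merges use BLOSUM62 sum-of-pairs scores with
    affine gaps. Deterministic."""
    ids = sorted(sequences)
    if len(ids) == 0:
        raise PhylogenomicsError("no sequences")
    if len(ids) == 1:
        s = sequences[ids[0]]
        return MSA({ids[0]: s}, len(s))
    seqs = [sequences[i] for i in ids]
    coded = [encode_protein(s) for s in seqs]
    if len(ids) == 2:
        merged = _merge([coded[0]], [coded[1]])
        order = [[0], [1]]
    else:
        dm = _kmer_distance(seqs)
        tree = neighbor_joining_from_array(dm, ids)
        merged, order = _progressive(tree, ids, coded)
    flat = [i for grp in order for i in grp]
    rows = {}
    for pos, i in enumerate(flat):
        rows[ids[i]] = "".join(
            "-" if c < 0 else _IDX_TO_AA[int(c)] for c in merged[pos]
        )
    ncols = len(merged[0]) if merged else 0
    return MSA(rows, ncols)


def _progressive(tree, ids, coded):
    index = {name: i for i, name in enumerate(ids)}

    def walk(node):
        if not node.children:
            i = index[node.name]
            return [np.asarray(coded[i], dtype=np.int8)], [[i]]
        sub = [walk(c) for c in node.children]
        rows, order = sub[0]
        for r2, o2 in sub[1:]:
            rows = _merge(rows, r2)
            order = [order + o2][0]
        return rows, order

    rows, order = walk(tree.root)
    return rows, order


# ---------------------------------------------------------------------------
# concatenation

@dataclasses.dataclass
class ConcatenatedAlignment:
    rows: dict[str, str]  # genome_id -> gapped sequence
    partitions: list[tuple[str, int, int]]  # (group_id, col_start, col_end) half-open

    @property
    def ncols(self) -> int:
        return self.partitions[-1][2] if self.partitions else 0

    def slice(self, group_id: str) -> "MSA":
        for gid, start, end in self.partitions:
            if gid == group_id:
                return MSA({g: s[start:end] for g, s in self.rows.items()}, end - start)
        raise KeyError(group_id)


def concatenate(
    msas: dict[str, MSA], genome_of_locus: dict[str, str]
) -> ConcatenatedAlignment:
    """Join per-group MSAs in sorted group_id order, one row per genome."""
    genome_rows: dict[str, list[str]] = None
    partitions = []
    col = 0
    for group_id in sorted(msas):
        msa = msas[group_id]
        per_genome = {}
        for sid, row in msa.rows.items():
            gid = genome_of_locus.get(sid, sid)
            if gid in per_genome:
                raise PhylogenomicsError(
                    f"group {group_id}: genome {gid} appears more than once"
                )
            per_genome[gid] = row
        if genome_rows is None:
            genome_rows = {g: [] for g in per_genome}
        if set(per_genome) != set(genome_rows):
            missing = set(genome_rows) ^ set(per_genome)
            raise PhylogenomicsError(
                f"group {group_id}: genome set mismatch (offending: {sorted(missing)})"
            )
        for g, row in per_genome.items():
            genome_rows[g].append(row)
        partitions.append((group_id, col, col + msa.ncols))
        col += msa.ncols
    if genome_rows is None:
        raise PhylogenomicsError("no alignments to concatenate")
    return ConcatenatedAlignment(
        {g: "".join(parts) for g, parts in genome_rows.items()}, partitions
    )


# ---------------------------------------------------------------------------
# distances

DIST_CAP = 10.0


def distance_matrix(alignment, model: str = "poisson_corrected"):
    """Pairwise distances over columns where both rows are non-gap.

    Models: ``p_distance`` (mismatch fraction) and ``poisson_corrected``
    (-ln(1 - p), capped at DIST_CAP with a warning when p >= 1).
    Returns (ids, matrix).
    """
    if model not in ("p_distance", "poisson_corrected"):
        raise PhylogenomicsError(f"unknown model {model!r}")
    rows = alignment.rows if hasattr(alignment, "rows") else dict(alignment)
    ids = sorted(rows)
    if len(ids) < 2:
        raise PhylogenomicsError("need >= 2 rows")
    arrs = {}
    for i in ids:
        a = np.frombuffer(rows[i].encode(), dtype=np.uint8)
        arrs[i] = a
    n = len(ids)
    dm = np.zeros((n, n))
    gap = ord("-")
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            both = (a != gap) & (b != gap)
            shared = int(both.sum())
            if shared == 0:
                p = 1.0
            else:
                p = float(np.sum((a != b) & both)) / shared
            if model == "p_distance":
                d = p
            else:
                if p >= 1.0 - 1e-12:
                    warnings.warn(
                        f"saturated distance between {ids[i]} and {ids[j]}; capped"
                    )
                    d = DIST_CAP
                else:
                    d = min(-np.log(1.0 - p), DIST_CAP)
            dm[i, j] = dm[j, i] = d
    return ids, dm


# ---------------------------------------------------------------------------
# trees

@dataclasses.dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list = dataclasses.field(default_factory=list)

    def leaves(self):
        if not self.children:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out


@dataclasses.dataclass
class PhyloTree:
    root: TreeNode

    def leaf_names(self) -> list[str]:
        return sorted(l.name for l in self.root.leaves())

    def splits(self) -> set[frozenset]:
        """Non-trivial unrooted bipartitions, each canonicalized as the side
        not containing the lexicographically first leaf."""
        all_leaves = set(self.leaf_names())
        ref = min(all_leaves)
        out = set()

        def walk(node):
            if not node.children:
                return {node.name}
            below = set()
            for c in node.children:
                below |= walk(c)
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                out.add(frozenset(side))
            return below

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def fmt(node):
            if not node.children:
                return f"{node.name}:{node.length:.9f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if node.support is not None:
                label = f"{node.support:g}"
            elif node.name:
                label = node.name
            return f"({inner}){label}:{node.length:.9f}"

        inner = ",".join(fmt(c) for c in self.root.children)
        label = f"{self.root.support:g}" if self.root.support is not None else ""
        return f"({inner}){label};"

    @classmethod
    def from_newick(cls, s: str) -> "PhyloTree":
        import dendropy

        dt = dendropy.Tree.get(data=s, schema="newick", suppress_internal_node_taxa=True)

        def conv(dn):
            node = TreeNode(
                name=dn.taxon.label if dn.taxon else None,
                length=dn.edge.length or 0.0,
            )
            if dn.label is not None:
                try:
                    node.support = float(dn.label)
                except ValueError:
                    node.name = dn.label
            node.children = [conv(c) for c in dn.child_nodes()]
            return node

        return cls(conv(dt.seed_node))


def neighbor_joining_from_array(dm: np.ndarray, ids: list[str]) -> PhyloTree:
    """Standard NJ with deterministic tie-breaking (lowest index pair).

    Negative branch lengths are clamped to 0 and the deficit moved to the
    sibling edge, preserving the path length between the joined leaves.
    """
    n = len(ids)
    if n < 3:
        raise PhylogenomicsError("neighbor joining needs n >= 3 taxa")
    if dm.shape != (n, n) or not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise PhylogenomicsError("distance matrix must be symmetric with zero diagonal")
    nodes = [TreeNode(name=i) for i in ids]
    D = dm.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima, scanning row-major
        flat = np.argmin(Q)
        qmin = Q.flat[flat]
        cand = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        cand = [tuple(c) for c in cand if c[0] < c[1]]
        ai, aj = min(cand)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += -li
            li = 0.0
        if lj < 0:
            li += -lj
            lj = 0.0
        nodes[i].length = li
        nodes[j].length = lj
        new = TreeNode(children=[nodes[i], nodes[j]])
        newdist = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newdist[k] = 0.5 * (D[i, k] + D[j, k] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newdist[:-1]
        D[:-1, -1] = newdist[:-1]
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]
    # join final three on a root trifurcation
    i, j, k = active
    di = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    dj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    dk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    for node, d in ((nodes[i], di), (nodes[j], dj), (nodes[k], dk)):
        node.length = max(d, 0.0)
    root = TreeNode(children=[nodes[i], nodes[j], nodes[k]])
    return PhyloTree(root)


def neighbor_joining(dm, ids: list[str] | None = None) -> PhyloTree:
    if ids is None:
        ids, dm = dm  # allow passing the (ids, matrix) tuple directly
    return neighbor_joining_from_array(np.asarray(dm, dtype=float), list(ids))


def bootstrap_support(
    concat: ConcatenatedAlignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson_corrected",
) -> PhyloTree:
    """NJ tree from the full alignment with internal-edge supports = % of
    column-resampled replicates containing each split. One RNG stream per
    replicate, derived from the seed by fixed offsets."""
    ids, dm = distance_matrix(concat, model)
    tree = neighbor_joining_from_array(dm, ids)
    ncols = concat.ncols
    mats = {g: np.frombuffer(s.encode(), dtype=np.uint8) for g, s in concat.rows.items()}
    counts: dict[frozenset, int] = defaultdict(int)
    target = tree.splits()
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(0, ncols, size=ncols)
        rows = {g: bytes(arr[cols]).decode() for g, arr in mats.items()}
        rep_aln = ConcatenatedAlignment(rows, [("all", 0, ncols)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rids, rdm = distance_matrix(rep_aln, model)
        rtree = neighbor_joining_from_array(rdm, rids)
        for split in rtree.splits():
            if split in target:
                counts[split] += 1

    def annotate(node, all_leaves, ref):
        if not node.children:
            return {node.name}
        below = set()
        for c in node.children:
            below |= annotate(c, all_leaves, ref)
        if 1 < len(below) < len(all_leaves) - 1:
            side = below if ref not in below else all_leaves - below
            node.support = 100.0 * counts[frozenset(side)] / n_reps
        return below

    all_leaves = set(tree.leaf_names())
    annotate(tree.root, all_leaves, min(all_leaves))
    return tree


def write_groups_tsv(groups: list[OrthologGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("group_id\tsingle_copy\tgenome_id\tlocus_tags\n")
        for g in groups:
            for gid in sorted(g.members):
                fh.write(
                    f"{g.group_id}\t{int(g.single_copy)}\t{gid}\t"
                    + ",".join(sorted(g.members[gid]))
                    + "\n"
                )
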