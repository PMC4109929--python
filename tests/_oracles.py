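"""Independent brute-force oracles, deliberately separate from the package
implementation: plain-Python dynamic programming with the substitution
matrix loaded from Biopython."""

from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")

NEG = float("-inf")


def blosum62(a: str, b: str) -> int:
    try:
        return int(_B62[a, b])
    except (KeyError, IndexError):
        return 0 if "X" in (a, b) else -4


def sw_affine_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Affine-gap local alignment score; opening a gap of length k costs
    gap_open + (k-1)*gap_extend."""
    m, n = len(a), len(b)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0.0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + blosum62(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return int(best)


def best_hits_oracle(entries_a, entries_b, gap_open=11, gap_extend=1):
    """{query_tag: set of best-scoring subject tags} by exhaustive scoring."""
    out = {}
    for tag_a, seq_a in entries_a:
        scores = {tag_b: sw_affine_score(seq_a, seq_b, gap_open, gap_extend)
                  for tag_b, seq_b in entries_b}
        top = max(scores.values())
        out[tag_a] = {t for t, s in scores.items() if s == top and s > 0}
    return out


def rbh_oracle(entries_a, entries_b):
    """Reciprocal unique-best-hit pairs by exhaustive search (pairs with
    score ties on either side are excluded as non-unique)."""
    ab = best_hits_oracle(entries_a, entries_b)
    ba = best_hits_oracle(entries_b, entries_a)
    pairs = set()
    for ta, hits in ab.items():
        if len(hits) != 1:
            continue
        tb = next(iter(hits))
        if ba.get(tb) == {ta}:
            pairs.add((ta, tb))
    return pairs


def global_identity_oracle(a: str, b: str, match=2, mismatch=-3, gap_open=5, gap_extend=2):
    """End-gap-free global alignment of nucleotide strings; returns percent
    identity over aligned columns excluding terminal-gap columns."""
    m, n = len(a), len(b)

    def s(x, y):
        if x == "N" or y == "N":
            return 0
        return match if x == y else mismatch

    H = [[NEG] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    P = [[None] * (n + 1) for _ in range(m + 1)]
    H[0][0] = 0.0
    for j in range(1, n + 1):
        H[0][j] = 0.0  # free leading gap in a
        P[0][j] = ("E", 0, j - 1)
    for i in range(1, m + 1):
        H[i][0] = 0.0
        P[i][0] = ("F", i - 1, 0)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open)
            e = E[i][j]
            f = F[i][j]
            if i == m:  # free trailing gap in a
                e = max(e, H[i][j - 1], E[i][j - 1])
                E[i][j] = e
            if j == n:  # free trailing gap in b
                f = max(f, H[i - 1][j], F[i - 1][j])
                F[i][j] = f
            d = H[i - 1][j - 1] + s(a[i - 1], b[j - 1])
            H[i][j] = max(d, e, f)
            if H[i][j] == d:
                P[i][j] = ("D", i - 1, j - 1)
            elif H[i][j] == e:
                P[i][j] = ("E", i, j - 1)
            else:
                P[i][j] = ("F", i - 1, j)
    # traceback for columns
    cols = []
    i, j = m, n
    while i > 0 or j > 0:
        kind, pi, pj = P[i][j]
        if kind == "D":
            cols.append((a[i - 1], b[j - 1]))
        elif kind == "E":
            cols.append(("-", b[j - 1]))
        else:
            cols.append((a[i - 1], "-"))
        i, j = pi, pj
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and "-" in cols[lo]:
        lo += 1
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    inner = cols[lo:hi]
    if not inner:
        return 0.0
    matches = sum(1 for x, y in inner if x == y and x != "-")
    return 100.0 * matches / len(inner)


def distances_from_tree(newick_like_edges, leaves):
    """Leaf-to-leaf path-length matrix from an edge list
    [(parent, child, length)] — oracle for NJ additive recovery."""
    import collections

    adj = collections.defaultdict(list)
    for p, c, w in newick_like_edges:
        adj[p].append((c, w))
        adj[c].append((p, w))
    import heapq

    dm = {}
    for src in leaves:
        dist = {src: 0.0}
        heap = [(0.0, src)]
        while heap:
            d, node = heapq.heappop(heap)
            if d > dist.get(node, float("inf")):
                continue
            for nb, w in adj[node]:
                nd = d + w
                if nd < dist.get(nb, float("inf")):
                    dist[nb] = nd
                    heapq.heappush(heap, (nd, nb))
        for dst in leaves:
            dm[(src, dst)] = dist[dst]
    return dm
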