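"""Numba-compiled dynamic-programming kernels for pairwise alignment.

All kernels operate on integer-encoded sequences (amino acids via
:data:`AA_ORDER`, nucleotides via :data:`NT_ORDER`) and are deterministic:
traceback ties are resolved in the fixed order diagonal > up (gap in
subject) > left (gap in query), and the best local cell is the first
maximum encountered scanning rows then columns.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Amino-acid alphabet: 20 canonical residues plus X (unknown) and * (stop).
AA_ORDER = "ARNDCQEGHILKMFPSTWYVX*"
AA_INDEX = {c: i for i, c in enumerate(AA_ORDER)}

NT_ORDER = "ACGTN"
NT_INDEX = {c: i for i, c in enumerate(NT_ORDER)}

NEG_INF = np.int32(-(10**8))

# BLOSUM62 over AA_ORDER (rows/cols in that order), X scored 0 vs
# everything except itself (-1), stop -4 vs everything (1 vs itself).
_BLOSUM62_TXT = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0  0 -4
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3 -1 -4
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3 -1 -4
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3 -1 -4
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1 -2 -4
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2 -1 -4
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2 -1 -4
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3 -1 -4
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3 -1 -4
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3 -1 -4
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1 -1 -4
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2 -1 -4
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1 -1 -4
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1 -1 -4
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2 -2 -4
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2  0 -4
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0  0 -4
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3 -2 -4
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -3 -1 -4
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -3  4 -1 -4
 0 -1 -1 -1 -2 -1 -1 -1 -1 -1 -1 -1 -1 -1 -2  0  0 -2 -1 -1 -1 -4
-4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4 -4  1
"""

BLOSUM62 = np.array(
    [[int(v) for v in row.split()] for row in _BLOSUM62_TXT.strip().splitlines()],
    dtype=np.int32,
)
assert BLOSUM62.shape == (22, 22)
assert np.array_equal(BLOSUM62, BLOSUM62.T)


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string to int8 codes; raises on bad symbols."""
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        code = AA_INDEX.get(c)
        if code is None:
            raise ValueError(f"non-amino-acid symbol {c!r} at position {i}")
        out[i] = code
    return out


def encode_nucleotide(seq: str) -> np.ndarray:
    out = np.empty(len(seq), dtype=np.int8)
    for i, c in enumerate(seq.upper()):
        code = NT_INDEX.get(c, 4)  # anything ambiguous -> N
        out[i] = code
    return out


@njit(cache=True)
def sw_score(a, b, submat, gap_open, gap_extend):  # pragma: no cover - jit
    """Score-only affine-gap Smith-Waterman. gap_open is the open+first-
    extend cost (BLAST convention: opening a gap of length k costs
    gap_open + (k-1)*gap_extend)."""
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    E = np.full(n + 1, NEG_INF, dtype=np.int32)
    best = np.int32(0)
    for i in range(1, m + 1):
        diag = np.int32(0)
        F = NEG_INF
        Hi_prev = np.int32(0)  # H[i][0]
        ai = a[i - 1]
        for j in range(1, n + 1):
            E[j] = max(E[j] - gap_extend, H[j] - gap_open)
            F = max(F - gap_extend, Hi_prev - gap_open)
            h = diag + submat[ai, b[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = np.int32(0)
            diag = H[j]
            H[j] = h
            Hi_prev = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def sw_score_batch(query, subjects_flat, offsets, submat, gap_open, gap_extend):
    """Scores of one query against many subjects (concatenated, with
    offsets[k]..offsets[k+1] delimiting subject k)."""
    nsub = offsets.shape[0] - 1
    out = np.zeros(nsub, dtype=np.int32)
    for k in range(nsub):
        out[k] = sw_score(
            query, subjects_flat[offsets[k]:offsets[k + 1]], submat, gap_open, gap_extend
        )
    return out


@njit(cache=True)
def sw_traceback(a, b, submat, gap_open, gap_extend):  # pragma: no cover - jit
    """Full affine Smith-Waterman with traceback.

    Returns (score, a_start, a_end, b_start, b_end, matches, aligned_cols,
    a_aligned, b_aligned) where ends are exclusive, matches counts identical
    residue pairs and aligned_cols counts columns including internal gaps.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    # pointer codes for H: 0 stop, 1 diag, 2 from E (gap in a / left), 3 from F (gap in b / up)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    # ptrE/ptrF: 1 = extend existing gap, 0 = open from H
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_ext = E[i, j - 1] - gap_extend
            e_open = H[i, j - 1] - gap_open
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_ext = F[i - 1, j] - gap_extend
            f_open = H[i - 1, j] - gap_open
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            h = np.int32(0)
            p = np.uint8(0)
            if d > h:
                h = d
                p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            H[i, j] = h
            ptrH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    # traceback from (bi, bj)
    a_aln = np.empty(m + n, dtype=np.int8)
    b_aln = np.empty(m + n, dtype=np.int8)
    pos = 0
    matches = 0
    i = bi
    j = bj
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    while i > 0 and j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 0:
                break
            if p == 1:
                a_aln[pos] = a[i - 1]
                b_aln[pos] = b[j - 1]
                if a[i - 1] == b[j - 1]:
                    matches += 1
                pos += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            a_aln[pos] = -1
            b_aln[pos] = b[j - 1]
            pos += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            a_aln[pos] = a[i - 1]
            b_aln[pos] = -1
            pos += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return best, i, bi, j, bj, matches, pos, a_aln[:pos][::-1], b_aln[:pos][::-1]


@njit(cache=True)
def nw_profile(M, gap_open, gap_extend):  # pragma: no cover - jit
    """Global affine-gap DP over a precomputed column-pair score matrix M
    (m x n, float64). Returns (score, path_a, path_b) where path arrays hold
    the source column index or -1 for a gap, in alignment order."""
    m, n = M.shape
    NEGF = -1e30
    H = np.full((m + 1, n + 1), NEGF)
    E = np.full((m + 1, n + 1), NEGF)
    F = np.full((m + 1, n + 1), NEGF)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, 0] = 0.0
    for j in range(1, n + 1):
        E[0, j] = -gap_open - (j - 1) * gap_extend
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1
    for i in range(1, m + 1):
        F[i, 0] = -gap_open - (i - 1) * gap_extend
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 3
        ptrF[i, 0] = 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_ext = E[i, j - 1] - gap_extend
            e_open = H[i, j - 1] - gap_open
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            f_ext = F[i - 1, j] - gap_extend
            f_open = H[i - 1, j] - gap_open
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            d = H[i - 1, j - 1] + M[i - 1, j - 1]
            h = d
            p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            H[i, j] = h
            ptrH[i, j] = p
    path_a = np.empty(m + n, dtype=np.int64)
    path_b = np.empty(m + n, dtype=np.int64)
    pos = 0
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                path_a[pos] = i - 1
                path_b[pos] = j - 1
                pos += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            path_a[pos] = -1
            path_b[pos] = j - 1
            pos += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            path_a[pos] = i - 1
            path_b[pos] = -1
            pos += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return H[m, n], path_a[:pos][::-1], path_b[:pos][::-1]


@njit(cache=True)
def nw_global(a, b, submat, gap_open, gap_extend, free_ends):  # pragma: no cover
    """Affine-gap global alignment; with ``free_ends`` terminal gaps in
    either sequence are unpenalized (semi-global / end-gap-free).

    Returns (score, matches, aligned_cols_total, a_aln, b_aln) over the full
    alignment including terminal gap columns.
    """
    m = a.shape[0]
    n = b.shape[0]
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG_INF, dtype=np.int32)
    ptrH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    H[0, 0] = 0
    for j in range(1, n + 1):
        if free_ends:
            E[0, j] = 0
            H[0, j] = 0
        else:
            E[0, j] = -gap_open - (j - 1) * gap_extend
            H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1
    for i in range(1, m + 1):
        if free_ends:
            F[i, 0] = 0
            H[i, 0] = 0
        else:
            F[i, 0] = -gap_open - (i - 1) * gap_extend
            H[i, 0] = F[i, 0]
        ptrH[i, 0] = 3
        ptrF[i, 0] = 1
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            e_ext = E[i, j - 1] - gap_extend
            e_open = H[i, j - 1] - gap_open
            if e_ext > e_open:
                E[i, j] = e_ext
                ptrE[i, j] = 1
            else:
                E[i, j] = e_open
            # free terminal gaps along the bottom row
            if free_ends and i == m and H[i, j - 1] > E[i, j]:
                E[i, j] = H[i, j - 1]
                ptrE[i, j] = 0
            if free_ends and i == m and E[i, j - 1] > E[i, j]:
                E[i, j] = E[i, j - 1]
                ptrE[i, j] = 1
            f_ext = F[i - 1, j] - gap_extend
            f_open = H[i - 1, j] - gap_open
            if f_ext > f_open:
                F[i, j] = f_ext
                ptrF[i, j] = 1
            else:
                F[i, j] = f_open
            if free_ends and j == n and H[i - 1, j] > F[i, j]:
                F[i, j] = H[i - 1, j]
                ptrF[i, j] = 0
            if free_ends and j == n and F[i - 1, j] > F[i, j]:
                F[i, j] = F[i - 1, j]
                ptrF[i, j] = 1
            d = H[i - 1, j - 1] + submat[ai, b[j - 1]]
            h = d
            p = np.uint8(1)
            if F[i, j] > h:
                h = F[i, j]
                p = np.uint8(3)
            if E[i, j] > h:
                h = E[i, j]
                p = np.uint8(2)
            H[i, j] = h
            ptrH[i, j] = p
    # traceback from (m, n)
    a_aln = np.empty(m + n, dtype=np.int8)
    b_aln = np.empty(m + n, dtype=np.int8)
    pos = 0
    matches = 0
    i = m
    j = n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if p == 1:
                a_aln[pos] = a[i - 1]
                b_aln[pos] = b[j - 1]
                if a[i - 1] == b[j - 1]:
                    matches += 1
                pos += 1
                i -= 1
                j -= 1
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            a_aln[pos] = -1
            b_aln[pos] = b[j - 1]
            pos += 1
            if ptrE[i, j] == 0:
                state = 0
            j -= 1
        else:
            a_aln[pos] = a[i - 1]
            b_aln[pos] = -1
            pos += 1
            if ptrF[i, j] == 0:
                state = 0
            i -= 1
    return H[m, n], matches, pos, a_aln[:pos][::-1], b_aln[:pos][::-1]
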