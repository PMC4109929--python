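"""Pairwise protein homology: local alignment, reciprocal best hits, AAI,
and 16S rRNA pairwise identity.

BLASTP is replaced by exact affine-gap Smith-Waterman under BLOSUM62
(open 11, extend 1). Identity follows the BLAST convention: matches over
aligned columns including internal gaps. For large proteome pairs an exact
search over all pairs is prohibitively slow, so candidate subjects are
prescreened by shared 4-mer counts; below ``EXHAUSTIVE_LIMIT`` query*subject
pairs the search is exhaustive and bit-identical to the brute-force oracle.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict

import numpy as np

from ._kernels import (
    BLOSUM62,
    encode_nucleotide,
    encode_protein,
    nw_global,
    sw_score_batch,
    sw_traceback,
)
from .genome_io import Proteome

GAP_OPEN = 11
GAP_EXTEND = 1

# Search is exhaustive whenever n_query * n_subject <= this.
EXHAUSTIVE_LIMIT = 10_000
SEED_K = 4
SEED_TOP = 25
SEED_MIN_COUNT = 3  # candidates below this shared-4-mer count compete only for the top few
SEED_KEEP_ALWAYS = 2

# AAI thresholds (per the cited AAI protocol); SCGO selection uses 50/0.70.
AAI_MIN_IDENTITY = 30.0
AAI_MIN_COV = 0.70


class HomologyError(ValueError):
    pass


class NoSharedGenesError(HomologyError):
    """Raised when no RBH pair passes the thresholds; AAI is undefined."""


@dataclasses.dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    score: int
    pct_identity: float
    aln_len: int
    qcov: float
    scov: float


@dataclasses.dataclass(frozen=True)
class RBHPair:
    locus_a: str
    locus_b: str
    pct_identity: float
    min_cov: float
    score: int = 0


@dataclasses.dataclass
class AAIResult:
    genome_a: str
    genome_b: str
    aai: float
    n_pairs: int
    sd_identity: float


def local_align(
    seq_a: str,
    seq_b: str,
    query_id: str = "query",
    subject_id: str = "subject",
    gap_open: int = GAP_OPEN,
    gap_extend: int = GAP_EXTEND,
) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein sequences."""
    if not seq_a or not seq_b:
        raise HomologyError("empty sequence")
    a = encode_protein(seq_a)
    b = encode_protein(seq_b)
    score, _ai, _aj, _bi, _bj, matches, cols, a_aln, b_aln = sw_traceback(
        a, b, BLOSUM62, gap_open, gap_extend
    )
    if cols == 0:
        return AlignmentResult(query_id, subject_id, 0, 0.0, 0, 0.0, 0.0)
    q_res = int(np.sum(a_aln >= 0))
    s_res = int(np.sum(b_aln >= 0))
    return AlignmentResult(
        query_id=query_id,
        subject_id=subject_id,
        score=int(score),
        pct_identity=100.0 * matches / cols,
        aln_len=int(cols),
        qcov=q_res / len(seq_a),
        scov=s_res / len(seq_b),
    )


def _encode_proteome(proteome: Proteome):
    tags = [t for t, _ in proteome.entries]
    seqs = [encode_protein(s) for _, s in proteome.entries]
    flat = np.concatenate(seqs) if seqs else np.empty(0, dtype=np.int8)
    offsets = np.zeros(len(seqs) + 1, dtype=np.int64)
    offsets[1:] = np.cumsum([len(s) for s in seqs])
    return tags, seqs, flat, offsets


def _seed_candidates(seqs_a, seqs_b, k: int = SEED_K, top: int = SEED_TOP):
    """For each a, the subjects in B sharing the most k-mers (top-``top``,
    ties at the cut included). The shared-seed relation is symmetric, so the
    same sparse counts serve both directions."""
    index: dict[bytes, list[int]] = defaultdict(list)
    for jb, s in enumerate(seqs_b):
        sb = s.tobytes()
        seen = set()
        for p in range(len(sb) - k + 1):
            kmer = sb[p:p + k]
            if kmer not in seen:
                seen.add(kmer)
                index[kmer].append(jb)
    cand_counts: list[dict[int, int]] = []
    for sa in seqs_a:
        counts: dict[int, int] = defaultdict(int)
        ba = sa.tobytes()
        seen = set()
        for p in range(len(ba) - k + 1):
            kmer = ba[p:p + k]
            if kmer in seen:
                continue
            seen.add(kmer)
            for jb in index.get(kmer, ()):
                counts[jb] += 1
        cand_counts.append(counts)
    lens_a = [len(s) for s in seqs_a]
    lens_b = [len(s) for s in seqs_b]

    def select(ordered, len_self, lens_other):
        """ordered = [(count, partner)] desc. Keep the top ``top`` whose
        shared-k-mer count clears a length-adaptive background threshold
        (mean chance count + 4 sd under a Poisson model), plus the top
        SEED_KEEP_ALWAYS unconditionally."""
        chosen = {p for _, p in ordered[:SEED_KEEP_ALWAYS]}
        kept = 0
        for c, p in ordered:
            if kept >= top:
                break
            mu = len_self * lens_other[p] / (20.0 ** k)
            if c >= max(SEED_MIN_COUNT, mu + 4.0 * mu ** 0.5):
                chosen.add(p)
                kept += 1
        return chosen

    pairs: set[tuple[int, int]] = set()
    by_subject: dict[int, list[tuple[int, int]]] = defaultdict(list)
    for ia, counts in enumerate(cand_counts):
        ordered = sorted(((c, jb) for jb, c in counts.items()), key=lambda kv: (-kv[0], kv[1]))
        for jb in select(ordered, lens_a[ia], lens_b):
            pairs.add((ia, jb))
        for jb, c in counts.items():
            by_subject[jb].append((c, ia))
    for jb, lst in by_subject.items():
        lst.sort(key=lambda kv: (-kv[0], kv[1]))
        for ia in select(lst, lens_b[jb], lens_a):
            pairs.add((ia, jb))
    return pairs


def _pair_scores(proteome_a: Proteome, proteome_b: Proteome, search: str = "auto"):
    """Sparse score map {(ia, jb): score}. One orientation per unordered
    pair is computed (scores are symmetric under a symmetric matrix)."""
    tags_a, seqs_a, flat_a, off_a = _encode_proteome(proteome_a)
    tags_b, seqs_b, flat_b, off_b = _encode_proteome(proteome_b)
    na, nb = len(seqs_a), len(seqs_b)
    if search == "auto":
        search = "exhaustive" if na * nb <= EXHAUSTIVE_LIMIT else "seed"
    scores: dict[tuple[int, int], int] = {}
    if search == "exhaustive":
        for ia in range(na):
            row = sw_score_batch(seqs_a[ia], flat_b, off_b, BLOSUM62, GAP_OPEN, GAP_EXTEND)
            for jb in range(nb):
                scores[(ia, jb)] = int(row[jb])
    elif search == "seed":
        pairs = _seed_candidates(seqs_a, seqs_b)
        by_query: dict[int, list[int]] = defaultdict(list)
        for ia, jb in pairs:
            by_query[ia].append(jb)
        for ia, jbs in by_query.items():
            jbs.sort()
            sub_flat = np.concatenate([seqs_b[j] for j in jbs])
            sub_off = np.zeros(len(jbs) + 1, dtype=np.int64)
            sub_off[1:] = np.cumsum([len(seqs_b[j]) for j in jbs])
            row = sw_score_batch(seqs_a[ia], sub_flat, sub_off, BLOSUM62, GAP_OPEN, GAP_EXTEND)
            for jb, sc in zip(jbs, row):
                scores[(ia, jb)] = int(sc)
    else:
        raise HomologyError(f"unknown search mode {search!r}")
    return tags_a, seqs_a, tags_b, seqs_b, scores


def _best_hits(scores, n_query, axis, tags_other):
    """Unique best subject per query along the given axis; ties broken by
    higher score then (after alignment detail upstream) smallest tag.
    Returns {query_index: [tied subject indices with max score]}."""
    best: dict[int, list[int]] = defaultdict(list)
    best_score: dict[int, int] = {}
    for (ia, jb), sc in scores.items():
        q, s = (ia, jb) if axis == 0 else (jb, ia)
        cur = best_score.get(q)
        if cur is None or sc > cur:
            best_score[q] = sc
            best[q] = [s]
        elif sc == cur:
            best[q].append(s)
    return best, best_score


def reciprocal_best_hits(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_identity: float = 50.0,
    min_cov: float = 0.70,
    search: str = "auto",
) -> list[RBHPair]:
    """RBH pairs meeting identity/coverage thresholds.

    A pair (a, b) qualifies iff b is a's unique best-scoring hit in B and
    vice versa (score ties resolved by higher identity then lexicographically
    smallest partner tag), pct_identity >= min_identity and
    min(qcov, scov) >= min_cov.
    """
    if not proteome_a.entries or not proteome_b.entries:
        raise HomologyError("empty proteome")
    tags_a, seqs_a, tags_b, seqs_b, scores = _pair_scores(proteome_a, proteome_b, search)

    def resolve(best_list, tags, seq_q, seqs_o):
        if len(best_list) == 1:
            return best_list[0]
        # score tie: higher identity, then smallest partner locus_tag
        ranked = []
        for s in best_list:
            r = sw_traceback(seq_q, seqs_o[s], BLOSUM62, GAP_OPEN, GAP_EXTEND)
            ident = r[5] / r[6] if r[6] else 0.0
            ranked.append((-ident, tags[s], s))
        ranked.sort()
        return ranked[0][2]

    best_ab, _ = _best_hits(scores, len(seqs_a), 0, tags_b)
    best_ba, _ = _best_hits(scores, len(seqs_b), 1, tags_a)
    pairs: list[RBHPair] = []
    for ia, blist in best_ab.items():
        jb = resolve(blist, tags_b, seqs_a[ia], seqs_b)
        alist = best_ba.get(jb, [])
        if not alist:
            continue
        back = resolve(alist, tags_a, seqs_b[jb], seqs_a)
        if back != ia:
            continue
        if scores[(ia, jb)] <= 0:
            continue
        r = sw_traceback(seqs_a[ia], seqs_b[jb], BLOSUM62, GAP_OPEN, GAP_EXTEND)
        score, _i0, _i1, _j0, _j1, matches, cols = r[:7]
        if cols == 0:
            continue
        ident = 100.0 * matches / cols
        qres = int(np.sum(r[7] >= 0))
        sres = int(np.sum(r[8] >= 0))
        cov = min(qres / len(seqs_a[ia]), sres / len(seqs_b[jb]))
        if ident >= min_identity and cov >= min_cov:
            pairs.append(RBHPair(tags_a[ia], tags_b[jb], ident, cov, int(score)))
    pairs.sort(key=lambda p: (p.locus_a, p.locus_b))
    return pairs


def compute_aai(
    proteome_a: Proteome,
    proteome_b: Proteome,
    min_identity: float = AAI_MIN_IDENTITY,
    min_cov: float = AAI_MIN_COV,
    search: str = "auto",
) -> AAIResult:
    """Average amino-acid identity: unweighted mean percent identity over
    qualifying reciprocal-best-hit pairs. Symmetric by construction."""
    pairs = reciprocal_best_hits(proteome_a, proteome_b, min_identity, min_cov, search)
    if not pairs:
        raise NoSharedGenesError(
            f"no shared genes between {proteome_a.genome_id} and {proteome_b.genome_id}: "
            "AAI undefined"
        )
    idents = np.array([p.pct_identity for p in pairs])
    return AAIResult(
        genome_a=proteome_a.genome_id,
        genome_b=proteome_b.genome_id,
        aai=float(np.mean(idents)),
        n_pairs=len(pairs),
        sd_identity=float(np.std(idents, ddof=1)) if len(pairs) > 1 else 0.0,
    )


def aai_matrix(proteomes: list[Proteome], search: str = "auto"):
    """Square AAI matrix over a genome set (100 on the diagonal; NaN where
    AAI is undefined)."""
    import pandas as pd

    ids = [p.genome_id for p in proteomes]
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i in range(len(proteomes)):
        for j in range(i + 1, len(proteomes)):
            try:
                res = compute_aai(proteomes[i], proteomes[j], search=search)
                val = res.aai
            except NoSharedGenesError:
                val = math.nan
            mat.iloc[i, j] = val
            mat.iloc[j, i] = val
    return mat


NT_MATCH = 2
NT_MISMATCH = -3
_NT_MATRIX = np.full((5, 5), NT_MISMATCH, dtype=np.int32)
np.fill_diagonal(_NT_MATRIX, NT_MATCH)
_NT_MATRIX[4, :] = 0  # N scores 0 vs everything
_NT_MATRIX[:, 4] = 0
_NT_MATRIX[4, 4] = 0


class PartialGeneWarning(HomologyError):
    pass


def rrna_identity(seq16s_a: str, seq16s_b: str, min_len: int = 500) -> float:
    """Percent identity from an end-gap-free global nucleotide alignment;
    terminal-gap columns are excluded from the denominator."""
    if len(seq16s_a) < min_len or len(seq16s_b) < min_len:
        raise PartialGeneWarning(
            f"16S sequence shorter than {min_len} nt ({len(seq16s_a)}, {len(seq16s_b)}): "
            "likely a partial gene"
        )
    a = encode_nucleotide(seq16s_a)
    b = encode_nucleotide(seq16s_b)
    _score, matches, cols, a_aln, b_aln = nw_global(a, b, _NT_MATRIX, 5, 2, True)
    # trim terminal gap columns
    lo, hi = 0, cols
    while lo < hi and (a_aln[lo] < 0 or b_aln[lo] < 0):
        lo += 1
    while hi > lo and (a_aln[hi - 1] < 0 or b_aln[hi - 1] < 0):
        hi -= 1
    inner = hi - lo
    if inner == 0:
        return 0.0
    inner_matches = int(
        np.sum((a_aln[lo:hi] == b_aln[lo:hi]) & (a_aln[lo:hi] >= 0))
    )
    return 100.0 * inner_matches / inner


def rrna_identity_matrix(seqs: dict[str, str]):
    import pandas as pd

    ids = sorted(seqs)
    mat = pd.DataFrame(100.0, index=ids, columns=ids)
    for i, ga in enumerate(ids):
        for gb in ids[i + 1:]:
            val = rrna_identity(seqs[ga], seqs[gb])
            mat.loc[ga, gb] = val
            mat.loc[gb, ga] = val
    return mat


def write_rbh_tsv(pairs: list[RBHPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("locus_a\tlocus_b\tidentity\tcoverage\tscore\n")
        for p in pairs:
            fh.write(f"{p.locus_a}\t{p.locus_b}\t{p.pct_identity:.2f}\t{p.min_cov:.3f}\t{p.score}\n")
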