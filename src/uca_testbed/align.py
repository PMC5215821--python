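"""Progressive multiple alignment (global, affine gaps).

A deliberately small stand-in for MUSCLE-class aligners: k-mer
distances feed a UPGMA guide tree, profiles are merged up the tree with
global affine-gap profile–profile dynamic programming, and gaps, once
introduced, are never removed ("once a gap, always a gap").  There is
no iterative refinement stage.

The default score matrix is a half-bit log-odds matrix derived from the
rtREV model at an evolutionary distance of 1.0 substitutions/site,
rounded to integers (a BLOSUM-like scale), with gap open -11 and gap
extend -2.  A length-k gap costs ``gap_open + (k-1) * gap_extend``.
The extension penalty is calibrated to the matrix scale: it matches the
expected score of aligning two unrelated residues (about -2 half-bits),
so that long gap runs and runs of random mismatches are priced
comparably, which keeps the gap load of force-aligned unrelated
profiles in a realistic range for MUSCLE-class aligners.

The point of this module in the wider testbed is not alignment quality
per se: it is the step whose presence or absence flips the verdict of
the fixed-alignment common-ancestry test, and any competent global
aligner exhibits the effect.  Quantities that depend on alignment
details (e.g. gap fractions) are aligner-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.cluster.hierarchy import linkage

from .models import ReversibleEigensystem, get_model
from .seqs import GAP, Alignment, SequenceSet, encode

__all__ = [
    "AlignParams",
    "default_score_matrix",
    "pairwise_align",
    "progressive_msa",
    "identity_alignment",
    "gap_fraction",
]

_NEG = -1e30


@lru_cache(maxsize=1)
def default_score_matrix() -> np.ndarray:
    """Half-bit integer log-odds matrix from rtREV at distance 1.0."""
    model = get_model("rtREV")
    p = ReversibleEigensystem.from_model(model).expm(1.0)
    pi = model.frequencies
    joint = pi[:, None] * p
    odds = joint / (pi[:, None] * pi[None, :])
    return np.round(2.0 * np.log2(odds))


@dataclass(frozen=True)
class AlignParams:
    gap_open: float = -11.0
    gap_extend: float = -2.0
    kmer: int = 3
    score_matrix: np.ndarray | None = None

    def matrix(self) -> np.ndarray:
        return self.score_matrix if self.score_matrix is not None else default_score_matrix()


def _affine_dp(score: np.ndarray, gap_open: float, gap_extend: float):
    """Global affine-gap DP over a precomputed position-score matrix.

    Returns (best_score, path) where path is a list of moves over
    {'M', 'X', 'Y'}; 'X' consumes a row (gap in the column sequence),
    'Y' consumes a column.  Tie-breaking prefers M, then X, then Y.
    """
    n, m = score.shape
    go, ge = float(gap_open), float(gap_extend)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    M[0, 0] = 0.0
    if n:
        X[1:, 0] = go + ge * np.arange(n)
    if m:
        Y[0, 1:] = go + ge * np.arange(m)
    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)
    if m:
        ptrY[0, 1:] = 2  # edge gap chains extend
        ptrY[0, 1] = 0
    for i in range(1, n + 1):
        pm, px, py = M[i - 1], X[i - 1], Y[i - 1]
        # M from diagonal predecessors
        diag = np.maximum(np.maximum(pm[:-1], px[:-1]), py[:-1])
        Mrow = diag + score[i - 1]
        pM = np.where(pm[:-1] >= np.maximum(px[:-1], py[:-1]), 0,
                      np.where(px[:-1] >= py[:-1], 1, 2)).astype(np.int8)
        M[i, 1:] = Mrow
        ptrM[i, 1:] = pM
        # X from the row above (prefer M, then X extension, then Y)
        fromM = pm + go
        fromX = px + ge
        fromY = py + go
        Xrow = np.maximum(np.maximum(fromM, fromX), fromY)
        X[i] = Xrow
        ptrX[i] = np.where(fromM >= np.maximum(fromX, fromY), 0,
                           np.where(fromX >= fromY, 1, 2)).astype(np.int8)
        X[i, 0] = go + ge * (i - 1)
        ptrX[i, 0] = 0 if i == 1 else 1
        # Y within the row: prefix-scan over max(M, X) + open vs Y extension
        bx = np.maximum(M[i], X[i])
        cand = bx[:-1] + go - ge * np.arange(1, m + 1)
        run = np.maximum.accumulate(cand)
        Yrow = run + ge * np.arange(1, m + 1)
        Y[i, 1:] = Yrow
        yM = M[i, :-1] + go
        yX = X[i, :-1] + go
        yE = np.concatenate(([_NEG], Yrow[:-1])) + ge
        ptrY[i, 1:] = np.where(yM >= np.maximum(yX, yE), 0,
                               np.where(yX >= yE, 1, 2)).astype(np.int8)
    ends = (M[n, m], X[n, m], Y[n, m])
    state = 0 if ends[0] >= max(ends[1], ends[2]) else (1 if ends[1] >= ends[2] else 2)
    best = ends[state]
    # traceback
    path: list[str] = []
    i, j = n, m
    ptrs = (ptrM, ptrX, ptrY)
    while i > 0 or j > 0:
        prev = int(ptrs[state][i, j])
        if state == 0:
            path.append("M")
            i, j = i - 1, j - 1
        elif state == 1:
            path.append("X")
            i -= 1
        else:
            path.append("Y")
            j -= 1
        state = prev
    path.reverse()
    return float(best), path


def pairwise_align(
    s1: str,
    s2: str,
    score_matrix: np.ndarray | None = None,
    gap_open: float = -11.0,
    gap_extend: float = -2.0,
) -> tuple[Alignment, float]:
    """Optimal global affine-gap alignment of two sequences.

    Returns the two-row alignment and its score.  Unknown residue
    symbols are rejected.
    """
    if score_matrix is None:
        score_matrix = default_score_matrix()
    c1 = encode(s1, allow_gap=False)
    c2 = encode(s2, allow_gap=False)
    score = score_matrix[np.ix_(c1, c2)] if len(c1) and len(c2) else np.zeros((len(c1), len(c2)))
    best, path = _affine_dp(score, gap_open, gap_extend)
    r1, r2 = [], []
    i = j = 0
    for move in path:
        if move == "M":
            r1.append(s1[i]); r2.append(s2[j]); i += 1; j += 1
        elif move == "X":
            r1.append(s1[i]); r2.append(GAP); i += 1
        else:
            r1.append(GAP); r2.append(s2[j]); j += 1
    return Alignment(["seq1", "seq2"], ["".join(r1), "".join(r2)], source="progressive"), best


# -- progressive MSA ---------------------------------------------------------

def _kmer_distance(codes: list[np.ndarray], k: int) -> np.ndarray:
    """1 - fractional shared k-mer count (MUSCLE-style crude distance)."""
    from collections import Counter

    counters = []
    for c in codes:
        kmers = Counter()
        for i in range(len(c) - k + 1):
            kmers[tuple(c[i : i + k])] += 1
        counters.append(kmers)
    n = len(codes)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = min(len(codes[i]), len(codes[j])) - k + 1
            if denom <= 0:
                shared_frac = 0.0
            else:
                shared = sum(min(counters[i][x], counters[j][x]) for x in counters[i])
                shared_frac = shared / denom
            d[i, j] = d[j, i] = 1.0 - shared_frac
    return d


def _profile(rows: list[np.ndarray]) -> np.ndarray:
    """(n_cols, 20) residue-frequency profile; gaps carry zero weight."""
    n_cols = rows[0].shape[0]
    prof = np.zeros((n_cols, 20))
    for r in rows:
        ok = r < 20
        prof[np.nonzero(ok)[0], r[ok]] += 1.0
    return prof / len(rows)


def _merge(rows_a: list[np.ndarray], rows_b: list[np.ndarray], params: AlignParams):
    """Profile–profile affine alignment; returns merged gapped rows."""
    S = params.matrix()
    pa, pb = _profile(rows_a), _profile(rows_b)
    score = (pa @ S) @ pb.T
    _, path = _affine_dp(score, params.gap_open, params.gap_extend)
    gap_code = np.int8(20)
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for move in path:
        if move == "M":
            for r, o in zip(rows_a, out_a):
                o.append(r[i])
            for r, o in zip(rows_b, out_b):
                o.append(r[j])
            i += 1; j += 1
        elif move == "X":
            for r, o in zip(rows_a, out_a):
                o.append(r[i])
            for o in out_b:
                o.append(gap_code)
            i += 1
        else:
            for o in out_a:
                o.append(gap_code)
            for r, o in zip(rows_b, out_b):
                o.append(r[j])
            j += 1
    return (
        [np.array(o, dtype=np.int8) for o in out_a]
        + [np.array(o, dtype=np.int8) for o in out_b]
    )


def progressive_msa(seqs: SequenceSet, params: AlignParams | None = None) -> Alignment:
    """Progressive multiple alignment up a UPGMA guide tree.

    Deterministic for a fixed input order; a single sequence is returned
    unchanged as a one-row alignment.
    """
    params = params or AlignParams()
    n = len(seqs)
    if n == 0:
        raise ValueError("empty sequence set")
    codes = [encode(s, allow_gap=False) for s in seqs.seqs]
    if n == 1:
        return Alignment(list(seqs.ids), list(seqs.seqs), source="progressive")
    d = _kmer_distance(codes, params.kmer)
    condensed = d[np.triu_indices(n, k=1)]
    merges = linkage(condensed, method="average")
    clusters: dict[int, tuple[list[int], list[np.ndarray]]] = {
        i: ([i], [codes[i]]) for i in range(n)
    }
    next_id = n
    for a, b, _, _ in merges:
        ia, ib = int(a), int(b)
        idx_a, rows_a = clusters.pop(ia)
        idx_b, rows_b = clusters.pop(ib)
        merged_rows = _merge(rows_a, rows_b, params)
        clusters[next_id] = (idx_a + idx_b, merged_rows)
        next_id += 1
    order, rows = clusters.popitem()[1]
    # restore input row order
    by_index = dict(zip(order, rows))
    from .seqs import decode

    out_rows = [decode(by_index[i]) for i in range(n)]
    aln = Alignment(list(seqs.ids), out_rows, source="progressive")
    for sid, row in zip(aln.ids, aln.rows):
        if row.replace(GAP, "") != seqs[sid]:
            raise AssertionError("de-gapping invariant violated (internal error)")
    return aln


def identity_alignment(seqs: SequenceSet) -> Alignment:
    """Stack equal-length sequences unchanged (the 'unaligned' mode).

    Only defined for indel-free, equal-length data; unequal lengths are
    rejected.
    """
    if len(seqs) == 0:
        raise ValueError("empty sequence set")
    lengths = {len(s) for s in seqs.seqs}
    if len(lengths) != 1:
        raise ValueError(
            "identity (unaligned) mode requires equal-length sequences; "
            f"got lengths {sorted(lengths)}"
        )
    return Alignment(list(seqs.ids), list(seqs.seqs), source="identity")


def gap_fraction(alignment: Alignment) -> float:
    """Fraction of gap cells over all cells of the alignment."""
    return alignment.gap_fraction()
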