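"""Independent brute-force oracles used to validate the optimized paths.

Each oracle is a direct transcription of the mathematical definition,
deliberately naive (quadratic loops, full unbanded matrices) and sharing no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np

from shapesearch.align import AlignScoreParams, score_column

NEG_INF = float("-inf")


def gini_pairwise(values) -> float:
    """Gini coefficient via the O(n^2) double loop over |x_i - x_j|."""
    x = np.asarray(values, dtype=float)
    n = x.size
    total = 0.0
    for i in range(n):
        for j in range(n):
            total += abs(x[i] - x[j])
    return total / (2 * n * n * x.mean())


def mass_naive(kmer, entry) -> np.ndarray:
    """Z-normalize every window explicitly and take Euclidean distances."""
    kmer = np.asarray(kmer, dtype=float)
    entry = np.asarray(entry, dtype=float)
    k = kmer.size
    zq = (kmer - kmer.mean()) / kmer.std()
    out = np.empty(entry.size - k + 1)
    for i in range(out.size):
        w = entry[i : i + k]
        if np.isnan(w).any() or w.std() == 0:
            out[i] = np.inf
        else:
            zw = (w - w.mean()) / w.std()
            out[i] = np.sqrt(((zq - zw) ** 2).sum())
    return out


def chain_hsgs_naive(matches, max_kmer_dist, min_kmers, kmer_len):
    """Exhaustive chain construction: group per (entry, diagonal) and walk.

    Returns a set of frozensets of (query_start, db_start) member tuples,
    one per HSG, for order-insensitive comparison.
    """
    groups = {}
    for m in matches:
        groups.setdefault((m.db_entry_id, m.db_start - m.query_start), []).append(m)
    hsgs = set()
    for key, ms in groups.items():
        ms = sorted(ms, key=lambda m: m.query_start)
        chain = [ms[0]]
        for m in ms[1:]:
            if m.query_start - chain[-1].query_start <= max_kmer_dist:
                chain.append(m)
            else:
                if len(chain) >= min_kmers:
                    hsgs.add(frozenset((c.query_start, c.db_start) for c in chain))
                chain = [m]
        if len(chain) >= min_kmers:
            hsgs.add(frozenset((c.query_start, c.db_start) for c in chain))
    return hsgs


def extend_score_naive(qv, ev, qseq, eseq, params: AlignScoreParams) -> float:
    """Unbanded three-state affine-gap extension DP, full matrices.

    Start state is the extension origin (0, 0) with score 0; the result is
    the best score over every cell (semi-global: the alignment may end
    anywhere).  No banding and no drop-off: callers must choose parameters
    for which drop-off cannot trigger when comparing with the production
    extension.
    """
    n, m = len(qv), len(ev)
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    go, ge = params.gap_open, params.gap_ext
    for i in range(n + 1):
        for j in range(m + 1):
            if i == 0 and j == 0:
                continue
            if j >= 1:
                X[i, j] = max(M[i, j - 1] + go + ge, X[i, j - 1] + ge)
            if i >= 1:
                Y[i, j] = max(M[i - 1, j] + go + ge, Y[i - 1, j] + ge)
            if i >= 1 and j >= 1:
                prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
                if prev > NEG_INF:
                    M[i, j] = prev + score_column(
                        qv[i - 1], ev[j - 1], qseq[i - 1], eseq[j - 1], params
                    )
    return float(max(M.max(), X.max(), Y.max(), 0.0))
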