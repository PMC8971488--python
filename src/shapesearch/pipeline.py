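"""Search orchestration: windowing, significance, merging and benchmarking.

Long queries are split into overlapping windows (200 nt with 100 nt overlap
by default), each window is run through the seed → extend pipeline against
the real database and, for calibration, against the block-shuffled decoy
database; alignment scores are converted to p- and E-values with the fitted
extreme-value null and matches below the E-value threshold are reported
(0.01 in reactivity-only mode, 0.005 when sequence identity is scored as
well).  Consecutive matching windows landing at consistent database
positions are merged into regions.  A benchmarking harness labels matches
as true/false against planted or positional ground truth and computes
sensitivity and false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .align import AlignScoreParams, AlignmentResult
from .nullmodel import best_scores_per_entry, collect_null_scores, evalue, fit_evd
from .profiles import ProfileDatabase
from .seed import SeedParams

__all__ = [
    "SearchResult",
    "MergedRegion",
    "BenchmarkLabel",
    "split_windows",
    "search",
    "merge_windows",
    "label_matches",
    "fdr",
    "sensitivity",
    "window_overlap_analysis",
    "results_table",
]

DEFAULT_EVALUE_SHAPE_ONLY = 0.01
DEFAULT_EVALUE_SHAPE_SEQ = 0.005


@dataclass
class SearchResult:
    """One significant window match against a database entry.

    ``window_interval`` is the query window searched; ``query_interval`` /
    ``db_interval`` are the aligned regions (0-based half-open, query
    coordinates in the full query profile).
    """

    query_id: str
    window_interval: tuple[int, int]
    db_entry_id: str
    query_interval: tuple[int, int]
    db_interval: tuple[int, int]
    score: float
    p_value: float
    e_value: float
    mode: str
    alignment: AlignmentResult


@dataclass
class MergedRegion:
    """Consecutive matching windows fused into one region match."""

    query_id: str
    db_entry_id: str
    query_interval: tuple[int, int]
    db_interval: tuple[int, int]
    e_value: float
    n_windows: int
    results: tuple[SearchResult, ...]


@dataclass
class BenchmarkLabel:
    """Truth label of one reported match under a positional ground-truth rule."""

    result: SearchResult
    truth: bool
    relative_position_delta: float


def split_windows(
    length: int, window_len: int = 200, overlap: int = 100
) -> list[tuple[int, int]]:
    """Overlapping query windows covering every base.

    Starts advance by ``window_len - overlap`` while ``start < length -
    overlap``; the final window is truncated at the profile end.  Profiles
    shorter than ``window_len`` give the single window [0, length).
    """
    if not window_len > overlap >= 0:
        raise ValueError("need window_len > overlap >= 0")
    if length <= window_len:
        return [(0, length)]
    step = window_len - overlap
    return [
        (start, min(start + window_len, length))
        for start in range(0, length - overlap, step)
    ]


def _shift_alignment(aln: AlignmentResult, offset: int) -> AlignmentResult:
    """Map window-local query coordinates back into the full query."""
    if offset == 0:
        return aln
    cols = []
    for c in aln.aligned_columns:
        if c[0] == "pair":
            cols.append(("pair", c[1] + offset, c[2]))
        elif c[0] == "gapd":
            cols.append(("gapd", c[1] + offset))
        else:
            cols.append(c)
    return AlignmentResult(
        query_id=aln.query_id,
        db_entry_id=aln.db_entry_id,
        query_interval=(aln.query_interval[0] + offset, aln.query_interval[1] + offset),
        db_interval=aln.db_interval,
        score=aln.score,
        aligned_columns=tuple(cols),
        seed_hsg=aln.seed_hsg,
        p_value=aln.p_value,
        e_value=aln.e_value,
    )


def search(
    queries,
    db: ProfileDatabase,
    shuffled_db: ProfileDatabase,
    seed_params: SeedParams = SeedParams(),
    align_params: AlignScoreParams = AlignScoreParams(),
    e_value_threshold: float | None = None,
    window_len: int = 200,
    overlap: int = 100,
    min_null_trials: int = 50,
) -> list[SearchResult]:
    """Search query profiles against a database with empirical significance.

    ``queries`` is a ``ProfileDatabase`` or an iterable of profiles (then
    assumed to be of the database's signal kind).  Per query window the
    seed/extend pipeline runs against ``db`` and against ``shuffled_db``
    (the decoys calibrate a window-specific Gumbel null); matches with
    E-value <= threshold are returned sorted by ascending E-value.
    """
    if isinstance(queries, ProfileDatabase):
        if queries.kind != db.kind:
            raise ValueError(
                f"query kind {queries.kind!r} does not match database kind {db.kind!r}"
            )
        query_list = list(queries)
    else:
        query_list = list(queries)
    if shuffled_db.kind != db.kind:
        raise ValueError("shuffled database kind does not match database kind")

    mode = "shape+sequence" if align_params.seq_scoring else "shape-only"
    # Each null trial is the best score over one shuffled chunk, so the
    # E-value multiplier is the number of chunk-sized search units the real
    # database contains (>= 1 per entry); using the raw entry count would
    # understate E whenever entries are longer than the null chunks.
    unit = np.mean([len(e) for e in shuffled_db])
    n_units = max(float(len(db)), db.total_length / unit)
    if e_value_threshold is None:
        e_value_threshold = (
            DEFAULT_EVALUE_SHAPE_SEQ
            if align_params.seq_scoring
            else DEFAULT_EVALUE_SHAPE_ONLY
        )

    results: list[SearchResult] = []
    for query in query_list:
        for ws, we in split_windows(len(query), window_len, overlap):
            window = query.slice(ws, we)
            alignments = best_scores_per_entry(window, db, seed_params, align_params)
            if not alignments:
                continue
            null_scores = collect_null_scores(
                window, shuffled_db, seed_params, align_params, min_null_trials
            )
            null = fit_evd(null_scores, min_trials=min_null_trials)
            for aln in alignments:
                p = null.pvalue(aln.score)
                e = evalue(p, n_units)
                if e > e_value_threshold:
                    continue
                aln = _shift_alignment(aln, ws)
                aln.p_value, aln.e_value = p, e
                results.append(
                    SearchResult(
                        query_id=query.id,
                        window_interval=(ws, we),
                        db_entry_id=aln.db_entry_id,
                        query_interval=aln.query_interval,
                        db_interval=aln.db_interval,
                        score=aln.score,
                        p_value=p,
                        e_value=e,
                        mode=mode,
                        alignment=aln,
                    )
                )
    results.sort(
        key=lambda r: (
            r.e_value,
            r.query_id,
            r.window_interval,
            r.db_entry_id,
            r.db_interval,
        )
    )
    return results


def merge_windows(
    results: list[SearchResult],
    diagonal_tolerance: int = 20,
    require_diagonal: bool = True,
) -> list[MergedRegion]:
    """Fuse consecutive matching windows into region matches.

    Results on the same (query, db entry) whose query intervals overlap or
    touch, and (when ``require_diagonal``) whose alignment diagonals agree
    within ``diagonal_tolerance`` bases, merge into one region spanning the
    union on both axes and keeping the best (lowest) E-value.  Idempotent.
    """
    def diag(qi, di):
        return di[0] - qi[0]

    by_pair: dict[tuple[str, str], list[SearchResult]] = {}
    for r in results:
        by_pair.setdefault((r.query_id, r.db_entry_id), []).append(r)

    regions: list[MergedRegion] = []
    for (qid, eid) in sorted(by_pair):
        chain: list[SearchResult] = []
        span_q: tuple[int, int] | None = None
        span_d: tuple[int, int] | None = None

        def flush():
            if chain:
                regions.append(
                    MergedRegion(
                        query_id=qid,
                        db_entry_id=eid,
                        query_interval=span_q,
                        db_interval=span_d,
                        e_value=min(r.e_value for r in chain),
                        n_windows=len(chain),
                        results=tuple(chain),
                    )
                )

        for r in sorted(by_pair[(qid, eid)], key=lambda r: (r.query_interval, r.db_interval)):
            if chain:
                contiguous = r.query_interval[0] <= span_q[1]
                consistent = (
                    abs(diag(r.query_interval, r.db_interval) - diag(span_q, span_d))
                    <= diagonal_tolerance
                    if require_diagonal
                    else True
                )
                if contiguous and consistent:
                    chain.append(r)
                    span_q = (span_q[0], max(span_q[1], r.query_interval[1]))
                    span_d = (
                        min(span_d[0], r.db_interval[0]),
                        max(span_d[1], r.db_interval[1]),
                    )
                    continue
                flush()
                chain = []
            chain.append(r)
            span_q = r.query_interval
            span_d = r.db_interval
        flush()
    regions.sort(key=lambda g: (g.e_value, g.query_id, g.db_entry_id, g.query_interval))
    return regions


def label_matches(
    results: list[SearchResult],
    query_len: int,
    db_len: int,
    tolerance: float = 0.02,
) -> list[BenchmarkLabel]:
    """Label matches true/false by relative genomic position.

    A match is true when the midpoints of its query and database intervals,
    expressed as fractions of the respective genome lengths, differ by at
    most ``tolerance`` (the rule used when comparing homologous genomes;
    use 0 to require the exact position).
    """
    labels = []
    for r in results:
        q_rel = (r.query_interval[0] + r.query_interval[1]) / 2 / query_len
        d_rel = (r.db_interval[0] + r.db_interval[1]) / 2 / db_len
        delta = abs(q_rel - d_rel)
        labels.append(
            BenchmarkLabel(result=r, truth=delta <= tolerance, relative_position_delta=delta)
        )
    return labels


def fdr(labels: list[BenchmarkLabel]) -> float | None:
    """False discovery rate over reported matches; None when undefined."""
    if not labels:
        return None
    false = sum(1 for l in labels if not l.truth)
    return false / len(labels)


def sensitivity(labels: list[BenchmarkLabel], n_expected: int) -> float:
    """Fraction of expected query windows recovered by >= 1 true match."""
    if n_expected < 1:
        raise ValueError("n_expected must be >= 1")
    if not labels:
        return 0.0
    recovered = {
        (l.result.query_id, l.result.window_interval) for l in labels if l.truth
    }
    return len(recovered) / n_expected


def window_overlap_analysis(
    results_a: list[SearchResult],
    results_b: list[SearchResult],
    min_overlap: float = 0.25,
) -> float | None:
    """Fraction of A's matched windows overlapped by a window matched in B.

    Overlap is measured on query coordinates relative to the smaller of the
    two windows; a window of A counts when at least one window of B reaches
    ``min_overlap``.  Returns None when A is empty (undefined).
    """
    a_windows = sorted({r.query_interval for r in results_a})
    b_windows = sorted({r.query_interval for r in results_b})
    if not a_windows:
        return None
    hit = 0
    for aw in a_windows:
        for bw in b_windows:
            inter = min(aw[1], bw[1]) - max(aw[0], bw[0])
            smaller = min(aw[1] - aw[0], bw[1] - bw[0])
            if smaller > 0 and inter / smaller >= min_overlap:
                hit += 1
                break
    return hit / len(a_windows)


def results_table(results: list[SearchResult]) -> pd.DataFrame:
    """Result table with 1-based inclusive coordinates for reporting."""
    rows = [
        {
            "query_id": r.query_id,
            "query_start": r.query_interval[0] + 1,
            "query_end": r.query_interval[1],
            "db_id": r.db_entry_id,
            "db_start": r.db_interval[0] + 1,
            "db_end": r.db_interval[1],
            "score": round(r.score, 4),
            "p_value": float(f"{r.p_value:.6g}"),
            "e_value": float(f"{r.e_value:.6g}"),
            "mode": r.mode,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "query_id",
            "query_start",
            "query_end",
            "db_id",
            "db_start",
            "db_end",
            "score",
            "p_value",
            "e_value",
            "mode",
        ],
    )
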