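"""Banded affine-gap extension of HSG seeds over reactivity profiles.

Each HSG is an ungapped seed; the alignment is grown independently
downstream and upstream of it with a three-state Gotoh dynamic program
(match / gap-in-query / gap-in-db, affine gap costs) whose substitution
score is a continuous, piecewise-linear function of the absolute reactivity
difference — the dynamic-time-warping ingredient: similar signal levels are
rewarded on a sliding scale rather than through a discrete alphabet.
Optionally a sequence identity term is added on top.

The DP is confined to a band around the seed diagonal whose half-width
grows with the extension length, and is terminated by an X-drop-style rule:
extension in a direction stops once the best score of the current
anti-diagonal has stayed below ``max_dropoff_rate`` times the global best
for more than ``max_dropoff_bases`` consecutive anti-diagonals, or when a
profile end is reached.  The reported alignment is the traceback from the
global-best cell of each direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .profiles import ReactivityProfile
from .seed import HSG

__all__ = [
    "AlignScoreParams",
    "AlignmentResult",
    "score_column",
    "extend_hsg",
    "alignment_score",
    "dedup_alignments",
]

NEG_INF = float("-inf")

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_CODE[b] for b in seq], dtype=np.int8)


@dataclass(frozen=True)
class AlignScoreParams:
    """Scoring and banding parameters of the extension stage.

    ``match_score`` / ``mismatch_score`` are (min, max) pairs: a reactivity
    difference of 0 earns ``match_score[1]``; the score decreases linearly
    to ``match_score[0]`` at the match/mismatch boundary
    (``match_boundary_fraction * max_reactivity``), then from
    ``mismatch_score[1]`` down to ``mismatch_score[0]`` at the maximal
    difference.  Gap costs are affine: a run of length L costs
    ``gap_open + L * gap_ext``.  ``band_fraction`` sets the band half-width
    ``max(10, ceil(band_fraction * extension_length))`` around the seed
    diagonal.  Defaults are the optimized SHAPE set; :meth:`for_bpp` gives
    the base-pairing-probability set.
    """

    match_score: tuple[float, float] = (-0.5, 2.0)
    mismatch_score: tuple[float, float] = (-6.0, -0.5)
    gap_open: float = -14.0
    gap_ext: float = -5.0
    max_dropoff_rate: float = 0.8
    max_dropoff_bases: int = 8
    max_reactivity: float = 1.0
    match_boundary_fraction: float = 0.5
    seq_scoring: bool = False
    seq_match: float = 0.5
    seq_mismatch: float = -2.0
    band_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.max_dropoff_rate <= 1):
            raise ValueError("max_dropoff_rate must be in (0, 1]")
        if self.max_dropoff_bases < 1 or self.max_reactivity <= 0:
            raise ValueError("invalid extension parameter")
        if not (0 < self.match_boundary_fraction < 1):
            raise ValueError("match_boundary_fraction must be in (0, 1)")
        if not (0 < self.band_fraction <= 1):
            raise ValueError("band_fraction must be in (0, 1]")
        if self.gap_open > 0 or self.gap_ext > 0:
            raise ValueError("gap penalties must be <= 0")

    @classmethod
    def for_bpp(cls, **overrides) -> "AlignScoreParams":
        base = cls(
            match_score=(0.0, 3.0),
            mismatch_score=(-7.0, 0.0),
            gap_open=-12.0,
            gap_ext=-9.0,
            max_dropoff_rate=0.7,
            max_dropoff_bases=6,
            max_reactivity=1.0,
        )
        return replace(base, **overrides) if overrides else base

    @classmethod
    def with_sequence(cls, **overrides) -> "AlignScoreParams":
        """SHAPE defaults plus the sequence-identity scoring term."""
        return cls(seq_scoring=True, **overrides)


# Column states of an alignment:
#   ("pair", qi, di)  query base qi aligned to db base di
#   ("gapq", di)      db base di aligned to a gap in the query
#   ("gapd", qi)      query base qi aligned to a gap in the db
Column = tuple


@dataclass
class AlignmentResult:
    """An extended, scored, gapped alignment between query and db regions.

    Intervals are 0-based half-open in the respective profiles; ``score``
    is recomputable from ``aligned_columns`` via :func:`alignment_score`.
    ``p_value`` / ``e_value`` are filled by the null model.
    """

    query_id: str
    db_entry_id: str
    query_interval: tuple[int, int]
    db_interval: tuple[int, int]
    score: float
    aligned_columns: tuple[Column, ...]
    seed_hsg: HSG
    p_value: float | None = None
    e_value: float | None = None


def score_column(
    rq: float,
    rd: float,
    bq: str | None = None,
    bd: str | None = None,
    params: AlignScoreParams = AlignScoreParams(),
) -> float:
    """Score of one aligned column from (capped) reactivities and bases.

    If either reactivity is missing (nan) the reactivity term is 0.  With
    ``seq_scoring``, ``seq_match`` is added when the bases are identical
    and both in {A, C, G, U} (N never matches), else ``seq_mismatch``.
    """
    if math.isnan(rq) or math.isnan(rd):
        s = 0.0
    else:
        d = abs(rq - rd)
        t = params.match_boundary_fraction * params.max_reactivity
        mmin, mmax = params.match_score
        xmin, xmax = params.mismatch_score
        if d <= t:
            s = mmax - (d / t) * (mmax - mmin)
        else:
            s = xmax - ((d - t) / (params.max_reactivity - t)) * (xmax - xmin)
            s = max(s, xmin)
    if params.seq_scoring:
        if bq is None or bd is None:
            raise ValueError("sequence scoring requires bases")
        if bq == bd and bq in "ACGU":
            s += params.seq_match
        else:
            s += params.seq_mismatch
    return s


@njit(cache=True)
def _col_score(
    rq, rd, t, max_r, m_min, m_max, x_min, x_max, seq_on, qc, ec, s_match, s_mismatch
):  # pragma: no cover - exercised through extend_hsg
    if math.isnan(rq) or math.isnan(rd):
        s = 0.0
    else:
        d = abs(rq - rd)
        if d <= t:
            s = m_max - (d / t) * (m_max - m_min)
        else:
            s = x_max - ((d - t) / (max_r - t)) * (x_max - x_min)
            if s < x_min:
                s = x_min
    if seq_on:
        if qc == ec and qc < 4:
            s += s_match
        else:
            s += s_mismatch
    return s


@njit(cache=True)
def _dp_fill(
    qv,
    ev,
    qc,
    ec,
    t,
    max_r,
    m_min,
    m_max,
    x_min,
    x_max,
    go,
    ge,
    rate,
    max_drop,
    band_frac,
    w_cap,
    seq_on,
    s_match,
    s_mismatch,
):  # pragma: no cover - exercised through extend_hsg
    """Anti-diagonal banded Gotoh fill with drop-off termination.

    The band half-width is max(10, ceil(band_frac * s / 2)) at
    anti-diagonal s, capped at ``w_cap``.  Returns the three state
    matrices plus the global-best cell (relative to the extension origin
    at (0, 0)).
    """
    n = qv.size
    m = ev.size
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in query (consumes db)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in db (consumes query)
    M[0, 0] = 0.0
    best = 0.0
    best_i = 0
    best_j = 0
    drop = 0
    dropped = False
    for s in range(1, n + m + 1):
        w = 10.0
        half = band_frac * s / 2.0
        if half > w:
            w = half
        w = math.ceil(w)
        if w > w_cap:
            w = w_cap
        step_best = NEG_INF
        ilo = s - m
        if ilo < 0:
            ilo = 0
        ihi = s if s < n else n
        for i in range(ilo, ihi + 1):
            j = s - i
            if abs(i - j) > w:
                continue
            if j >= 1:
                o = M[i, j - 1] + go + ge
                e = X[i, j - 1] + ge
                X[i, j] = o if o > e else e
            if i >= 1:
                o = M[i - 1, j] + go + ge
                e = Y[i - 1, j] + ge
                Y[i, j] = o if o > e else e
            if i >= 1 and j >= 1:
                prev = M[i - 1, j - 1]
                if X[i - 1, j - 1] > prev:
                    prev = X[i - 1, j - 1]
                if Y[i - 1, j - 1] > prev:
                    prev = Y[i - 1, j - 1]
                if prev > NEG_INF:
                    M[i, j] = prev + _col_score(
                        qv[i - 1],
                        ev[j - 1],
                        t,
                        max_r,
                        m_min,
                        m_max,
                        x_min,
                        x_max,
                        seq_on,
                        qc[i - 1],
                        ec[j - 1],
                        s_match,
                        s_mismatch,
                    )
            cell = M[i, j]
            if X[i, j] > cell:
                cell = X[i, j]
            if Y[i, j] > cell:
                cell = Y[i, j]
            if cell > step_best:
                step_best = cell
            if cell > best:
                best = cell
                best_i = i
                best_j = j
        if step_best < rate * best:
            drop += 1
            if drop > max_drop:
                dropped = True
                break
        else:
            drop = 0
    return M, X, Y, best_i, best_j, dropped


_DECODE = "ACGUN"


def _scores_vec(rq, rd, qc, ec, params: AlignScoreParams) -> np.ndarray:
    """Vectorized column scores over parallel value/base-code vectors."""
    rq = np.asarray(rq, dtype=float)
    rd = np.asarray(rd, dtype=float)
    d = np.abs(rq - rd)
    t = params.match_boundary_fraction * params.max_reactivity
    mmin, mmax = params.match_score
    xmin, xmax = params.mismatch_score
    with np.errstate(invalid="ignore"):
        match = mmax - (d / t) * (mmax - mmin)
        mism = np.maximum(
            xmax - ((d - t) / (params.max_reactivity - t)) * (xmax - xmin), xmin
        )
        s = np.where(d <= t, match, mism)
    s = np.where(np.isnan(d), 0.0, s)
    if params.seq_scoring:
        qc = np.asarray(qc)
        ec = np.asarray(ec)
        ident = (qc == ec) & (qc < 4)
        s = s + np.where(ident, params.seq_match, params.seq_mismatch)
    return s


def _traceback(M, X, Y, best_i, best_j, qv, ev, qs, es, params) -> list[tuple[str, int, int]]:
    """Walk back from the best cell to the origin.

    Returns relative columns ("pair", i, j) / ("gapq", j) / ("gapd", i)
    in alignment order (origin outward), with 0-based relative indices.
    Ties prefer pair > gap-in-db > gap-in-query for determinism.
    """
    go, ge = params.gap_open, params.gap_ext
    i, j = best_i, best_j
    # state at the end cell
    state = "M"
    top = M[i, j]
    if Y[i, j] > top:
        state, top = "Y", Y[i, j]
    if X[i, j] > top:
        state, top = "X", X[i, j]
    cols: list[tuple] = []
    while (i, j) != (0, 0):
        if state == "M":
            cols.append(("pair", i - 1, j - 1))
            cs = score_column(
                qv[i - 1],
                ev[j - 1],
                _DECODE[qs[i - 1]],
                _DECODE[es[j - 1]],
                params,
            )
            target = M[i, j] - cs
            if math.isclose(target, M[i - 1, j - 1], rel_tol=1e-9, abs_tol=1e-9):
                state = "M"
            elif math.isclose(target, Y[i - 1, j - 1], rel_tol=1e-9, abs_tol=1e-9):
                state = "Y"
            else:
                state = "X"
            i, j = i - 1, j - 1
        elif state == "Y":  # gap in db: consumes query base i-1
            cols.append(("gapd", i - 1))
            if math.isclose(Y[i, j], M[i - 1, j] + go + ge, rel_tol=1e-9, abs_tol=1e-9):
                state = "M"
            else:
                state = "Y"
            i = i - 1
        else:  # X: gap in query, consumes db base j-1
            cols.append(("gapq", j - 1))
            if math.isclose(X[i, j], M[i, j - 1] + go + ge, rel_tol=1e-9, abs_tol=1e-9):
                state = "M"
            else:
                state = "X"
            j = j - 1
    cols.reverse()
    return cols


def _extend_one_direction(qv, ev, qc, ec, params):
    """Run the banded DP on one flank; returns (score, rel columns, qi, dj).

    The DP window starts small and doubles only when the extension truly
    reaches its boundary without drop-off termination: most flanks stop
    within a few anti-diagonals, so allocating the full (n+1) x (m+1)
    matrices up front would dominate the search runtime.
    """
    if qv.size == 0 and ev.size == 0:
        return 0.0, [], 0, 0
    t = params.match_boundary_fraction * params.max_reactivity
    n, m = qv.size, ev.size
    # band-width ceiling from the query flank length: gap runs wider than
    # this are never score-optimal under affine penalties
    w_cap = max(10, math.ceil(2 * params.band_fraction * max(n, 1)))
    margin = w_cap + params.max_dropoff_bases + 8
    limit = 64
    while True:
        n_eff = min(n, limit)
        m_eff = min(m, n_eff + margin)
        M, X, Y, bi, bj, dropped = _dp_fill(
            np.ascontiguousarray(qv[:n_eff], dtype=float),
            np.ascontiguousarray(ev[:m_eff], dtype=float),
            np.ascontiguousarray(qc[:n_eff]),
            np.ascontiguousarray(ec[:m_eff]),
            t,
            params.max_reactivity,
            params.match_score[0],
            params.match_score[1],
            params.mismatch_score[0],
            params.mismatch_score[1],
            params.gap_open,
            params.gap_ext,
            params.max_dropoff_rate,
            params.max_dropoff_bases,
            params.band_fraction,
            w_cap,
            params.seq_scoring,
            params.seq_match,
            params.seq_mismatch,
        )
        if dropped or (n_eff == n and m_eff == m) or n_eff >= n:
            break
        limit *= 2
    score = max(M[bi, bj], X[bi, bj], Y[bi, bj])
    cols = _traceback(M, X, Y, bi, bj, qv, ev, qc, ec, params)
    return float(score), cols, bi, bj


def profile_context(
    profile: ReactivityProfile, params: AlignScoreParams
) -> tuple[np.ndarray, np.ndarray]:
    """Precompute (capped values, encoded bases) for repeated extensions."""
    return np.minimum(profile.reactivity, params.max_reactivity), _encode(profile.sequence)


def extend_hsg(
    query: ReactivityProfile,
    entry: ReactivityProfile,
    hsg: HSG,
    params: AlignScoreParams = AlignScoreParams(),
    query_ctx: tuple[np.ndarray, np.ndarray] | None = None,
    entry_ctx: tuple[np.ndarray, np.ndarray] | None = None,
) -> AlignmentResult:
    """Extend an HSG seed bidirectionally into a scored gapped alignment.

    The seed span contributes its ungapped column scores; each flank is
    extended with the banded drop-off DP and the global-best prefix of each
    direction is kept.  The returned score always equals the column-wise
    recomputation (:func:`alignment_score`).  ``query_ctx`` / ``entry_ctx``
    from :func:`profile_context` avoid re-capping and re-encoding when many
    HSGs of the same profile pair are extended.
    """
    qs, qe = hsg.query_span
    ds, de = hsg.db_span
    if qe <= qs:
        raise ValueError("degenerate HSG with empty span")
    qv, qc_full = query_ctx if query_ctx is not None else profile_context(query, params)
    ev, ec_full = entry_ctx if entry_ctx is not None else profile_context(entry, params)

    seed_cols = [("pair", qi, qi - qs + ds) for qi in range(qs, qe)]
    seed_score = float(
        _scores_vec(qv[qs:qe], ev[ds:de], qc_full[qs:qe], ec_full[ds:de], params).sum()
    )

    # downstream flank
    d_score, d_cols, d_qi, d_dj = _extend_one_direction(
        qv[qe:], ev[de:], qc_full[qe:], ec_full[de:], params
    )
    # upstream flank: reversed prefixes
    u_score, u_cols, u_qi, u_dj = _extend_one_direction(
        qv[:qs][::-1],
        ev[:ds][::-1],
        qc_full[:qs][::-1],
        ec_full[:ds][::-1],
        params,
    )

    cols: list[Column] = []
    for c in reversed(u_cols):  # map reversed-relative to absolute upstream coords
        if c[0] == "pair":
            cols.append(("pair", qs - 1 - c[1], ds - 1 - c[2]))
        elif c[0] == "gapq":
            cols.append(("gapq", ds - 1 - c[1]))
        else:
            cols.append(("gapd", qs - 1 - c[1]))
    cols.extend(seed_cols)
    for c in d_cols:
        if c[0] == "pair":
            cols.append(("pair", qe + c[1], de + c[2]))
        elif c[0] == "gapq":
            cols.append(("gapq", de + c[1]))
        else:
            cols.append(("gapd", qe + c[1]))

    result = AlignmentResult(
        query_id=query.id,
        db_entry_id=entry.id,
        query_interval=(qs - u_qi, qe + d_qi),
        db_interval=(ds - u_dj, de + d_dj),
        score=float(seed_score + d_score + u_score),
        aligned_columns=tuple(cols),
        seed_hsg=hsg,
    )
    return result


def alignment_score(
    columns,
    query: ReactivityProfile,
    entry: ReactivityProfile,
    params: AlignScoreParams = AlignScoreParams(),
) -> float:
    """Recompute an alignment score from its columns (pairs + affine gaps)."""
    qv = np.minimum(query.reactivity, params.max_reactivity)
    ev = np.minimum(entry.reactivity, params.max_reactivity)
    total = 0.0
    prev_gap = None
    for c in columns:
        if c[0] == "pair":
            _, qi, di = c
            total += score_column(
                qv[qi], ev[di], query.sequence[qi], entry.sequence[di], params
            )
            prev_gap = None
        else:
            if c[0] != prev_gap:
                total += params.gap_open
            total += params.gap_ext
            prev_gap = c[0]
    return total


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return inter / min(a[1] - a[0], b[1] - b[0])


def dedup_alignments(results: list[AlignmentResult]) -> list[AlignmentResult]:
    """Drop near-duplicate alignments seeded from overlapping HSGs.

    Alignments of the same query/db entry overlapping by more than 50% in
    both intervals are considered one region; the best-scoring one is kept
    (ties broken by coordinates for determinism).
    """
    order = sorted(
        results,
        key=lambda r: (-r.score, r.db_entry_id, r.query_interval, r.db_interval),
    )
    kept_by_entry: dict[str, list[AlignmentResult]] = {}
    kept: list[AlignmentResult] = []
    for r in order:
        dup = any(
            _overlap_frac(k.query_interval, r.query_interval) > 0.5
            and _overlap_frac(k.db_interval, r.db_interval) > 0.5
            for k in kept_by_entry.get(r.db_entry_id, ())
        )
        if not dup:
            kept_by_entry.setdefault(r.db_entry_id, []).append(r)
            kept.append(r)
    return kept
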