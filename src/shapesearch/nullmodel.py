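"""Empirical extreme-value null model for alignment scores.

Significance is calibrated empirically, BLAST-style but without analytic
Karlin–Altschul theory: the database is block-shuffled (blocks of
consecutive bases move as units, preserving the local structural context
of the signal), the query is searched against the shuffled database with
the identical seed-and-extend pipeline, and the best alignment score per
shuffled entry builds a null sample of maxima.  A Gumbel (type-I extreme
value) distribution fitted to these maxima converts an observed score S
into p = P(S_null >= S), and E = p * (number of real database entries).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .align import AlignScoreParams, dedup_alignments, extend_hsg, profile_context
from .profiles import ProfileDatabase, ReactivityProfile
from .seed import SeedParams, group_hsgs, match_kmers

__all__ = [
    "ShuffleParams",
    "NullDistribution",
    "block_shuffle",
    "build_shuffled_db",
    "collect_null_scores",
    "fit_evd",
    "pvalue",
    "evalue",
]


@dataclass(frozen=True)
class ShuffleParams:
    """Shuffled-database construction parameters.

    ``block_size`` bases move as a unit (default 10, preserving local
    structural context); ``n_shuffles`` independent shuffles are generated
    per entry and a random contiguous chunk of at most ``chunk_size`` bases
    is kept from each (an unbiased subsample provided queries are shorter
    than the chunk).  ``min_trials`` is the minimum number of null scores
    required before an extreme-value fit is permitted.
    """

    block_size: int = 10
    n_shuffles: int = 100
    chunk_size: int = 1000
    seed: int | None = None
    min_trials: int = 50

    def __post_init__(self) -> None:
        if self.block_size < 1 or self.n_shuffles < 1 or self.chunk_size < 1:
            raise ValueError("shuffle parameters must be positive")
        if self.min_trials < 2:
            raise ValueError("min_trials must be >= 2")


@dataclass
class NullDistribution:
    """Null alignment-score maxima and fitted Gumbel parameters."""

    scores: np.ndarray
    mu: float
    beta: float
    n_trials: int = field(default=0)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.n_trials == 0:
            self.n_trials = self.scores.size
        if self.beta <= 0:
            raise ValueError("EVD scale beta must be > 0")

    def pvalue(self, score: float) -> float:
        return pvalue(score, self.mu, self.beta)


def block_shuffle(
    profile: ReactivityProfile, block_size: int, rng: np.random.Generator
) -> ReactivityProfile:
    """Permute a profile in blocks of ``block_size`` consecutive bases.

    The profile is cut into consecutive blocks (the last possibly shorter)
    whose order is permuted uniformly at random; within-block order and the
    base-reactivity pairing at every position are preserved, so the
    multiset of (base, reactivity) pairs is invariant.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    L = len(profile)
    starts = np.arange(0, L, block_size)
    order = rng.permutation(starts.size)
    seq_parts = []
    rea_parts = []
    for b in order:
        s = int(starts[b])
        e = min(s + block_size, L)
        seq_parts.append(profile.sequence[s:e])
        rea_parts.append(profile.reactivity[s:e])
    return ReactivityProfile(
        id=profile.id,
        sequence="".join(seq_parts),
        reactivity=np.concatenate(rea_parts) if rea_parts else np.empty(0),
    )


def build_shuffled_db(
    db: ProfileDatabase, params: ShuffleParams = ShuffleParams()
) -> ProfileDatabase:
    """Shuffled decoy database: ``n_shuffles`` chunked shuffles per entry.

    Each output entry id encodes its provenance
    (``<entry>|shuf<i>|<start>-<end>``); the database metadata records the
    seed so a persisted shuffled database is reproducible.
    """
    if len(db) == 0:
        raise ValueError("cannot shuffle an empty database")
    rng = np.random.default_rng(params.seed)
    entries: list[ReactivityProfile] = []
    for entry in db:
        L = len(entry)
        chunk = min(params.chunk_size, L)
        for i in range(params.n_shuffles):
            shuf = block_shuffle(entry, params.block_size, rng)
            start = int(rng.integers(0, L - chunk + 1))
            entries.append(
                shuf.slice(start, start + chunk, new_id=f"{entry.id}|shuf{i}|{start}-{start + chunk}")
            )
    meta = {"shuffled": "1", "block_size": str(params.block_size)}
    if params.seed is not None:
        meta["seed"] = str(params.seed)
    return ProfileDatabase(entries=entries, kind=db.kind, metadata=meta)


def collect_null_scores(
    query: ReactivityProfile,
    shuffled_db: ProfileDatabase,
    seed_params: SeedParams = SeedParams(),
    align_params: AlignScoreParams = AlignScoreParams(),
    min_trials: int = 50,
) -> np.ndarray:
    """Best alignment score of the query against each shuffled entry.

    Runs the identical seed → HSG → extension pipeline against the decoy
    database; entries yielding no HSG contribute the floor score 0 (skipping
    them would bias the null upward).  Returns one score per shuffled entry.
    """
    if len(shuffled_db) < min_trials:
        raise ValueError(
            f"insufficient null trials: {len(shuffled_db)} shuffled entries "
            f"< minimum {min_trials}"
        )
    matches = match_kmers(query, shuffled_db, seed_params)
    hsgs = group_hsgs(matches, seed_params)
    by_entry: dict[str, list] = {}
    for h in hsgs:
        by_entry.setdefault(h.db_entry_id, []).append(h)
    qctx = profile_context(query, align_params)
    scores = np.zeros(len(shuffled_db))
    for i, entry in enumerate(shuffled_db):
        entry_hsgs = by_entry.get(entry.id, [])
        if not entry_hsgs:
            continue
        results = _extend_entry_hsgs(query, entry, entry_hsgs, align_params, qctx)
        scores[i] = max(r.score for r in results)
    return scores


def fit_evd(
    scores, min_trials: int = 50, method: str = "moments"
) -> NullDistribution:
    """Fit a Gumbel distribution to null score maxima.

    The default method-of-moments fit is deterministic and closed-form:
    ``beta = s * sqrt(6) / pi`` and ``mu = mean - gamma * beta`` (gamma the
    Euler–Mascheroni constant).  ``method="ml"`` uses the maximum-likelihood
    fit instead.  Degenerate (zero-variance) score sets are an error.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < min_trials:
        raise ValueError(f"insufficient null trials: {x.size} < {min_trials}")
    if not np.isfinite(x).all():
        raise ValueError("null scores must be finite")
    if np.std(x) == 0:
        raise ValueError("degenerate null: zero-variance scores")
    if method == "moments":
        beta = np.std(x, ddof=1) * np.sqrt(6.0) / np.pi
        mu = np.mean(x) - np.euler_gamma * beta
    elif method == "ml":
        mu, beta = stats.gumbel_r.fit(x)
    else:
        raise ValueError(f"unknown EVD fit method {method!r}")
    return NullDistribution(scores=x, mu=float(mu), beta=float(beta))


def pvalue(score: float, mu: float, beta: float) -> float:
    """Gumbel survival probability P(S_null >= score)."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    z = (score - mu) / beta
    # survival of the Gumbel max distribution, numerically stable
    return float(-np.expm1(-np.exp(-z)))


def evalue(p: float, n_units: float) -> float:
    """Expected chance matches at this p-value over the searched database.

    ``n_units`` is the size of the search space in units matching the null
    trials — the number of database entries when entries and null chunks
    are comparable in length, or the number of chunk-sized units otherwise.
    """
    if n_units < 1:
        raise ValueError("search-space multiplier must be >= 1")
    return float(p) * float(n_units)


def best_scores_per_entry(
    query: ReactivityProfile,
    db: ProfileDatabase,
    seed_params: SeedParams = SeedParams(),
    align_params: AlignScoreParams = AlignScoreParams(),
):
    """All deduplicated alignments of a query against a database.

    Shared by the real search and diagnostics; returns the alignment list
    (unfiltered by significance).
    """
    matches = match_kmers(query, db, seed_params)
    hsgs = group_hsgs(matches, seed_params)
    by_entry: dict[str, list] = {}
    for h in hsgs:
        by_entry.setdefault(h.db_entry_id, []).append(h)
    qctx = profile_context(query, align_params)
    results = []
    for entry in db:
        entry_hsgs = by_entry.get(entry.id, [])
        if entry_hsgs:
            results.extend(
                _extend_entry_hsgs(query, entry, entry_hsgs, align_params, qctx)
            )
    return dedup_alignments(results)


def _contained(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return inner[0] >= outer[0] and inner[1] <= outer[1]


def _extend_entry_hsgs(query, entry, hsgs, align_params, qctx):
    """Extend an entry's HSGs, largest seeds first, skipping absorbed ones.

    Overlapping seeds extend to near-identical alignments; a seed whose
    query and db spans both fall inside an already-extended alignment of
    the same entry is skipped (the BLAST-style contained-hit shortcut),
    which changes nothing downstream because such duplicates would be
    removed by :func:`dedup_alignments` anyway.
    """
    ectx = profile_context(entry, align_params)
    order = sorted(
        hsgs,
        key=lambda h: (-len(h.matches), h.query_span[0] - h.query_span[1], h.query_span),
    )
    results = []
    for h in order:
        absorbed = any(
            _contained(h.query_span, r.query_interval)
            and _contained(h.db_span, r.db_interval)
            for r in results
        )
        if not absorbed:
            results.append(extend_hsg(query, entry, h, align_params, qctx, ectx))
    return results
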