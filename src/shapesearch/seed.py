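"""K-mer seeding: complexity filtering, MASS lookup and HSG grouping.

The seeding stage mirrors BLAST-style word matching, transposed to
continuous signals.  Every k-mer window of the query reactivity profile is
enumerated; windows with low structural complexity (little disparity among
reactivities, as inside a fully paired or fully unpaired stretch) are
discarded by a Gini-coefficient cutoff.  Surviving k-mers are looked up in
every database entry with MASS (Mueen's Algorithm for Similarity Search),
which computes the z-normalized Euclidean distance between the k-mer and
every same-length window of the entry via FFT sliding dot products.
Matches whose local GC content deviates too much from the query k-mer are
dropped (structurally related RNAs show limited local GC variation), as are
promiscuous k-mers matching more often than once every
``kmer_max_match_every_nt`` database bases.  Finally, matches on a common
(db_start - query_start) diagonal within ``max_kmer_dist`` of each other are
chained into high scoring groups (HSGs), the seeds of alignment extension.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import fft as sp_fft

from .profiles import ProfileDatabase, ReactivityProfile, cap_reactivity

__all__ = [
    "SeedParams",
    "KmerMatch",
    "HSG",
    "gini",
    "enumerate_query_kmers",
    "mass_distance_profile",
    "match_kmers",
    "group_hsgs",
]


@dataclass(frozen=True)
class SeedParams:
    """Parameters of the seeding stage.

    Defaults are the optimized set for SHAPE reactivities; use
    :meth:`for_bpp` for base-pairing-probability profiles.

    ``dist_coeff`` scales the MASS match cutoff: an offset is a match when
    its z-normalized distance is <= ``dist_coeff * sqrt(kmer_len)``, i.e.
    the per-position normalized discrepancy is length-independent.  The
    default 0.6 (window correlation >= 0.82) is calibrated so that, on
    realistic run-structured profiles, background matches stay rarer than
    once per ``kmer_max_match_every_nt`` bases while seeds survive the
    reactivity noise between matched homologs.
    ``max_gc_diff`` is in percentage points; ``None`` disables the GC
    filter.  ``kmer_max_match_every_nt`` discards any k-mer whose total
    match count exceeds ``database length / kmer_max_match_every_nt``.
    """

    kmer_len: int = 15
    min_kmers: int = 2
    max_kmer_dist: int = 30
    kmer_min_complexity: float = 0.3
    kmer_max_match_every_nt: int = 200
    max_reactivity: float = 1.0
    max_gc_diff: float | None = 10.0
    dist_coeff: float = 0.6

    def __post_init__(self) -> None:
        if self.kmer_len < 2:
            raise ValueError("kmer_len must be >= 2")
        if self.min_kmers < 1 or self.kmer_max_match_every_nt < 1:
            raise ValueError("min_kmers and kmer_max_match_every_nt must be >= 1")
        if not 0 <= self.kmer_min_complexity < 1:
            raise ValueError("kmer_min_complexity must be in [0, 1)")
        if self.max_kmer_dist < 0 or self.max_reactivity <= 0 or self.dist_coeff <= 0:
            raise ValueError("invalid seed parameter")

    @classmethod
    def for_bpp(cls, **overrides) -> "SeedParams":
        """Optimized set for base-pairing-probability profiles."""
        base = cls(
            kmer_len=15,
            min_kmers=3,
            max_kmer_dist=10,
            kmer_min_complexity=0.4,
            kmer_max_match_every_nt=200,
            max_reactivity=1.0,
        )
        return replace(base, **overrides) if overrides else base

    @property
    def distance_threshold(self) -> float:
        return self.dist_coeff * math.sqrt(self.kmer_len)


@dataclass(frozen=True)
class KmerMatch:
    """A query k-mer matched to one database offset (0-based starts)."""

    query_start: int
    db_entry_id: str
    db_start: int
    znorm_distance: float
    gc_diff: float

    @property
    def diagonal(self) -> int:
        return self.db_start - self.query_start


@dataclass(frozen=True)
class HSG:
    """High scoring group: co-diagonal k-mer matches chained into a seed.

    ``query_span`` / ``db_span`` are 0-based half-open intervals covering
    the union of member k-mers; both have equal length (the seed is
    ungapped) and satisfy ``db_span[0] - query_span[0] == diagonal``.
    """

    matches: tuple[KmerMatch, ...]
    db_entry_id: str
    diagonal: int
    query_span: tuple[int, int]
    db_span: tuple[int, int]


# ---------------------------------------------------------------------------
# Gini complexity


def gini(values) -> float:
    """Gini coefficient of a vector of non-negative reactivities.

    G = sum_ij |x_i - x_j| / (2 n^2 mean(x)), computed via the sorted-vector
    identity.  0 for a perfectly uniform vector, (n-1)/n for a one-hot
    vector.  Raises ``ValueError`` for inputs on which the coefficient is
    uncomputable (fewer than two values, negative or missing entries,
    all-zero vector); callers skip such k-mers.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("gini needs at least two values")
    if np.isnan(x).any():
        raise ValueError("gini is uncomputable with missing values")
    if (x < 0).any():
        raise ValueError("gini requires non-negative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini is uncomputable for an all-zero vector")
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(((2 * i - n - 1) * xs).sum() / (n * total))


def _gini_or_nan(window: np.ndarray) -> float:
    try:
        return gini(window)
    except ValueError:
        return float("nan")


def enumerate_query_kmers(
    query: ReactivityProfile, params: SeedParams
) -> list[tuple[int, np.ndarray]]:
    """All complexity-passing k-mer windows of the query profile.

    Yields ``(query_start, capped_values)`` for every offset whose window,
    after capping at ``max_reactivity``, contains no missing value, has
    nonzero variance and Gini >= ``kmer_min_complexity``.  A query shorter
    than ``kmer_len`` yields no k-mers.
    """
    k = params.kmer_len
    capped = cap_reactivity(query, params.max_reactivity)
    if len(capped) < k:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(capped, k)
    out = []
    for start, win in enumerate(windows):
        if np.isnan(win).any() or np.ptp(win) == 0:
            continue
        g = _gini_or_nan(win)
        if np.isnan(g) or g < params.kmer_min_complexity:
            continue
        out.append((start, win.copy()))
    return out


# ---------------------------------------------------------------------------
# MASS z-normalized sliding distance


def _window_stats(entry: np.ndarray, k: int):
    """Sliding window mean/std and validity mask over an entry vector.

    Windows containing missing values or with zero variance are invalid
    (unmatchable).  Statistics are computed on a nan-zeroed copy; invalid
    windows are masked, so the zeros never leak into distances.
    """
    m = entry.size
    nanmask = np.isnan(entry)
    filled = np.where(nanmask, 0.0, entry)
    csum = np.concatenate(([0.0], np.cumsum(filled)))
    csum2 = np.concatenate(([0.0], np.cumsum(filled**2)))
    cnan = np.concatenate(([0], np.cumsum(nanmask)))
    n_win = m - k + 1
    idx = np.arange(n_win)
    has_nan = (cnan[idx + k] - cnan[idx]) > 0
    mean = (csum[idx + k] - csum[idx]) / k
    var = (csum2[idx + k] - csum2[idx]) / k - mean**2
    var = np.maximum(var, 0.0)
    std = np.sqrt(var)
    # tolerance absorbs cumulative-sum cancellation on constant windows
    valid = ~has_nan & (std > 1e-7 * np.maximum(1.0, np.abs(mean)))
    return filled, mean, std, valid


def _mass_batch(kmers: np.ndarray, entry: np.ndarray) -> np.ndarray:
    """Z-normalized distances of each k-mer row to every entry window.

    FFT-based sliding dot products (the MASS core): the entry spectrum is
    computed once and shared across all k-mers.  Returns an array of shape
    ``(n_kmers, len(entry) - k + 1)`` with ``inf`` at unmatchable offsets
    (windows containing missing values or with zero variance).
    """
    kmers = np.atleast_2d(np.asarray(kmers, dtype=float))
    entry = np.asarray(entry, dtype=float)
    nk, k = kmers.shape
    m = entry.size
    if m < k:
        return np.empty((nk, 0))
    if np.isnan(kmers).any():
        raise ValueError("query k-mers must not contain missing values")
    kmean = kmers.mean(axis=1)
    kstd = kmers.std(axis=1)
    if (kstd == 0).any():
        raise ValueError("zero-variance k-mer (should be complexity-filtered)")

    filled, wmean, wstd, valid = _window_stats(entry, k)
    nfft = sp_fft.next_fast_len(m + k - 1)
    ef = sp_fft.rfft(filled, nfft)
    kf = sp_fft.rfft(kmers[:, ::-1], nfft, axis=1)
    conv = sp_fft.irfft(ef * kf, nfft, axis=1)
    qt = conv[:, k - 1 : m]  # qt[i, j] = sum_t kmer[i, t] * entry[j + t]

    # dist^2 = 2k (1 - corr); corr from the sliding dot product
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qt - k * np.outer(kmean, wmean)) / (k * np.outer(kstd, wstd))
    dist2 = 2.0 * k * (1.0 - corr)
    dist2 = np.where(valid[None, :], np.maximum(dist2, 0.0), np.inf)
    return np.sqrt(dist2)


def mass_distance_profile(kmer, entry) -> np.ndarray:
    """Distance of one k-mer to every window of an entry's value vector.

    Position ``i`` holds the Euclidean distance between the z-normalized
    k-mer and the z-normalized window ``entry[i : i + k]``; unmatchable
    windows yield ``inf``.  Affine-invariant: windows equal to
    ``a * kmer + b`` (a > 0) are at distance 0.
    """
    return _mass_batch(np.asarray(kmer, dtype=float)[None, :], entry)[0]


# ---------------------------------------------------------------------------
# GC filter


_GC = frozenset("GC")


def _gc_percent_windows(sequence: str, k: int) -> np.ndarray:
    """Sliding percent GC over non-N bases; nan where a window is all N."""
    s = np.frombuffer(sequence.encode(), dtype=np.uint8)
    is_gc = ((s == ord("G")) | (s == ord("C"))).astype(float)
    not_n = (s != ord("N")).astype(float)
    cgc = np.concatenate(([0.0], np.cumsum(is_gc)))
    cnn = np.concatenate(([0.0], np.cumsum(not_n)))
    idx = np.arange(len(sequence) - k + 1)
    denom = cnn[idx + k] - cnn[idx]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * (cgc[idx + k] - cgc[idx]) / denom
    return np.where(denom > 0, pct, np.nan)


def gc_percent(sequence: str) -> float:
    """Percent GC of a sequence, counting G and C over non-N bases."""
    vals = _gc_percent_windows(sequence, len(sequence))
    return float(vals[0])


# ---------------------------------------------------------------------------
# k-mer matching and HSG grouping


def match_kmers(
    query: ReactivityProfile, db: ProfileDatabase, params: SeedParams
) -> list[KmerMatch]:
    """MASS lookup of every retained query k-mer across all database entries.

    An offset is a match when its z-normalized distance is below the
    threshold and the window's GC content deviates from the query k-mer's by
    at most ``max_gc_diff`` percentage points.  K-mers with more surviving
    matches than ``db.total_length / kmer_max_match_every_nt`` are dropped
    entirely (promiscuity filter).
    """
    k = params.kmer_len
    kmers = enumerate_query_kmers(query, params)
    if not kmers:
        return []
    starts = np.array([s for s, _ in kmers])
    kmat = np.stack([w for _, w in kmers])
    query_gc = _gc_percent_windows(query.sequence, k)

    # (entry_id, rows, cols, dists, gc_diffs) per entry, GC-filtered
    hits_per_entry = []
    counts = np.zeros(len(kmers), dtype=np.int64)
    for entry in db:
        if len(entry) < k:
            continue
        values = np.minimum(entry.reactivity, params.max_reactivity)
        dists = _mass_batch(kmat, values)
        entry_gc = _gc_percent_windows(entry.sequence, k)
        rows, cols = np.nonzero(dists <= params.distance_threshold)
        gc_d = np.abs(query_gc[starts[rows]] - entry_gc[cols])
        keep = ~np.isnan(gc_d)  # all-N window on either side: GC undefined
        if params.max_gc_diff is not None:
            keep &= gc_d <= params.max_gc_diff
        rows, cols, gc_d = rows[keep], cols[keep], gc_d[keep]
        counts += np.bincount(rows, minlength=len(kmers))
        hits_per_entry.append((entry.id, rows, cols, dists[rows, cols], gc_d))

    # promiscuity filter: discard a k-mer (with all its matches) when it
    # matches more often than once every kmer_max_match_every_nt db bases;
    # the floor of 1 keeps single matches reportable in tiny databases
    promiscuous = counts > max(
        1.0, db.total_length / params.kmer_max_match_every_nt
    )
    out: list[KmerMatch] = []
    for entry_id, rows, cols, dist, gc_d in hits_per_entry:
        for r, c, d, g in zip(rows, cols, dist, gc_d):
            if promiscuous[r]:
                continue
            out.append(
                KmerMatch(
                    query_start=int(starts[r]),
                    db_entry_id=entry_id,
                    db_start=int(c),
                    znorm_distance=float(d),
                    gc_diff=float(g),
                )
            )
    return out


def group_hsgs(matches: list[KmerMatch], params: SeedParams) -> list[HSG]:
    """Chain co-diagonal matches into high scoring groups.

    Per (database entry, diagonal), matches sorted by query start are
    chained while the gap between consecutive k-mer starts is at most
    ``max_kmer_dist``; chains with at least ``min_kmers`` members become
    HSGs with merged query/db spans.
    """
    k = params.kmer_len
    by_diag: dict[tuple[str, int], list[KmerMatch]] = {}
    for m in matches:
        by_diag.setdefault((m.db_entry_id, m.diagonal), []).append(m)

    hsgs: list[HSG] = []
    for (entry_id, diag) in sorted(by_diag):
        group = sorted(by_diag[(entry_id, diag)], key=lambda m: m.query_start)
        chain: list[KmerMatch] = []
        for m in group + [None]:  # sentinel flushes the last chain
            if chain and (
                m is None or m.query_start - chain[-1].query_start > params.max_kmer_dist
            ):
                if len(chain) >= params.min_kmers:
                    qs = chain[0].query_start
                    qe = chain[-1].query_start + k
                    hsgs.append(
                        HSG(
                            matches=tuple(chain),
                            db_entry_id=entry_id,
                            diagonal=diag,
                            query_span=(qs, qe),
                            db_span=(qs + diag, qe + diag),
                        )
                    )
                chain = []
            if m is not None:
                chain.append(m)
    return hsgs
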