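"""Synthetic reactivity profiles and planted-homology benchmarks.

Real probing data alternates runs of low-reactivity (paired) and
high-reactivity (unpaired/loop) nucleotides.  The generator emulates this
with a two-state Markov chain over paired/unpaired states whose emissions
are a bimodal mixture: a low mode for paired bases and a broad high mode
for unpaired ones, truncated at zero.  The run structure makes the Gini
complexity filter behave as on real data (most 15-mers straddle both
states and pass the 0.3 cutoff) and gives block shuffling a realistic
local context to preserve.

Benchmarks plant copies of query regions into database entries with
controlled reactivity noise and sequence identity, recording the ground
truth so sensitivity and FDR can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import ProfileDatabase, ReactivityProfile, SHAPE_KIND

__all__ = [
    "FixtureSpec",
    "TruthRecord",
    "random_profile",
    "plant_homology",
    "make_benchmark",
    "write_truth_tsv",
]

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class FixtureSpec:
    """Benchmark geometry and perturbation levels.

    ``n_planted`` query regions of ``region_length`` bases are planted into
    ``n_entries`` database entries of ``entry_length`` bases; the planted
    copies receive per-base Gaussian reactivity noise of sd
    ``reactivity_noise_sd`` (re-truncated at 0) and random base
    substitutions leaving ``sequence_identity`` of positions identical.
    """

    n_entries: int = 10
    entry_length: int = 5000
    n_planted: int = 50
    region_length: int = 200
    reactivity_noise_sd: float = 0.15
    sequence_identity: float = 0.8
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.region_length > self.entry_length:
            raise ValueError("region_length must fit inside entry_length")
        if self.reactivity_noise_sd < 0:
            raise ValueError("reactivity_noise_sd must be >= 0")
        if not 0 <= self.sequence_identity <= 1:
            raise ValueError("sequence_identity must be in [0, 1]")


@dataclass(frozen=True)
class TruthRecord:
    """Planted homology: where a query region lives in the database."""

    query_id: str
    query_interval: tuple[int, int]
    db_entry_id: str
    db_interval: tuple[int, int]


def random_profile(
    length: int,
    rng: np.random.Generator,
    prefix: str = "synth",
    p_unpaired: float = 0.4,
    stay: float = 0.85,
) -> ReactivityProfile:
    """A random transcript with structure-like reactivity runs.

    The paired/unpaired state follows a two-state Markov chain
    (stationary unpaired fraction ``p_unpaired``, persistence ``stay``);
    paired bases emit from a low gamma mode, unpaired bases from a broad
    normal mode around 0.85, both truncated at 0.  Sequence is uniform over
    A/C/G/U.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    seq = "".join(rng.choice(_BASES, size=length))
    # Markov chain over states: 1 = unpaired (high reactivity)
    state = np.empty(length, dtype=bool)
    state[0] = rng.random() < p_unpaired
    # switch probabilities preserving the stationary unpaired fraction
    leave = 1.0 - stay
    p_to_unpaired = leave * p_unpaired / (1 - p_unpaired)
    p_to_paired = leave
    for i in range(1, length):
        if state[i - 1]:
            state[i] = rng.random() >= p_to_paired
        else:
            state[i] = rng.random() < p_to_unpaired
    low = rng.gamma(shape=0.8, scale=0.07, size=length)
    high = rng.normal(loc=0.85, scale=0.30, size=length)
    values = np.where(state, high, low)
    values = np.clip(values, 0.0, None)
    return ReactivityProfile(
        id=f"{prefix}", sequence=seq, reactivity=values
    )


def plant_homology(
    query: ReactivityProfile,
    entry: ReactivityProfile,
    spec: FixtureSpec,
    rng: np.random.Generator,
    query_start: int | None = None,
    db_start: int | None = None,
) -> tuple[ReactivityProfile, ReactivityProfile, TruthRecord]:
    """Copy a query region into a database entry with controlled divergence.

    The copy's reactivities receive Gaussian noise of sd
    ``spec.reactivity_noise_sd`` (clipped at 0) and its bases are
    substituted independently so that the expected identity equals
    ``spec.sequence_identity``.  Returns the (unchanged) query, the
    modified entry and the ground-truth record.
    """
    L = spec.region_length
    if L > len(query) or L > len(entry):
        raise ValueError("region does not fit in query or entry")
    if query_start is None:
        query_start = int(rng.integers(0, len(query) - L + 1))
    if db_start is None:
        db_start = int(rng.integers(0, len(entry) - L + 1))

    region_seq = list(query.sequence[query_start : query_start + L])
    sub = rng.random(L) >= spec.sequence_identity
    for i in np.nonzero(sub)[0]:
        choices = [b for b in "ACGU" if b != region_seq[i]]
        region_seq[i] = choices[int(rng.integers(0, 3))]
    region_rea = query.reactivity[query_start : query_start + L].copy()
    if spec.reactivity_noise_sd > 0:
        region_rea = np.clip(
            region_rea + rng.normal(0, spec.reactivity_noise_sd, L), 0.0, None
        )

    new_seq = (
        entry.sequence[:db_start]
        + "".join(region_seq)
        + entry.sequence[db_start + L :]
    )
    new_rea = entry.reactivity.copy()
    new_rea[db_start : db_start + L] = region_rea
    planted = ReactivityProfile(id=entry.id, sequence=new_seq, reactivity=new_rea)
    truth = TruthRecord(
        query_id=query.id,
        query_interval=(query_start, query_start + L),
        db_entry_id=entry.id,
        db_interval=(db_start, db_start + L),
    )
    return query, planted, truth


def make_benchmark(
    spec: FixtureSpec,
) -> tuple[ProfileDatabase, ProfileDatabase, list[TruthRecord]]:
    """Planted-homology benchmark: queries, database and ground truth.

    ``spec.n_planted`` queries of ``spec.region_length`` bases are
    generated and each is planted (with the spec's noise and identity) at a
    non-overlapping random slot of a random database entry.  Returns
    (queries, database, truth records); both databases carry SHAPE-kind
    signal.
    """
    rng = np.random.default_rng(spec.seed)
    entries = [
        random_profile(spec.entry_length, rng, prefix=f"entry{i:03d}")
        for i in range(spec.n_entries)
    ]
    # non-overlapping slots per entry
    slots_per_entry = spec.entry_length // spec.region_length
    slots = [
        (ei, si)
        for ei in range(spec.n_entries)
        for si in range(slots_per_entry)
    ]
    if spec.n_planted > len(slots):
        raise ValueError("database too small for the requested planted regions")
    chosen = rng.choice(len(slots), size=spec.n_planted, replace=False)

    queries = []
    truths: list[TruthRecord] = []
    for qi, slot_idx in enumerate(chosen):
        ei, si = slots[int(slot_idx)]
        query = random_profile(spec.region_length, rng, prefix=f"query{qi:03d}")
        db_start = si * spec.region_length
        _, entries[ei], truth = plant_homology(
            query, entries[ei], spec, rng, query_start=0, db_start=db_start
        )
        queries.append(query)
        truths.append(truth)

    return (
        ProfileDatabase(entries=queries, kind=SHAPE_KIND),
        ProfileDatabase(entries=entries, kind=SHAPE_KIND),
        truths,
    )


def write_truth_tsv(truths: list[TruthRecord], path) -> None:
    """Persist ground truth as TSV with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("query_id\tquery_start\tquery_end\tdb_id\tdb_start\tdb_end\n")
        for t in truths:
            fh.write(
                f"{t.query_id}\t{t.query_interval[0] + 1}\t{t.query_interval[1]}\t"
                f"{t.db_entry_id}\t{t.db_interval[0] + 1}\t{t.db_interval[1]}\n"
            )
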