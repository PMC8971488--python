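"""Gini filter, MASS distances, GC/promiscuity filters and HSG grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from oracles import chain_hsgs_naive, gini_pairwise, mass_naive
from shapesearch.profiles import ProfileDatabase, ReactivityProfile
from shapesearch.seed import (
    KmerMatch,
    SeedParams,
    enumerate_query_kmers,
    gini,
    group_hsgs,
    mass_distance_profile,
    match_kmers,
)
from shapesearch.synthetic import random_profile

positive_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(2, 20),
    elements=st.floats(0.0, 5.0, allow_nan=False),
).filter(lambda x: x.sum() > 1e-3)


class TestGini:
    def test_uniform_is_zero(self):
        assert gini([1, 1, 1, 1]) == pytest.approx(0.0)

    def test_one_hot_closed_form(self):
        assert gini([0, 0, 0, 1]) == pytest.approx(0.75)

    @given(positive_vectors)
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_pairwise_oracle(self, x):
        assert gini(x) == pytest.approx(gini_pairwise(x), abs=1e-12)

    @given(positive_vectors, st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_scale_invariance(self, x, c):
        assert gini(c * x) == pytest.approx(gini(x), abs=1e-9)

    @pytest.mark.parametrize("bad", [[0.0, 0.0], [1.0], [0.3, np.nan]])
    def test_uncomputable_inputs_raise(self, bad):
        with pytest.raises(ValueError):
            gini(bad)


class TestEnumerateKmers:
    def test_flat_profile_yields_nothing(self):
        prof = ReactivityProfile(id="f", sequence="A" * 30, reactivity=np.full(30, 0.5))
        assert enumerate_query_kmers(prof, SeedParams()) == []

    def test_alternating_profile_keeps_every_offset(self):
        prof = ReactivityProfile(
            id="alt", sequence="A" * 30, reactivity=np.tile([0.0, 1.0], 15)
        )
        kmers = enumerate_query_kmers(prof, SeedParams())
        assert [s for s, _ in kmers] == list(range(16))
        # oracle agreement on the window's complexity
        assert gini_pairwise(np.tile([0.0, 1.0], 15)[:15]) > 0.3

    def test_missing_positions_excluded(self):
        rea = np.tile([0.0, 1.0], 13)[:25]
        rea[7] = np.nan
        prof = ReactivityProfile(id="m", sequence="A" * 25, reactivity=rea)
        starts = [s for s, _ in enumerate_query_kmers(prof, SeedParams())]
        assert starts == [8, 9, 10]  # only windows not covering index 7

    def test_short_query_is_empty_not_error(self):
        prof = ReactivityProfile(id="s", sequence="ACGU", reactivity=np.arange(4.0))
        assert enumerate_query_kmers(prof, SeedParams()) == []


class TestMassDistance:
    def test_verbatim_subsequence_at_distance_zero(self, rng):
        entry = rng.random(40)
        kmer = entry[5:13]
        d = mass_distance_profile(kmer, entry)
        assert d[5] == pytest.approx(0.0, abs=1e-6)

    def test_affine_invariance(self, rng):
        kmer = rng.random(8)
        entry = np.concatenate([rng.random(10), 2.0 * kmer + 0.3, rng.random(5)])
        d = mass_distance_profile(kmer, entry)
        assert d[10] == pytest.approx(0.0, abs=1e-6)

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            kmer = rng.random(8)
            entry = rng.random(40)
            np.testing.assert_allclose(
                mass_distance_profile(kmer, entry), mass_naive(kmer, entry), atol=1e-9
            )

    def test_missing_and_flat_windows_unmatchable(self, rng):
        entry = rng.random(30)
        entry[10] = np.nan
        entry[20:28] = 0.7
        d = mass_distance_profile(rng.random(8), entry)
        assert np.isinf(d[3:11]).all()  # windows covering the nan
        assert np.isinf(d[20])  # zero-variance window

    def test_zero_variance_kmer_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            mass_distance_profile(np.full(8, 0.5), rng.random(30))


def _db_of(*profiles):
    return ProfileDatabase(entries=list(profiles))


class TestMatchKmers:
    def test_planted_kmer_found(self, rng):
        query = random_profile(30, rng, prefix="q")
        entry_rea = np.concatenate([rng.random(20), query.reactivity[5:20], rng.random(20)])
        entry = ReactivityProfile(
            id="e",
            sequence="A" * 20 + query.sequence[5:20] + "A" * 20,
            reactivity=entry_rea,
        )
        matches = match_kmers(query, _db_of(entry), SeedParams(max_gc_diff=None))
        assert any(m.query_start == 5 and m.db_start == 20 for m in matches)

    def test_gc_filter_discards_divergent_match(self, rng):
        rea = np.tile([0.05, 0.9], 10)[:15]
        query = ReactivityProfile(id="q", sequence="G" * 9 + "A" * 6, reactivity=rea)
        entry = ReactivityProfile(id="e", sequence="A" * 12 + "G" * 3, reactivity=rea.copy())
        with_gc = match_kmers(query, _db_of(entry), SeedParams(max_gc_diff=10.0))
        without = match_kmers(query, _db_of(entry), SeedParams(max_gc_diff=None))
        assert any(m.db_start == 0 for m in without)
        assert not any(m.db_start == 0 for m in with_gc)

    def test_promiscuous_kmer_dropped_entirely(self, rng):
        # one kmer planted 30x in a database allowing at most 20 matches
        kmer_rea = np.tile([0.05, 0.95, 0.4], 5)
        kmer_seq = "ACGUACGUACGUACG"
        query = ReactivityProfile(id="q", sequence=kmer_seq, reactivity=kmer_rea)
        pad = np.full(5, np.nan)  # unmatchable spacers
        entry_rea = np.concatenate([np.concatenate([kmer_rea, pad]) for _ in range(30)])
        entry_seq = (kmer_seq + "AAAAA") * 30
        entry = ReactivityProfile(id="rep", sequence=entry_seq, reactivity=entry_rea)
        filler = random_profile(4000 - len(entry), rng, prefix="fill")
        params = SeedParams(kmer_max_match_every_nt=200, max_gc_diff=None)
        matches = match_kmers(query, _db_of(entry, filler), params)
        assert len(entry) + len(filler) == 4000
        assert [m for m in matches if m.db_entry_id == "rep"] == []

    def test_empty_database_gives_no_matches(self, rng):
        query = random_profile(30, rng, prefix="q")
        assert match_kmers(query, ProfileDatabase(entries=[]), SeedParams()) == []


class TestGroupHsgs:
    def mk(self, qs, ds, entry="e"):
        return KmerMatch(
            query_start=qs, db_entry_id=entry, db_start=ds, znorm_distance=0.1, gc_diff=0.0
        )

    def test_within_distance_chained(self):
        params = SeedParams(max_kmer_dist=30, min_kmers=2)
        hsgs = group_hsgs([self.mk(0, 100), self.mk(20, 120)], params)
        assert len(hsgs) == 1
        assert hsgs[0].query_span == (0, 35)
        assert hsgs[0].db_span == (100, 135)

    def test_distance_break_prevents_grouping(self):
        params = SeedParams(max_kmer_dist=30, min_kmers=2)
        assert group_hsgs([self.mk(0, 100), self.mk(40, 140)], params) == []

    def test_matches_chaining_oracle_on_random_input(self, rng):
        params = SeedParams(max_kmer_dist=20, min_kmers=2)
        matches = [
            self.mk(int(q), int(q) + int(diag), entry)
            for entry in ("e1", "e2")
            for diag in rng.choice(200, 3, replace=False)
            for q in rng.choice(150, rng.integers(3, 10), replace=False)
        ]
        got = {
            frozenset((m.query_start, m.db_start) for m in h.matches)
            for h in group_hsgs(matches, params)
        }
        expected = chain_hsgs_naive(matches, 20, 2, 15)
        assert got == expected

    def test_hsg_memberships_disjoint_and_subset(self, rng):
        params = SeedParams(max_kmer_dist=25, min_kmers=2)
        matches = [self.mk(int(q), int(q) + 7) for q in rng.choice(120, 30, replace=False)]
        hsgs = group_hsgs(matches, params)
        seen = []
        for h in hsgs:
            for m in h.matches:
                assert m in matches
                assert m not in seen
                seen.append(m)


def test_self_search_always_yields_diagonal_zero_hsg(rng):
    """A database containing the query verbatim must seed on diagonal 0."""
    for trial in range(5):
        query = random_profile(120, rng, prefix=f"q{trial}")
        hsgs = group_hsgs(
            match_kmers(query, _db_of(query), SeedParams()), SeedParams()
        )
        assert any(h.diagonal == 0 for h in hsgs)
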