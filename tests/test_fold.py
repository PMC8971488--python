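"""Consensus-structure evaluation: shuffling, Z-score p-values, support."""

import numpy as np
import pytest
from scipy.stats import norm

from shapesearch.fold import (
    FoldEvaluation,
    MockFoldEngine,
    ProfileAlignment,
    RNAalifoldEngine,
    bp_support,
    evaluate_fold,
    parse_dotbracket,
    retain,
    shuffle_alignment,
    write_stockholm,
)


@pytest.fixture
def hairpin_alignment():
    # two rows supporting a 4-bp stem with a 4-nt loop
    return ProfileAlignment(
        names=["row1", "row2"],
        gapped_sequences=["GGCGAAAACGCC", "GGUGAAAACACC"],
        gapped_reactivities=[
            np.array([0.1, 0.1, 0.1, 0.1, 0.9, 0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1]),
            np.array([0.2, 0.1, 0.1, 0.2, 0.8, 0.9, 0.9, 0.8, 0.1, 0.1, 0.2, 0.1]),
        ],
    )


HAIRPIN = "((((....))))"


class TestProfileAlignment:
    def test_degapping_recovers_rows(self):
        aln = ProfileAlignment(
            names=["a", "b"],
            gapped_sequences=["AC-GU", "ACAGU"],
            gapped_reactivities=[
                np.array([0.1, 0.2, np.nan, 0.3, 0.4]),
                np.array([0.5, 0.6, 0.7, 0.8, 0.9]),
            ],
        )
        seq, rea = aln.degapped_row(0)
        assert seq == "ACGU"
        np.testing.assert_array_equal(rea, [0.1, 0.2, 0.3, 0.4])

    def test_unequal_columns_rejected(self):
        with pytest.raises(ValueError, match="equal column"):
            ProfileAlignment(
                names=["a", "b"],
                gapped_sequences=["ACGU", "ACG"],
                gapped_reactivities=[np.zeros(4), np.zeros(3)],
            )


class TestShuffleAlignment:
    def test_column_multiset_preserved(self, hairpin_alignment):
        rng = np.random.default_rng(3)
        shuf = shuffle_alignment(hairpin_alignment, block=3, rng=rng)
        for orig_seq, shuf_seq in zip(
            hairpin_alignment.gapped_sequences, shuf.gapped_sequences
        ):
            assert sorted(orig_seq) == sorted(shuf_seq)
        cols_before = set(
            zip(*[s for s in hairpin_alignment.gapped_sequences])
        )
        cols_after = set(zip(*[s for s in shuf.gapped_sequences]))
        assert cols_before == cols_after

    def test_rows_and_tracks_stay_synchronized(self, hairpin_alignment):
        rng = np.random.default_rng(4)
        shuf = shuffle_alignment(hairpin_alignment, block=3, rng=rng)
        pairing = {}
        for seq, rea in zip(
            hairpin_alignment.gapped_sequences, hairpin_alignment.gapped_reactivities
        ):
            for b, v in zip(seq, rea):
                pairing.setdefault(b, set()).add(round(float(v), 6))
        for seq, rea in zip(shuf.gapped_sequences, shuf.gapped_reactivities):
            for b, v in zip(seq, rea):
                assert round(float(v), 6) in pairing[b]

    def test_three_columns_single_block(self):
        aln = ProfileAlignment(
            names=["a", "b"],
            gapped_sequences=["ACG", "UGC"],
            gapped_reactivities=[np.arange(3.0), np.arange(3.0)],
        )
        shuf = shuffle_alignment(aln, block=3, rng=np.random.default_rng(0))
        assert sorted(shuf.gapped_sequences[0]) == ["A", "C", "G"]

    def test_deterministic_given_seed(self, hairpin_alignment):
        a = shuffle_alignment(hairpin_alignment, rng=np.random.default_rng(9))
        b = shuffle_alignment(hairpin_alignment, rng=np.random.default_rng(9))
        assert a.gapped_sequences == b.gapped_sequences


class TestEvaluateFold:
    def test_injected_engine_outputs_carried_through(self, hairpin_alignment):
        engine = MockFoldEngine(structure=HAIRPIN, energy=-10.0)
        ev = evaluate_fold(
            hairpin_alignment, engine, n_shuffles=10, rng=np.random.default_rng(0)
        )
        assert ev.structure == HAIRPIN
        assert ev.energy == -10.0

    def test_z_and_p_closed_form(self, hairpin_alignment):
        # true energy -20; null alternating -8/-12: mean -10, sd 2 (ddof=1
        # over an even count) => z = -5
        calls = iter([-20.0] + [-8.0, -12.0] * 50)
        engine = MockFoldEngine(
            structure=HAIRPIN, energy_fn=lambda aln: next(calls)
        )
        ev = evaluate_fold(
            hairpin_alignment, engine, n_shuffles=100, rng=np.random.default_rng(0)
        )
        sd = np.std([-8.0, -12.0] * 50, ddof=1)
        expected_z = (-20.0 + 10.0) / sd
        assert ev.z == pytest.approx(expected_z)
        assert ev.p_value == pytest.approx(norm.cdf(expected_z))
        assert norm.cdf(-5.0) == pytest.approx(2.87e-7, rel=0.01)

    def test_true_energy_at_null_mean_gives_half(self, hairpin_alignment):
        calls = iter([-10.0] + [-8.0, -12.0] * 50)
        engine = MockFoldEngine(structure=HAIRPIN, energy_fn=lambda a: next(calls))
        ev = evaluate_fold(
            hairpin_alignment, engine, n_shuffles=100, rng=np.random.default_rng(0)
        )
        assert ev.z == pytest.approx(0.0)
        assert ev.p_value == pytest.approx(0.5)

    def test_degenerate_null_reports_one(self, hairpin_alignment):
        engine = MockFoldEngine(structure=HAIRPIN, energy=-10.0)
        ev = evaluate_fold(
            hairpin_alignment, engine, n_shuffles=10, rng=np.random.default_rng(0)
        )
        assert ev.p_value == 1.0

    def test_z_invariant_to_energy_offset(self, hairpin_alignment):
        def run(offset):
            calls = iter([-20.0 + offset] + [e + offset for e in [-8.0, -12.0] * 10])
            engine = MockFoldEngine(structure=HAIRPIN, energy_fn=lambda a: next(calls))
            return evaluate_fold(
                hairpin_alignment, engine, n_shuffles=20, rng=np.random.default_rng(0)
            ).z

        assert run(0.0) == pytest.approx(run(100.0))

    def test_deterministic_given_seed(self, hairpin_alignment):
        def run():
            rng = np.random.default_rng(5)
            engine = MockFoldEngine(
                structure=HAIRPIN,
                energy_fn=lambda a: -float(sum(ord(c) for c in a.gapped_sequences[0][:3])) / 20,
            )
            return evaluate_fold(hairpin_alignment, engine, n_shuffles=30, rng=rng)

        assert run().p_value == run().p_value

    def test_all_gap_row_is_degenerate(self):
        aln = ProfileAlignment(
            names=["a", "b"],
            gapped_sequences=["----", "ACGU"],
            gapped_reactivities=[np.full(4, np.nan), np.zeros(4)],
        )
        engine = MockFoldEngine(structure="....", energy=-1.0)
        with pytest.raises(ValueError, match="degenerate"):
            engine.consensus_fold(aln)


class TestBpSupport:
    def test_perfect_support(self, hairpin_alignment):
        fractions = bp_support(HAIRPIN, hairpin_alignment)
        assert fractions == [1.0, 1.0]

    def test_broken_pairs_counted_per_row(self):
        aln = ProfileAlignment(
            names=["good", "bad"],
            gapped_sequences=["GGCGAAAACGCC", "AACGAAAACGCA"],
            gapped_reactivities=[np.zeros(12), np.zeros(12)],
        )
        fractions = bp_support(HAIRPIN, aln)
        assert fractions[0] == pytest.approx(1.0)
        assert fractions[1] == pytest.approx(0.5)  # outer two pairs broken

    def test_gap_touching_pair_unsupported(self):
        aln = ProfileAlignment(
            names=["a", "b"],
            gapped_sequences=["GGCGAAAACGCC", "-GCGAAAACGC-"],
            gapped_reactivities=[np.zeros(12), np.zeros(12)],
        )
        assert bp_support(HAIRPIN, aln)[1] == pytest.approx(0.75)

    def test_unbalanced_structure_rejected(self, hairpin_alignment):
        with pytest.raises(ValueError, match="unbalanced"):
            parse_dotbracket("((..)")


class TestRetain:
    def ev(self, p, supports):
        e = FoldEvaluation(
            structure=HAIRPIN, energy=-10.0, null_energies=np.zeros(3), z=0.0, p_value=p
        )
        e.bp_support_per_row = supports
        return e

    def test_gate_is_exact(self):
        assert retain(self.ev(0.049, [1.0, 0.75]))
        assert not retain(self.ev(0.05, [1.0, 1.0]))  # p must be < 0.05
        assert not retain(self.ev(0.01, [1.0, 0.74]))  # every row >= 0.75
        assert not retain(self.ev(0.2, [1.0, 1.0]))

    def test_mean_mode_relaxes_row_rule(self):
        assert not retain(self.ev(0.01, [1.0, 0.5]))
        assert retain(self.ev(0.01, [1.0, 0.5]), support_mode="mean")

    def test_no_pairs_never_retained(self):
        assert not retain(self.ev(0.001, []))

    def test_monotone_in_p_and_support(self):
        base = self.ev(0.04, [0.8, 0.76])
        assert retain(base)
        assert retain(self.ev(0.01, [0.9, 0.8]))  # better on both axes


def test_stockholm_output(tmp_path, hairpin_alignment):
    out = tmp_path / "region.sto"
    write_stockholm(hairpin_alignment, HAIRPIN, out)
    text = out.read_text()
    assert text.startswith("# STOCKHOLM 1.0")
    assert "#=GC SS_cons" in text
    assert text.rstrip().endswith("//")


@pytest.mark.skipif(
    not RNAalifoldEngine().available(), reason="RNAalifold executable not on PATH"
)
def test_real_engine_folds_hairpin(hairpin_alignment):
    engine = RNAalifoldEngine()
    structure, energy = engine.consensus_fold(hairpin_alignment, slope=1.0, intercept=-0.4)
    pairs = parse_dotbracket(structure)
    assert len(structure) == hairpin_alignment.n_columns
    assert len(pairs) >= 1
    assert energy < 0
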