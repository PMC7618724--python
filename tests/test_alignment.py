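"""Global alignment, column classification, summaries and assessments."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from structcheck.alignment import (
    DEFAULT_SCORING,
    ID_DIFFER_MESSAGE,
    ID_MATCH_MESSAGE,
    SEQ_DIFFER_MESSAGE,
    SEQ_MATCH_MESSAGE,
    Assessment,
    Label,
    ScoringScheme,
    align_strings,
    assess_identifiers,
    assess_sequence,
    classify,
    global_align,
    summarize,
)
from structcheck.synthetic import (
    EditPlan,
    apply_edits,
    make_reference,
    random_edit_plan,
)

from conftest import brute_force_align, chain_from_string, reference_from_string


class TestGlobalAlign:
    def test_identical_sequences_align_without_gaps(self):
        ref = reference_from_string("ACDE")
        cols = global_align(ref, chain_from_string("ACDE"))
        assert len(cols) == 4
        assert [(c.ref_pos, c.query_index) for c in cols] == [
            (1, 0), (2, 1), (3, 2), (4, 3)
        ]

    def test_internal_deletion_yields_reference_only_columns(self):
        # expected alignment computed by exhaustive enumeration: D and E
        # fall in reference-only (missing) columns
        ref = reference_from_string("ACDEFG")
        cols = global_align(ref, chain_from_string("ACFG"))
        ops = "".join(
            "D" if c.ref_pos and c.query_index is not None
            else ("U" if c.query_index is None else "L")
            for c in cols
        )
        assert ops == "DDUUDD"
        assert brute_force_align("ACDEFG", "ACFG")[1] == ops

    def test_single_mismatch_prefers_diagonal_over_double_gap(self):
        score, ops = align_strings("A", "G")
        assert ops == "D"
        assert score == 0.0

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            align_strings("", "ACD")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration_on_short_sequences(self, seed):
        rng = random.Random(seed)
        for _ in range(40):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 8)))
            expected = brute_force_align(a, b)
            got = align_strings(a, b)
            assert got[0] == pytest.approx(expected[0])
            assert got[1] == expected[1]

    def test_score_agrees_with_biopython_global_aligner(self):
        """Independent score oracle: Biopython's pairwise aligner configured
        with the same scoring implements the same optimisation."""
        from Bio.Align import PairwiseAligner

        aligner = PairwiseAligner(
            match_score=1.0,
            mismatch_score=0.0,
            open_gap_score=0.0,
            extend_gap_score=0.0,
            mode="global",
        )
        rng = random.Random(99)
        for _ in range(50):
            a = "".join(rng.choice("ACDEFGHIKL") for _ in range(rng.randint(1, 40)))
            b = "".join(rng.choice("ACDEFGHIKL") for _ in range(rng.randint(1, 40)))
            assert align_strings(a, b)[0] == pytest.approx(aligner.score(a, b))

    def test_nonzero_gap_scores_are_supported(self):
        scoring = ScoringScheme(2.0, -1.0, -2.0)
        score, ops = align_strings("ACGT", "AGT", scoring)
        assert score == pytest.approx(brute_force_align("ACGT", "AGT", scoring)[0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.text(alphabet="ACDEFG", min_size=1, max_size=30),
        b=st.text(alphabet="ACDEFG", min_size=1, max_size=30),
    )
    def test_alignment_columns_are_monotone_and_exhaustive(self, a, b):
        cols = global_align(
            reference_from_string(a), chain_from_string(b)
        )
        ref_positions = [c.ref_pos for c in cols if c.ref_pos is not None]
        query_indices = [c.query_index for c in cols if c.query_index is not None]
        assert ref_positions == list(range(1, len(a) + 1))
        assert query_indices == list(range(len(b)))
        assert all(
            c.ref_pos is not None or c.query_index is not None for c in cols
        )


class TestClassify:
    def test_identical_numbered_from_one_all_id_match(self):
        ref = reference_from_string("MKVWLE")
        chain = chain_from_string("MKVWLE", start=1)
        rows = classify(global_align(ref, chain), chain)
        assert all(r.label is Label.ID_MATCH for r in rows)
        assert not any(r.variation for r in rows)

    def test_offset_numbering_all_id_mismatch(self):
        ref = reference_from_string("MKVWLE")
        chain = chain_from_string("MKVWLE", start=11)
        rows = classify(global_align(ref, chain), chain)
        assert all(r.label is Label.ID_MISMATCH for r in rows)
        assert rows[0].structure_id == "11"
        assert rows[0].uniprot_id == 1

    def test_insertion_code_breaks_id_match(self):
        ref = reference_from_string("MKV")
        chain = chain_from_string("MKV", start=1, icodes={1: "A"})
        rows = classify(global_align(ref, chain), chain)
        assert [r.label for r in rows] == [
            Label.ID_MATCH, Label.ID_MISMATCH, Label.ID_MATCH
        ]
        assert rows[1].structure_id == "2A"

    def test_unknown_residue_is_a_variation_never_an_identity(self):
        ref = reference_from_string("MXV")
        chain = chain_from_string("MXV", start=1)
        rows = classify(global_align(ref, chain), chain)
        assert rows[1].variation  # X aligned to X still not an identity
        assert summarize(rows).identity_pct == pytest.approx(100 * 2 / 3)


class TestSummarize:
    def test_identical_sequences_are_fully_identical(self):
        ref = reference_from_string("MKVWLE")
        chain = chain_from_string("MKVWLE")
        stats = summarize(classify(global_align(ref, chain), chain))
        assert stats.identity_pct == 100.0
        assert stats.n_gap_runs == 0
        assert stats.n_variations == 0
        assert stats.sequence_assessment is Assessment.SEQ_MATCH
        assert stats.id_assessment is Assessment.ID_MATCH

    def test_hand_counted_fixture(self):
        # 20-residue reference, one internal deletion of 5, one substitution:
        # 20 columns, 5 missing, 1 variation, 14 identical -> 70.0 %
        ref = make_reference(20, 123)
        plan = None
        for seed in range(200):
            candidate = EditPlan(
                internal_deletions=((8, 5),),
                substitutions=((2, random.Random(seed).choice(
                    [a for a in "ACDEFGHIKLMNPQRSTVWY"
                     if a != ref.sequence[1]])),),
            )
            try:
                apply_edits(ref, candidate)
            except ValueError:
                continue
            plan = candidate
            break
        assert plan is not None
        chain, _ = apply_edits(ref, plan)
        stats = summarize(classify(global_align(ref, chain), chain))
        assert stats.aln_length == 20
        assert stats.n_missing == 5
        assert stats.n_variations == 1
        assert stats.identity_pct == pytest.approx(70.0)
        assert stats.n_gap_runs == 1

    @pytest.mark.parametrize("seed", range(20))
    def test_count_conservation_identities(self, seed):
        ref = make_reference(80 + seed, 500 + seed)
        chain, rows = apply_edits(ref, random_edit_plan(ref, 900 + seed))
        stats = summarize(classify(global_align(ref, chain), chain))
        assert stats.n_id_match + stats.n_id_mismatch + stats.n_insertions \
            == stats.n_struct_residues == len(chain)
        assert stats.n_id_match + stats.n_id_mismatch + stats.n_missing \
            == len(ref)
        assert stats.aln_length == stats.n_struct_residues + stats.n_missing
        assert stats.aln_length == len(ref) + stats.n_insertions
        assert 0 <= stats.identity_pct <= 100

    @pytest.mark.parametrize("seed", range(10))
    def test_swapping_sequences_mirrors_missing_and_insertions(self, seed):
        ref = make_reference(90, 300 + seed)
        chain, _ = apply_edits(ref, random_edit_plan(ref, 400 + seed))
        fwd = summarize(classify(global_align(ref, chain), chain))
        swapped_ref = reference_from_string(chain.sequence)
        swapped_chain = chain_from_string(ref.sequence)
        rev = summarize(
            classify(global_align(swapped_ref, swapped_chain), swapped_chain)
        )
        assert fwd.n_missing == rev.n_insertions
        assert fwd.n_insertions == rev.n_missing
        assert fwd.n_variations == rev.n_variations

    def test_extra_edits_never_decrease_their_counts(self):
        ref = make_reference(100, 77)
        base = EditPlan(internal_deletions=((40, 4),))
        apply_edits(ref, base)  # must be valid
        base_stats = None
        chain, _ = apply_edits(ref, base)
        base_stats = summarize(classify(global_align(ref, chain), chain))

        more_del = EditPlan(internal_deletions=((40, 4), (60, 3)))
        try:
            chain2, _ = apply_edits(ref, more_del)
        except ValueError:
            pytest.skip("ambiguous extension for this reference draw")
        stats2 = summarize(classify(global_align(ref, chain2), chain2))
        assert stats2.n_missing >= base_stats.n_missing

        for pos in range(10, 30):
            options = [a for a in "ACDEFGHIKLMNPQRSTVWY"
                       if a != ref.sequence[pos - 1]]
            plan = EditPlan(
                internal_deletions=((40, 4),),
                substitutions=((pos, options[0]),),
            )
            try:
                chain3, _ = apply_edits(ref, plan)
            except ValueError:
                continue
            stats3 = summarize(classify(global_align(ref, chain3), chain3))
            assert stats3.n_variations >= base_stats.n_variations
            break

    def test_empty_rows_error(self):
        with pytest.raises(ValueError):
            summarize([])


class TestAssessments:
    def _stats(self, ref_seq, chain_seq, start=1):
        ref = reference_from_string(ref_seq)
        chain = chain_from_string(chain_seq, start=start)
        return summarize(classify(global_align(ref, chain), chain))

    def test_perfect_match_message(self):
        stats = self._stats("MKVW", "MKVW")
        assert assess_sequence(stats) == SEQ_MATCH_MESSAGE
        assert assess_identifiers(stats) == ID_MATCH_MESSAGE

    def test_pure_fragment_has_full_identity_but_differs(self):
        # 100% of aligned pairs identical, yet coverage is partial
        stats = self._stats("MKVWLE", "KVW", start=2)
        assert stats.identity_aligned_pct == 100.0
        assert assess_sequence(stats) == SEQ_DIFFER_MESSAGE

    def test_any_variation_differs(self):
        stats = self._stats("MKVW", "MKVA")
        assert assess_sequence(stats) == SEQ_DIFFER_MESSAGE

    def test_missing_residues_still_allow_id_match(self):
        # identifiers agree for every present residue; missing ones allowed
        stats = self._stats("MKVWLE", "KVW", start=2)
        assert stats.n_missing == 3
        assert assess_identifiers(stats) == ID_MATCH_MESSAGE

    def test_single_id_mismatch_differs(self):
        stats = self._stats("MKVW", "MKVW", start=2)
        assert assess_identifiers(stats) == ID_DIFFER_MESSAGE
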