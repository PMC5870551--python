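"""Unit and property tests for the contact/sequence data model."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmaptools.core import (
    Contact,
    ContactFile,
    ContactMap,
    ContactStatus,
    DuplicateContactError,
    Sequence,
    SequenceFile,
    satisfied_long_range_count,
)
from conftest import make_map
from _oracles import precision_oracle


class TestContact:
    def test_canonicalize_swaps_indices_codes_and_chains(self):
        c = Contact(5, 3, raw_score=0.7, res1_code="M", res2_code="K",
                    chain1="A", chain2="B")
        canon = c.canonicalize()
        assert (canon.res1_index, canon.res2_index) == (3, 5)
        assert (canon.res1_code, canon.res2_code) == ("K", "M")
        assert (canon.chain1, canon.chain2) == ("B", "A")
        assert canon.raw_score == 0.7

    def test_canonical_contact_returned_unchanged(self):
        c = Contact(3, 5, raw_score=0.7)
        assert c.canonicalize() is c

    @given(st.integers(1, 500), st.integers(1, 500))
    @settings(max_examples=100, derandomize=True)
    def test_canonicalize_is_idempotent(self, i, j):
        if i == j:
            with pytest.raises(ValueError, match=f"\\({i}, {j}\\)"):
                Contact(i, j)
            return
        once = Contact(i, j).canonicalize()
        assert once.canonicalize() == once

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(res1_index=0, res2_index=5),
            dict(res1_index=3, res2_index=-1),
            dict(res1_index=4, res2_index=4),
            dict(res1_index=1, res2_index=2, dist_lower=8.0, dist_upper=8.0),
        ],
    )
    def test_invalid_construction_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Contact(**kwargs)


class TestContactMapConstruction:
    def test_add_single_contact(self):
        cmap = ContactMap().add(Contact(3, 5, raw_score=0.7))
        assert len(cmap) == 1 and (3, 5) in cmap

    def test_keep_first_discards_duplicate_with_warning(self):
        cmap = ContactMap().add(Contact(3, 5, raw_score=0.7))
        with pytest.warns(UserWarning, match="duplicate"):
            cmap.add(Contact(3, 5, raw_score=0.9), on_duplicate="keep_first")
        assert cmap.get((3, 5)).raw_score == 0.7

    def test_replace_after_canonicalization(self):
        # the duplicate arrives in swapped order and still replaces
        cmap = ContactMap().add(Contact(3, 5, raw_score=0.7))
        cmap.add(Contact(5, 3, raw_score=0.9), on_duplicate="replace")
        assert len(cmap) == 1
        assert cmap.get((3, 5)).raw_score == 0.9

    def test_error_policy_raises_naming_pair(self):
        cmap = ContactMap().add(Contact(3, 5))
        with pytest.raises(DuplicateContactError, match="\\(3, 5\\)"):
            cmap.add(Contact(3, 5), on_duplicate="error")


class TestSortAndSelect:
    def test_sort_by_score_descending(self):
        cmap = make_map([(1, 9, 0.5), (2, 8, 0.9), (3, 7, 0.7)])
        assert [c.raw_score for c in cmap.sort()] == [0.9, 0.7, 0.5]

    def test_equal_scores_tie_break_by_pair(self):
        cmap = make_map([(7, 9, 0.5), (2, 8, 0.5)])
        assert cmap.sort()[0].pair == (2, 8)

    def test_sort_empty_map(self):
        assert len(ContactMap().sort()) == 0

    def test_top_n_clamps_and_empties(self):
        cmap = make_map([(i, i + 10, i / 10) for i in range(1, 6)])
        assert len(cmap.top_n(0)) == 0
        assert len(cmap.top_n(9)) == 5
        top2 = cmap.top_n(2)
        assert {c.pair for c in top2} == {(5, 15), (4, 14)}

    def test_top_n_rejects_negative(self):
        with pytest.raises(ValueError):
            ContactMap().top_n(-1)

    def test_top_n_monotone_nesting(self):
        rng = random.Random(5)
        cmap = make_map(
            [(i, i + rng.randint(1, 30), rng.random()) for i in range(1, 40)]
        )
        for a in range(0, len(cmap), 3):
            small = {c.pair for c in cmap.top_n(a)}
            large = {c.pair for c in cmap.top_n(a + 5)}
            assert small <= large

    @pytest.mark.parametrize(
        "L,factor,expected",
        [(100, 1.0, 100), (57, 0.5, 28), (10, 0.05, 0)],
    )
    def test_select_by_l_factor_floor_rule(self, L, factor, expected):
        cmap = make_map(
            [(i, j, (i * 211 + j) % 997 / 997.0)
             for i in range(1, 30) for j in range(i + 1, 30)]
        )
        assert len(cmap.select_by_l_factor(factor, L)) == min(expected, len(cmap))

    def test_select_requires_known_length(self):
        cmap = make_map([(1, 9, 0.5)])
        with pytest.raises(ValueError, match="length"):
            cmap.select_by_l_factor(1.0)
        cmap.length_hint = 10
        assert len(cmap.select_by_l_factor(1.0)) == 1


class TestFilters:
    def test_remove_neighbors_boundary_inclusive(self):
        cmap = make_map([(10, 12, 0.1), (10, 20, 0.2), (1, 5, 0.3), (1, 6, 0.4)])
        kept = {c.pair for c in cmap.remove_neighbors(5)}
        # separation >= 5 survives: (1,6) sits exactly on the boundary
        assert kept == {(10, 20), (1, 6)}

    def test_remove_neighbors_identity_at_one(self):
        cmap = make_map([(1, 2, 0.1), (5, 30, 0.2)])
        assert len(cmap.remove_neighbors(1)) == 2

    def test_rescale_min_max(self):
        cmap = make_map([(1, 9, 2.0), (2, 8, 4.0), (3, 7, 6.0)])
        scaled = [c.scaled_score for c in cmap.rescale_scores()]
        assert scaled == [0.0, 0.5, 1.0]
        assert [c.raw_score for c in cmap] == [2.0, 4.0, 6.0]  # untouched

    def test_rescale_shift_invariance(self):
        cmap = make_map([(1, 9, -1.0), (2, 8, 0.0), (3, 7, 1.0)])
        assert [c.scaled_score for c in cmap.rescale_scores()] == [0.0, 0.5, 1.0]

    def test_rescale_degenerate_all_equal(self):
        cmap = make_map([(1, 9, 3.7)])
        with pytest.warns(UserWarning, match="identical"):
            scaled = cmap.rescale_scores()
        assert scaled[0].scaled_score == 0.0

    @given(st.lists(st.integers(-1000, 1000), min_size=2, max_size=30, unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_rescale_preserves_ranking(self, raw):
        scores = [v / 7 for v in raw]
        cmap = make_map([(k + 1, k + 100, s) for k, s in enumerate(scores)])
        scaled = cmap.rescale_scores()
        order_raw = sorted(range(len(scores)), key=lambda k: cmap[k].raw_score)
        order_scaled = sorted(range(len(scores)), key=lambda k: scaled[k].scaled_score)
        assert order_raw == order_scaled


class TestMatchAndPrecision:
    def test_exact_pair_is_true_positive(self):
        matched = make_map([(1, 9, 1.0)]).match(
            make_map([(1, 9, 1.0)]), set(range(1, 11))
        )
        assert matched[0].status is ContactStatus.TRUE_POSITIVE

    def test_absent_pair_with_resolved_residues_is_false_positive(self):
        matched = make_map([(2, 8, 1.0)]).match(
            make_map([(1, 9, 1.0)]), set(range(1, 11))
        )
        assert matched[0].status is ContactStatus.FALSE_POSITIVE

    def test_unresolved_residue_gives_unknown(self):
        matched = make_map([(2, 11, 1.0)]).match(
            make_map([(1, 9, 1.0)]), set(range(1, 11))
        )
        assert matched[0].status is ContactStatus.UNKNOWN

    def test_precision_examples(self):
        statuses = (
            [ContactStatus.TRUE_POSITIVE] * 2
            + [ContactStatus.FALSE_POSITIVE]
            + [ContactStatus.UNKNOWN] * 7
        )
        cmap = ContactMap()
        for k, s in enumerate(statuses):
            cmap.add(Contact(k + 1, k + 50, status=s))
        assert cmap.precision == pytest.approx(2 / 3)

    def test_precision_without_classification_rejected(self):
        cmap = make_map([(1, 9, 1.0)])
        with pytest.raises(ValueError, match="nothing to evaluate"):
            cmap.precision

    def test_self_match_is_perfect(self):
        cmap = make_map([(1, 9, 0.3), (2, 14, 0.8), (5, 30, 0.1)])
        resolved = {i for c in cmap for i in c.pair}
        assert cmap.match(cmap, resolved).precision == 1.0

    def test_precision_agrees_with_set_membership_oracle(self):
        rng = random.Random(42)
        for _ in range(50):
            n = rng.randint(1, 50)
            pred = set()
            while len(pred) < n:
                i = rng.randint(1, 40)
                j = rng.randint(1, 40)
                if i != j:
                    pred.add((min(i, j), max(i, j)))
            ref = {p for p in pred if rng.random() < 0.5}
            resolved = {i for i in range(1, 41) if rng.random() < 0.8}
            matched = make_map([(i, j, 1.0) for i, j in pred]).match(
                make_map([(i, j, 1.0) for i, j in ref]) if ref else ContactMap(),
                resolved,
            )
            expected = precision_oracle(pred, ref, resolved)
            if expected is None:
                with pytest.raises(ValueError):
                    matched.precision
            else:
                assert matched.precision == expected


class TestLongRangeSatisfaction:
    def test_subset_fully_satisfied(self):
        model = make_map([(1, 30, 1.0), (2, 40, 1.0)])
        pred = make_map([(1, 30, 0.9)])
        assert satisfied_long_range_count(model, pred, 23) == 1

    def test_disjoint_maps_give_zero(self):
        assert (
            satisfied_long_range_count(
                make_map([(1, 30, 1.0)]), make_map([(2, 40, 0.9)]), 23
            )
            == 0
        )

    def test_separation_filter_applies_to_prediction(self):
        model = make_map([(1, 30, 1.0), (1, 3, 1.0)])
        pred = make_map([(1, 30, 0.9), (1, 3, 0.8)])
        assert satisfied_long_range_count(model, pred, 23) == 1


class TestSequenceAssociation:
    def test_assign_within_range(self):
        cmap = make_map([(1, 5, 0.5)])
        cmap.assign_sequence(Sequence("q", "MKVLA"), validate=True)
        assert cmap.sequence.seq == "MKVLA"

    def test_out_of_range_index_rejected(self):
        cmap = make_map([(1, 6, 0.5)])
        with pytest.raises(ValueError, match="6"):
            cmap.assign_sequence(Sequence("q", "MKVLA"), validate=True)

    def test_code_mismatch_names_position(self):
        cmap = ContactMap().add(Contact(1, 5, res1_code="M"))
        with pytest.raises(ValueError, match="position 1"):
            cmap.assign_sequence(Sequence("q", "KKVLA"), validate=True)

    def test_gapped_sequence_rejected(self):
        with pytest.raises(ValueError, match="gap-free"):
            make_map([(1, 2, 0.5)]).assign_sequence(Sequence("q", "MK-LA"))


class TestHierarchyContainers:
    def test_contact_file_unique_map_ids(self):
        cfile = ContactFile(id="f", maps=[ContactMap(id="m1")])
        with pytest.raises(ValueError, match="m1"):
            cfile.add(ContactMap(id="m1"))

    def test_sequence_file_rejects_ragged_alignment(self):
        with pytest.raises(ValueError, match="ragged"):
            SequenceFile(
                sequences=[Sequence("a", "AAA"), Sequence("b", "AA")],
                is_alignment=True,
            )

    def test_shift_indices_renumbers_both_ends(self):
        shifted = make_map([(3, 7, 0.5)]).shift_indices(10)
        assert shifted[0].pair == (13, 17)
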