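"""Clone calling, false-positive rate, spread geometry, and summaries."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otoclone.clonecall import (
    NONDISPERSED,
    ClonalSummary,
    PickRecord,
    UndefinedRateError,
    call_clones,
    clonal_spread,
    cross_ear_collision_check,
    false_positive_rate,
    percent,
    summarize,
    tag_match,
)

TAG1 = "GA" * 12
TAG2 = "CT" * 12
TAG3 = "GT" * 12


def make_pick(
    pick_id,
    tag=None,
    ear="HJ-5",
    status="positive",
    outcome=None,
    region="organ of corti",
    cell_type="hair cell",
    section=0,
):
    if outcome is None:
        outcome = "single_tag" if tag else "no_product"
    return PickRecord(
        ear_id=ear,
        pick_id=pick_id,
        plap_status=status,
        region=region,
        cell_type=cell_type,
        section_index=section,
        outcome=outcome,
        tag=tag,
    )


class TestPickRecord:
    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="region"):
            make_pick("p1", TAG1, region="cochlea")
        with pytest.raises(ValueError, match="cell_type"):
            make_pick("p1", TAG1, cell_type="glia")

    def test_single_tag_requires_tag(self):
        with pytest.raises(ValueError):
            make_pick("p1", outcome="single_tag")

    def test_negative_with_product_is_legal_but_flagged(self):
        pick = make_pick("p1", TAG1, status="negative")
        assert pick.is_false_positive


class TestCallClones:
    def test_groups_by_ear_and_tag(self):
        picks = [
            make_pick("A", TAG1),
            make_pick("B", TAG1),
            make_pick("C", TAG2),
        ]
        clones = call_clones(picks)
        assert [(c.tag, c.size) for c in clones] == [(TAG1, 2), (TAG2, 1)]
        assert clones[0].is_multicellular and not clones[1].is_multicellular

    def test_multi_tag_picks_excluded_from_membership(self):
        picks = [
            make_pick("A", TAG1),
            make_pick("B", outcome="multiple_tags"),
        ]
        clones = call_clones(picks)
        assert len(clones) == 1 and clones[0].size == 1

    def test_same_tag_in_two_ears_not_merged(self):
        picks = [make_pick("A", TAG1, ear="HJ-5"), make_pick("B", TAG1, ear="HJ-6")]
        clones = call_clones(picks)
        assert len(clones) == 2
        assert cross_ear_collision_check(clones) == [TAG1]

    def test_no_cross_ear_collision_for_distinct_tags(self):
        clones = call_clones(
            [make_pick("A", TAG1, ear="HJ-5"), make_pick("B", TAG2, ear="HJ-6")]
        )
        assert cross_ear_collision_check(clones) == []

    def test_partition_property(self):
        # every positive single-tag pick lands in exactly one clone
        picks = [
            make_pick(f"p{i}", tag, section=i)
            for i, tag in enumerate([TAG1, TAG1, TAG2, TAG3, TAG3, TAG3])
        ]
        clones = call_clones(picks)
        member_ids = [m.pick_id for c in clones for m in c.members]
        assert sorted(member_ids) == sorted(p.pick_id for p in picks)
        assert sum(c.size for c in clones) == len(picks)


class TestFalsePositiveRate:
    def test_three_of_108(self):
        picks = [
            make_pick(f"n{i}", TAG1 if i < 3 else None, status="negative")
            for i in range(108)
        ]
        assert false_positive_rate(picks) == pytest.approx(3 / 108)
        assert percent(3, 108) == 2.8

    def test_zero_of_108(self):
        picks = [make_pick(f"n{i}", status="negative") for i in range(108)]
        assert false_positive_rate(picks) == 0.0

    def test_undefined_without_negatives(self):
        with pytest.raises(UndefinedRateError):
            false_positive_rate([make_pick("p1", TAG1)])


class TestClonalSpread:
    @pytest.mark.parametrize(
        "indices,thickness,expected",
        [([5, 8], 14, 42), ([0, 29], 14, 406), ([2, 2, 5], 14, 42), ([0, 3], 12, 36)],
    )
    def test_spread_values(self, indices, thickness, expected):
        assert clonal_spread(indices, thickness) == expected

    def test_same_section_is_nondispersed_not_zero(self):
        result = clonal_spread([7], 14)
        assert result is NONDISPERSED
        assert clonal_spread([4, 4, 4], 14) is NONDISPERSED
        assert repr(result) == "(-)"

    def test_empty_indices_error(self):
        with pytest.raises(ValueError):
            clonal_spread([], 14)

    @given(
        indices=st.lists(st.integers(0, 500), min_size=1, max_size=20),
        shift=st.integers(0, 100),
    )
    @settings(max_examples=100, derandomize=True)
    def test_translation_invariance_and_nonnegativity(self, indices, shift):
        base = clonal_spread(indices, 14)
        shifted = clonal_spread([i + shift for i in indices], 14)
        if base is NONDISPERSED:
            assert shifted is NONDISPERSED
            assert len(set(indices)) == 1
        else:
            assert base == shifted > 0


class TestTagMatch:
    def test_exact_identity_default(self):
        assert tag_match(TAG1, TAG1)
        one_off = "CA" + TAG1[2:]
        assert not tag_match(TAG1, one_off)
        assert tag_match(TAG1, one_off, max_mismatches=1)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError):
            tag_match(TAG1, TAG1[:-2])

    def test_case_insensitive(self):
        assert tag_match(TAG1, TAG1.lower())


class TestSummarize:
    def test_counts_and_complementarity(self):
        picks = (
            [make_pick(f"s{i}", TAG1, section=i) for i in range(2)]
            + [make_pick("s2", TAG2)]
            + [make_pick("m0", outcome="multiple_tags")]
            + [make_pick("x0")]
            + [make_pick(f"n{i}", status="negative") for i in range(4)]
        )
        s = summarize(picks)
        assert s.n_picks == 9
        assert s.n_positive == 5 and s.n_negative == 4
        assert s.n_positive_with_product == 4
        assert s.n_single_tag == 3 and s.n_multi_tag == 1
        assert s.n_single_cell_clones == 1 and s.n_multicellular_clones == 1
        # complementarity of recomputed percentages
        assert s.pct_positive + s.pct_negative == pytest.approx(100.0)
        assert s.pct_single_tag + s.pct_multi_tag == pytest.approx(100.0)
        assert s.pct_single_cell + s.pct_multicellular == pytest.approx(100.0)
        assert sum(r.size for r in s.clone_rows) == s.n_single_tag

    def test_empty_pick_set_flags_undefined(self):
        s = summarize([])
        assert s.n_picks == 0
        assert s.pct_positive is None
        assert "pct_positive" in s.undefined_fractions

    def test_presence_grid_requires_two_picks(self):
        picks = [
            make_pick("a", TAG1, region="spiral limbus", cell_type="interdental"),
            make_pick("b", TAG2, region="spiral limbus", cell_type="interdental"),
            make_pick("c", TAG3, region="utricle", cell_type="nonsensory epithelial"),
        ]
        s = summarize(picks)
        assert s.presence_grid[("HJ-5", "spiral limbus")] is True
        assert s.presence_grid[("HJ-5", "utricle")] is False

    def test_from_counts_percentages(self):
        s = ClonalSummary.from_counts(655, 547, 108, 3, 285, 230, 55, 195, 35)
        assert s.pct_positive == 83.5
        assert s.pct_fpr == 2.8
        assert s.pct_positive_with_product == 52.1  # recomputed, not the printed 51.1
        assert s.render_text().splitlines()[1].endswith("na")
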