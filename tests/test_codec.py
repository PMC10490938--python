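"""Legend, word validation, day binning, record encoding, and rendering."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from udswords import (
    BinningScheme,
    DEFAULT_LEGEND,
    ResultCategory,
    SymbolLegend,
    VisitRecord,
    bin_visit_day,
    decode_word,
    encode_cohort,
    encode_participant,
    render_cohort,
    validate_word,
)

ALPHABET = sorted(DEFAULT_LEGEND.alphabet)
CATEGORIES = [c for c in ResultCategory if c is not ResultCategory.NOT_REQUIRED]

words_st = st.text(alphabet=ALPHABET, min_size=1, max_size=60)


class TestLegend:
    def test_default_legend_is_the_quinary_alphabet(self):
        assert DEFAULT_LEGEND.alphabet == frozenset("+-o*_")
        assert DEFAULT_LEGEND.symbol(ResultCategory.MISSING) == "o"
        assert DEFAULT_LEGEND.category("*") is ResultCategory.MIXED

    def test_non_injective_mapping_rejected(self):
        with pytest.raises(ValueError, match="injective"):
            SymbolLegend({ResultCategory.POSITIVE: "+", ResultCategory.NEGATIVE: "+"})

    def test_non_printable_symbol_rejected(self):
        with pytest.raises(ValueError, match="printable ASCII"):
            SymbolLegend({ResultCategory.POSITIVE: "é"})

    def test_oversized_legend_warns_but_is_usable(self):
        # Likert-style extension past the seven-symbol readability bound
        import enum

        Cat = enum.Enum("Cat", [f"C{i}" for i in range(10)])
        mapping = {Cat[f"C{i}"]: s for i, s in enumerate("+-o*_12345")}
        with pytest.warns(UserWarning, match="readability"):
            legend = SymbolLegend(mapping)
        assert len(legend.alphabet) == 10


class TestValidateWord:
    @pytest.mark.parametrize(
        "word", ["+-o*_", "+++++---+--------------o-"]
    )
    def test_valid_words_pass_and_keep_length(self, word):
        assert len(validate_word(word)) == len(word)

    def test_first_offending_position_reported(self):
        with pytest.raises(ValueError, match="position 3"):
            validate_word("+-x")

    def test_empty_word_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            validate_word("")

    def test_one_based_symbol_access(self, example_word):
        w = validate_word(example_word)
        assert w.symbol_at(1) == "+"
        assert w.symbol_at(24) == "o"
        with pytest.raises(IndexError):
            w.symbol_at(0)


class TestBinning:
    @pytest.mark.parametrize(
        "day,expected",
        [(0, 0), (7, 1), (15, 2), (21, 3), (162, 23), (169, 24)],
    )
    def test_weekly_floor_binning(self, day, expected, weekly_scheme):
        assert bin_visit_day(day, weekly_scheme) == expected

    def test_day_before_origin_rejected(self):
        scheme = BinningScheme(bin_width=7, origin_day=7, n_bins=4)
        with pytest.raises(ValueError, match="precedes"):
            bin_visit_day(3, scheme)


class TestEncodeParticipant:
    def test_example_table_encodes_to_printed_word(
        self, table_records, weekly_scheme, example_word
    ):
        word = encode_participant(table_records, weekly_scheme)
        assert word == example_word

    def test_agreeing_duplicates_collapse_to_shared_symbol(self):
        scheme = BinningScheme(n_bins=1)
        recs = [
            VisitRecord("1", ResultCategory.NEGATIVE, 0),
            VisitRecord("1", ResultCategory.NEGATIVE, 3),
        ]
        assert encode_participant(recs, scheme) == "-"

    def test_disagreeing_duplicates_become_mixed(self):
        scheme = BinningScheme(n_bins=1)
        recs = [
            VisitRecord("1", ResultCategory.NEGATIVE, 0),
            VisitRecord("1", ResultCategory.POSITIVE, 3),
        ]
        assert encode_participant(recs, scheme) == "*"

    def test_missing_plus_substantive_yields_substantive(self):
        # the specimen exists; the failed attempt in the same bin is moot
        scheme = BinningScheme(n_bins=1)
        recs = [
            VisitRecord("1", ResultCategory.MISSING, 0),
            VisitRecord("1", ResultCategory.NEGATIVE, 3),
        ]
        assert encode_participant(recs, scheme) == "-"

    def test_lattice_masks_unscheduled_empty_bins(self):
        scheme = BinningScheme(n_bins=4)
        recs = [VisitRecord("1", ResultCategory.POSITIVE, 0)]
        word = encode_participant(recs, scheme, lattice="o_o_")
        assert word == "+_o_"

    def test_record_past_schedule_rejected(self):
        scheme = BinningScheme(n_bins=2)
        recs = [VisitRecord("1", ResultCategory.POSITIVE, 20)]
        with pytest.raises(ValueError, match="past the last"):
            encode_participant(recs, scheme)

    def test_mixed_participant_ids_rejected(self):
        scheme = BinningScheme(n_bins=2)
        recs = [
            VisitRecord("1", ResultCategory.POSITIVE, 0),
            VisitRecord("2", ResultCategory.POSITIVE, 7),
        ]
        with pytest.raises(ValueError, match="multiple participants"):
            encode_participant(recs, scheme)


@st.composite
def single_record_sets(draw):
    """Record sets with at most one record per bin (the lossless case)."""
    n_bins = draw(st.integers(1, 12))
    cats = draw(
        st.lists(
            st.one_of(st.none(), st.sampled_from(CATEGORIES)),
            min_size=n_bins,
            max_size=n_bins,
        )
    )
    recs = [
        VisitRecord("p", cat, b * 7 + draw(st.integers(0, 6)))
        for b, cat in enumerate(cats)
        if cat is not None
    ]
    return recs, cats, BinningScheme(bin_width=7, n_bins=n_bins)


class TestCodecProperties:
    @given(single_record_sets())
    def test_round_trip_recovers_categories(self, case):
        recs, cats, scheme = case
        word = encode_participant(recs, scheme)
        expected = [c if c is not None else ResultCategory.MISSING for c in cats]
        assert decode_word(word) == expected

    @given(single_record_sets(), st.randoms(use_true_random=False))
    def test_encoding_is_order_independent(self, case, rnd):
        recs, _, scheme = case
        shuffled = list(recs)
        rnd.shuffle(shuffled)
        assert encode_participant(shuffled, scheme) == encode_participant(recs, scheme)

    @given(single_record_sets())
    def test_length_equals_n_bins(self, case):
        recs, _, scheme = case
        assert len(encode_participant(recs, scheme)) == scheme.n_bins

    def test_mixed_symbol_appears_iff_bin_disagrees(self):
        scheme = BinningScheme(n_bins=3)
        recs = [
            VisitRecord("p", ResultCategory.POSITIVE, 0),
            VisitRecord("p", ResultCategory.POSITIVE, 7),
            VisitRecord("p", ResultCategory.NEGATIVE, 8),
            VisitRecord("p", ResultCategory.NEGATIVE, 14),
            VisitRecord("p", ResultCategory.NEGATIVE, 15),
        ]
        assert encode_participant(recs, scheme) == "+*-"


class TestRenderCohort:
    def test_rows_align_on_a_common_word_column(self):
        block = render_cohort({4: "------", 17: "++o+++"})
        lines = block.splitlines()
        assert len(lines) == 2
        offsets = {line.index(": ") for line in lines}
        assert len(offsets) == 1
        assert lines[0].endswith("------")

    def test_single_participant_single_row(self):
        assert render_cohort({"9": "+-"}) == "9: +-"

    def test_empty_cohort_renders_empty_block(self):
        assert render_cohort({}) == ""

    def test_simulated_cohort_columns_align(self, sim_words):
        words = {f"id{i}": w for i, w in enumerate(sim_words[:10])}
        lines = render_cohort(words).splitlines()
        starts = {len(line) - len(line.split(": ", 1)[1]) for line in lines}
        assert len(starts) == 1


def test_encode_cohort_with_roster_includes_recordless_participants(weekly_scheme):
    recs = [VisitRecord("1", ResultCategory.POSITIVE, 0)]
    words = encode_cohort(recs, weekly_scheme, participants=["1", "2"])
    assert set(words) == {"1", "2"}
    assert words["2"] == "o" * 25
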