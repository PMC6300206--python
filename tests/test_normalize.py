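"""Preparation parsing, count resolution, type status, name cardinality."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from fishsurvey.normalize import (
    CountPolicy,
    CountSource,
    classify_type_status,
    name_cardinality,
    parse_preparations,
    resolve_count,
)


class TestParsePreparations:
    def test_worked_example_etoh_skeleton(self):
        parse = parse_preparations("EtOH -15, Skeleton—1")
        assert parse.category_counts == {"ethanol": 15, "skeleton": 1}
        assert parse.total_individuals == 16
        assert not parse.media_mentioned

    @pytest.mark.parametrize("raw", [None, "", "   "])
    def test_absent_input_gives_empty_parse(self, raw):
        parse = parse_preparations(raw)
        assert parse.category_counts == {}
        assert parse.total_individuals is None
        assert not parse.media_mentioned

    def test_mixed_tokens_with_unrecognized(self):
        parse = parse_preparations("c&s - 2; tissue: 3; churn")
        assert parse.category_counts == {
            "cleared_and_stained": 2,
            "tissue": 3,
            "other": None,
        }
        assert parse.total_individuals == 5
        assert parse.unrecognized_tokens == ["churn"]

    @pytest.mark.parametrize(
        "token", ["EtOH-3", "EtOH—3", "EtOH–3", "EtOH: 3", "EtOH 3", "EtOH - 3"]
    )
    def test_count_separator_dialects(self, token):
        parse = parse_preparations(token)
        assert parse.category_counts == {"ethanol": 3}

    def test_hyphen_next_to_digit_is_separator_not_minus(self):
        assert parse_preparations("EtOH -15").category_counts["ethanol"] == 15

    def test_media_token_sets_flag(self):
        parse = parse_preparations("EtOH - 4, photo")
        assert parse.media_mentioned
        assert parse.category_counts == {"ethanol": 4, "media": None}

    def test_same_category_counts_accumulate(self):
        parse = parse_preparations("EtOH - 4; alcohol: 6")
        assert parse.category_counts == {"ethanol": 10}

    def test_compound_label_falls_back_to_containment(self):
        parse = parse_preparations("dry skeleton prep - 2")
        assert parse.category_counts == {"skeleton": 2}

    @settings(max_examples=200, derandomize=True)
    @given(st.text(max_size=60))
    def test_total_is_parser_invariant_on_arbitrary_text(self, text):
        """Parser is total; total_individuals equals the sum of numeric
        category counts for any input."""
        parse = parse_preparations(text)
        nums = [v for v in parse.category_counts.values() if v is not None]
        assert parse.total_individuals == (sum(nums) if nums else None)
        assert all(v >= 0 for v in nums)


class TestResolveCount:
    def test_individual_count_field_wins(self):
        rec = make_record(individual_count_verbatim="12",
                          preparations_verbatim="EtOH -15, Skeleton—1")
        res = resolve_count(rec, parse_preparations(rec.preparations_verbatim))
        assert (res.resolved_count, res.source) == (12, CountSource.individual_count_field)

    def test_parsed_from_preparations_when_count_absent(self):
        rec = make_record(preparations_verbatim="EtOH -15, Skeleton—1")
        res = resolve_count(rec, parse_preparations(rec.preparations_verbatim))
        assert (res.resolved_count, res.source) == (16, CountSource.parsed_from_preparations)

    @pytest.mark.parametrize("placeholder", ["0", "9999", "99999"])
    def test_placeholder_treated_as_absent(self, placeholder):
        rec = make_record(individual_count_verbatim=placeholder, family_verbatim="Percidae")
        res = resolve_count(rec, parse_preparations(None))
        assert (res.resolved_count, res.source) == (1, CountSource.default_one)

    def test_unresolved_without_evidence(self):
        rec = make_record()
        res = resolve_count(rec, parse_preparations(None))
        assert (res.resolved_count, res.source) == (None, CountSource.unresolved)

    def test_default_one_switchable_off(self):
        rec = make_record(family_verbatim="Percidae")
        res = resolve_count(rec, parse_preparations(None), CountPolicy(default_one=False))
        assert res.source == CountSource.unresolved

    def test_garbage_count_field_falls_through(self):
        rec = make_record(individual_count_verbatim="ca. 12",
                          preparations_verbatim="EtOH - 3")
        res = resolve_count(rec, parse_preparations(rec.preparations_verbatim))
        assert (res.resolved_count, res.source) == (3, CountSource.parsed_from_preparations)


class TestClassifyTypeStatus:
    @pytest.mark.parametrize(
        "value,expected",
        [
            ("Holotype", "primary"),
            ("lectotype", "primary"),
            ("NEOTYPE", "primary"),
            ("syntype series", "primary"),
            ("Paratype", "secondary"),
            ("paratype of Perca flavescens", "secondary"),
            ("paralectotype", "secondary"),  # must not match embedded lectotype
            ("allotype", "secondary"),
            ("", "none"),
            (None, "none"),
            ("possible type material", "none"),
        ],
    )
    def test_vocabulary_scan(self, value, expected):
        assert classify_type_status(value) == expected

    @settings(max_examples=100, derandomize=True)
    @given(st.text(max_size=30))
    def test_never_both_primary_and_secondary(self, text):
        assert classify_type_status(text) in ("primary", "secondary", "none")


class TestNameCardinality:
    def test_trim_only(self):
        recs = [
            make_record("a", scientific_name_verbatim="Lepomis macrochirus"),
            make_record("b", scientific_name_verbatim="Lepomis macrochirus "),
        ]
        assert name_cardinality(recs, "scientific_name_verbatim") == 1

    def test_case_sensitive_no_cleaning(self):
        recs = [
            make_record("a", scientific_name_verbatim="Lepomis macrochirus"),
            make_record("b", scientific_name_verbatim="lepomis macrochirus"),
        ]
        assert name_cardinality(recs, "scientific_name_verbatim") == 2

    def test_absent_values_excluded(self):
        recs = [make_record("a"), make_record("b", family_verbatim="Percidae")]
        assert name_cardinality(recs, "family_verbatim") == 1

    def test_known_distinct_count_among_1000_padded_strings(self):
        rng = random.Random(5)
        base = [f"Name {i}" for i in range(137)]
        recs = [
            make_record(
                f"r{j}",
                scientific_name_verbatim=" " * rng.randrange(3) + rng.choice(base)
                + " " * rng.randrange(3),
            )
            for j in range(1000)
        ]
        used = {r.scientific_name_verbatim.strip() for r in recs}
        assert name_cardinality(recs, "scientific_name_verbatim") == len(used)
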