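"""Collection discovery, reconciliation and registry coverage."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from _oracles import group_counts
from conftest import make_record
from fishsurvey.discovery import (
    MOBILIZATION_STATUSES,
    CollectionIdentity,
    RegistryEntry,
    apply_fish_collection_definition,
    classify_registry_coverage,
    drop_excluded_records,
    flag_by_indicator_taxon,
    flag_by_metadata,
    reconcile,
)
from fishsurvey.dwc import Recordset


def rs(rsid, title, description="", publisher=""):
    return Recordset(recordset_id=rsid, title=title, description=description,
                     publisher=publisher)


class TestFlagByMetadata:
    @pytest.mark.parametrize(
        "title,expected",
        [
            ("Ichthyology Collection", True),
            ("Herpetology Collection", False),
            ("Catfish Survey of Texas", True),  # substring hit, tolerated
            ("FISH of the Great Lakes", True),
            ("Mammal Survey", False),
        ],
    )
    def test_title_substring(self, title, expected):
        flagged = flag_by_metadata([rs("x", title)])
        assert (("x" in flagged)) == expected

    def test_description_and_publisher_searched(self):
        catalog = [
            rs("a", "Vertebrates", description="mostly fishes"),
            rs("b", "Vertebrates", publisher="Museum of Ichthyology"),
            rs("c", "Vertebrates"),
        ]
        assert flag_by_metadata(catalog) == {"a", "b"}

    def test_empty_keywords_rejected(self):
        with pytest.raises(ValueError):
            flag_by_metadata([rs("a", "t")], keywords=())


class TestFlagByIndicatorTaxon:
    def test_three_records_one_row(self):
        recs = [
            make_record(f"r{i}", "rs1", institution_code="UF",
                        collection_code="Fish", family_verbatim="Centrarchidae")
            for i in range(3)
        ]
        rows = flag_by_indicator_taxon(recs)
        assert len(rows) == 1
        assert rows[0]["record_count"] == 3
        assert rows[0]["recordset_id"] == "rs1"

    def test_recordset_without_indicator_absent(self):
        recs = [make_record("r1", "rs1", family_verbatim="Percidae")]
        assert flag_by_indicator_taxon(recs) == []

    def test_case_insensitive_family_match(self):
        recs = [make_record("r1", "rs1", family_verbatim="centrarchidae ")]
        assert len(flag_by_indicator_taxon(recs)) == 1

    def test_distinct_triples_get_distinct_rows(self):
        recs = [
            make_record("r1", "rs1", institution_code="UF", family_verbatim="Centrarchidae"),
            make_record("r2", "rs1", institution_code="UMMZ", family_verbatim="Centrarchidae"),
        ]
        assert len(flag_by_indicator_taxon(recs)) == 2


REGISTRY = [
    RegistryEntry("UF", "Florida Museum", [], "US", "idigbio"),
    RegistryEntry("USNM", "National Museum", ["NMNH"], "US", "idigbio"),
    RegistryEntry("UWFC", "U Washington Fish Collection", [], "US", "idigbio"),
]


class TestReconcile:
    def test_exact_code_match(self):
        recs = [make_record("r1", "rs1", institution_code="UF", collection_code="Fish")]
        (ident,) = reconcile({"metadata_keyword": {"rs1"}}, recs, REGISTRY)
        assert ident.registry_code == "UF"
        assert ident.identity_id == "UF"
        assert ident.discovered_by == {"metadata_keyword"}

    def test_alias_match(self):
        recs = [make_record("r1", "rs1", institution_code="NMNH", collection_code="Fishes")]
        (ident,) = reconcile({"indicator_taxon": {"rs1"}}, recs, REGISTRY)
        assert ident.registry_code == "USNM"

    def test_no_codes_no_registry_hit_retained(self):
        recs = [make_record("r1", "rs1")]
        (ident,) = reconcile({"metadata_keyword": {"rs1"}}, recs, REGISTRY)
        assert ident.registry_code is None
        assert ident.identity_id == "rs1"
        assert ident.member_recordset_ids == {"rs1"}

    def test_merge_rule_folds_sub_collections(self):
        subs = ["rsA", "rsB", "rsC", "rsD"]
        labels = ["UWFC adult", "UWFC juvenile", "UWFC larval", "UWFC egg"]
        recs = [
            make_record(f"r{i}", rsid, institution_code="UWFC",
                        collection_code=f"Fish {lbl.split()[1]}")
            for i, (rsid, lbl) in enumerate(zip(subs, labels))
        ]
        rules = {"merges": [{"identity_id": "UWFC", "recordset_ids": subs, "labels": labels}]}
        (ident,) = reconcile({"metadata_keyword": set(subs)}, recs, REGISTRY, rules)
        assert len(ident.merged_from) == 4
        assert ident.member_recordset_ids == set(subs)
        assert ident.registry_code == "UWFC"

    def test_ambiguous_alias_is_hard_error(self):
        registry = [
            RegistryEntry("A1", "one", ["X"], "US", "none"),
            RegistryEntry("A2", "other", ["X"], "US", "none"),
        ]
        recs = [make_record("r1", "rs1", institution_code="X")]
        with pytest.raises(ValueError, match="multiple registry entries"):
            reconcile({"metadata_keyword": {"rs1"}}, recs, registry)

    def test_partition_each_recordset_exactly_one_identity(self):
        rng = random.Random(0)
        recs = []
        for i in range(20):
            inst = rng.choice(["UF", "USNM", None])
            recs.append(make_record(f"r{i}", f"rs{i % 8}", institution_code=inst,
                                    collection_code="Fish" if inst else None))
        flagged = {"metadata_keyword": {f"rs{i}" for i in range(8)}}
        identities = reconcile(flagged, recs, REGISTRY)
        seen = [rsid for i in identities for rsid in i.member_recordset_ids]
        assert sorted(seen) == sorted(set(seen))
        assert set(seen) == {f"rs{i}" for i in range(8)}


class TestFishCollectionDefinition:
    def _ident(self, rsid="rs1"):
        return CollectionIdentity(identity_id="X", member_recordset_ids={rsid},
                                  discovered_by={"metadata_keyword"})

    def test_all_fossil_identity_dropped(self):
        recs = [make_record(f"r{i}", "rs1", family_verbatim="Percidae", is_fossil=True)
                for i in range(3)]
        assert apply_fish_collection_definition([self._ident()], recs) == []

    def test_mixed_fossil_identity_kept(self):
        recs = [
            make_record("r1", "rs1", family_verbatim="Percidae", is_fossil=True),
            make_record("r2", "rs1", family_verbatim="Percidae"),
        ]
        kept = apply_fish_collection_definition([self._ident()], recs)
        assert len(kept) == 1
        # per-record exclusion happens downstream
        assert len(drop_excluded_records(recs)) == 1

    def test_keyword_decoy_with_no_fish_records_dropped(self):
        recs = [make_record(f"r{i}", "rs1", family_verbatim="Colubridae")
                for i in range(3)]
        assert apply_fish_collection_definition([self._ident()], recs) == []

    def test_living_stock_identity_dropped(self):
        recs = [make_record("r1", "rs1", family_verbatim="Percidae", is_living_stock=True)]
        assert apply_fish_collection_definition([self._ident()], recs) == []

    def test_misspelled_fish_family_still_counts_as_fish(self):
        recs = [make_record("r1", "rs1", family_verbatim="Percidaee")]
        kept = apply_fish_collection_definition([self._ident()], recs)
        assert len(kept) == 1


class TestRegistryCoverage:
    def test_all_discovered_gives_empty_table(self):
        registry = [RegistryEntry("UF", mobilization_status="idigbio")]
        discovered = [CollectionIdentity("UF", registry_code="UF",
                                         member_recordset_ids={"rs"},
                                         discovered_by={"metadata_keyword"})]
        assert classify_registry_coverage(registry, discovered) == []

    def test_percentages_sum_to_100(self):
        rng = random.Random(3)
        registry = [
            RegistryEntry(f"C{i}", mobilization_status=rng.choice(MOBILIZATION_STATUSES))
            for i in range(57)
        ]
        table = classify_registry_coverage(registry, [])
        assert abs(sum(row["percent"] for row in table) - 100.0) <= 0.1
        assert sum(row["count"] for row in table) == 57

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from(MOBILIZATION_STATUSES), min_size=1, max_size=60))
    def test_bucket_counts_equal_brute_force_group_by(self, statuses):
        registry = [RegistryEntry(f"C{i}", mobilization_status=s)
                    for i, s in enumerate(statuses)]
        table = classify_registry_coverage(registry, [])
        expected = group_counts(list(statuses))
        assert {row["mobilization_status"]: row["count"] for row in table} == expected
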