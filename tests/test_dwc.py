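"""Occurrence and catalog readers/writers."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_record
from fishsurvey.dwc import (
    SpecimenRecord,
    compute_geopoint,
    read_media_table,
    read_occurrences,
    read_recordset_catalog,
    write_occurrences,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestReadDelimited:
    def test_three_row_identity_read(self, tmp_path):
        src = _write(
            tmp_path,
            "occ.csv",
            "occurrenceID,datasetID,family,decimalLatitude,decimalLongitude\n"
            "a,rs1,Percidae,29.6,-82.3\n"
            "b,rs1,Cottidae,,\n"
            "c,rs2,,0,0\n",
        )
        recs = read_occurrences(src)
        assert [r.record_id for r in recs] == ["a", "b", "c"]
        assert recs[0].family_verbatim == "Percidae"
        assert recs[0].has_geopoint_indexed
        assert not recs[1].has_geopoint_indexed
        # (0, 0) is a valid geopoint: no null-island heuristic
        assert recs[2].has_geopoint_indexed

    def test_out_of_range_latitude_forces_absent_geopoint(self, tmp_path):
        src = _write(
            tmp_path,
            "occ.csv",
            "occurrenceID,datasetID,decimalLatitude,decimalLongitude\nx,rs,91.0,10.0\n",
        )
        (rec,) = read_occurrences(src)
        assert rec.latitude is None
        assert not rec.has_geopoint_indexed

    def test_unparseable_coordinate_keeps_record(self, tmp_path):
        src = _write(
            tmp_path,
            "occ.csv",
            "occurrenceID,datasetID,decimalLatitude,decimalLongitude\nx,rs,abc,10.0\n",
        )
        (rec,) = read_occurrences(src)
        assert rec.record_id == "x"
        assert not rec.has_geopoint_indexed

    def test_missing_id_column_is_hard_error(self, tmp_path):
        src = _write(tmp_path, "occ.csv", "family,decimalLatitude\nPercidae,1\n")
        with pytest.raises(ValueError, match="id column"):
            read_occurrences(src)

    def test_duplicate_record_id_is_hard_error(self, tmp_path):
        src = _write(tmp_path, "occ.csv", "occurrenceID,datasetID\na,rs\na,rs\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_occurrences(src)

    def test_idigbio_raw_dialect_autodetected(self, tmp_path):
        src = _write(
            tmp_path,
            "occ.csv",
            "uuid,recordset,dwc.family,dwc.preparations,idigbio.isoCountryCode\n"
            "u1,rsA,Percidae,EtOH -15,us\n",
        )
        (rec,) = read_occurrences(src)
        assert rec.recordset_id == "rsA"
        assert rec.preparations_verbatim == "EtOH -15"
        assert rec.country_code_indexed == "US"  # upper-cased ISO code

    def test_tsv_autodetected_and_unmapped_columns_preserved(self, tmp_path):
        src = _write(
            tmp_path,
            "occ.tsv",
            "occurrenceID\tdatasetID\tfamily\tmyExtra\n" "a\trs\tPercidae\tsomething\n",
        )
        (rec,) = read_occurrences(src)
        assert rec.extras == {"myExtra": "something"}


def _random_record(rng: random.Random, i: int) -> SpecimenRecord:
    opt = lambda v: v if rng.random() < 0.7 else None  # noqa: E731
    lat = opt(round(rng.uniform(-90, 90), 4))
    lon = opt(round(rng.uniform(-180, 180), 4))
    return SpecimenRecord(
        record_id=f"rec-{i}",
        recordset_id=f"rs-{rng.randrange(3)}",
        institution_code=opt("UF"),
        collection_code=opt("Fish"),
        family_verbatim=opt(rng.choice(["Percidae", "Cottidae", "Söldidae"])),
        scientific_name_verbatim=opt("Perca flavescens"),
        preparations_verbatim=opt("EtOH -15, Skeleton—1"),
        individual_count_verbatim=opt(str(rng.randrange(1, 99))),
        type_status_verbatim=opt("Holotype"),
        country_code_indexed=opt(rng.choice(["US", "MX"])),
        latitude=lat,
        longitude=lon,
        has_geopoint_indexed=compute_geopoint(lat, lon),
        media_record_count=rng.randrange(4),
        is_fossil=rng.random() < 0.1,
        is_living_stock=rng.random() < 0.1,
    )


class TestRoundTrip:
    def test_write_read_round_trip_100_random_records(self, tmp_path):
        rng = random.Random(42)
        records = [_random_record(rng, i) for i in range(100)]
        dest = tmp_path / "out.csv"
        write_occurrences(records, dest)
        assert read_occurrences(dest) == records

    def test_empty_list_gives_header_only_file(self, tmp_path):
        dest = tmp_path / "empty.csv"
        write_occurrences([], dest)
        assert len(dest.read_text().splitlines()) == 1
        assert read_occurrences(dest) == []

    def test_all_absent_fields_round_trip(self, tmp_path):
        rec = make_record("only-ids", "rs9")
        dest = tmp_path / "one.csv"
        write_occurrences([rec], dest)
        assert read_occurrences(dest) == [rec]


@settings(max_examples=50, derandomize=True)
@given(
    lat=st.one_of(st.none(), st.floats(-200, 200, allow_nan=False)),
    lon=st.one_of(st.none(), st.floats(-200, 200, allow_nan=False)),
)
def test_geopoint_is_pure_function_of_coordinates(lat, lon):
    expected = (
        lat is not None and lon is not None and abs(lat) <= 90 and abs(lon) <= 180
    )
    assert compute_geopoint(lat, lon) == expected


class TestCatalog:
    def test_csv_catalog(self, tmp_path):
        src = _write(
            tmp_path,
            "cat.csv",
            "recordset_id,title,description,publisher,record_count\n"
            "rs1,Fish Collection,desc,UF,10\n"
            "rs2,Herps,,ANSP,5\n",
        )
        cats = read_recordset_catalog(src)
        assert len(cats) == 2
        assert cats[1].description == ""

    def test_jsonl_catalog(self, tmp_path):
        src = _write(
            tmp_path,
            "cat.jsonl",
            '{"recordset_id": "a", "title": "T"}\n{"uuid": "b", "title": "U"}\n',
        )
        cats = read_recordset_catalog(src)
        assert [c.recordset_id for c in cats] == ["a", "b"]

    def test_duplicate_recordset_id_is_hard_error(self, tmp_path):
        src = _write(tmp_path, "cat.csv", "recordset_id,title\na,X\na,Y\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_recordset_catalog(src)


class TestDwcArchive:
    def test_directory_archive_with_meta_xml(self, tmp_path):
        arch = tmp_path / "dwca"
        arch.mkdir()
        (arch / "meta.xml").write_text(
            '<archive xmlns="http://rs.tdwg.org/dwc/text/">'
            '<core encoding="UTF-8" fieldsTerminatedBy="\\t" ignoreHeaderLines="1" '
            'rowType="http://rs.tdwg.org/dwc/terms/Occurrence">'
            "<files><location>occurrence.txt</location></files>"
            '<id index="0"/>'
            '<field index="1" term="http://rs.tdwg.org/dwc/terms/family"/>'
            '<field index="2" term="http://rs.tdwg.org/dwc/terms/preparations"/>'
            "</core></archive>",
            encoding="utf-8",
        )
        (arch / "occurrence.txt").write_text(
            "id\tfamily\tpreparations\nocc1\tPercidae\tEtOH -2\n", encoding="utf-8"
        )
        (rec,) = read_occurrences(arch)
        assert rec.record_id == "occ1"
        assert rec.family_verbatim == "Percidae"
        assert rec.recordset_id == "dwca"  # archive name backstops recordset id


def test_media_table_aggregates_to_counts(tmp_path):
    occ = _write(tmp_path, "occ.csv", "occurrenceID,datasetID\na,rs\nb,rs\n")
    media = _write(
        tmp_path, "media.csv", "record_id,media_uri\na,u1\na,u2\nb,u3\nzz,u4\n"
    )
    assert read_media_table(media) == {"a": 2, "b": 1, "zz": 1}
    recs = read_occurrences(occ, media_table=media)
    assert [r.media_record_count for r in recs] == [2, 1]
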