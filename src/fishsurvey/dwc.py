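"""Darwin Core occurrence data model and file I/O.

A :class:`SpecimenRecord` is one cataloged lot with both verbatim
(provider-supplied) and indexed (aggregator-derived) fields; a
:class:`Recordset` is the aggregator's unit of publication. Occurrence data
load from delimited text with Darwin Core term headers (plain DwC or
aggregator raw-export ``dwc.*`` style, auto-detected) or from a Darwin Core
Archive (meta.xml + occurrence core, directory or zip).

The reader never drops rows silently: rows in = records out + rejected rows,
with every rejection logged.
"""

from __future__ import annotations

import csv
import io
import json
import logging
import zipfile
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable

log = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "Recordset",
    "Dialect",
    "CANONICAL",
    "PLAIN_DWC",
    "IDIGBIO_RAW",
    "compute_geopoint",
    "read_occurrences",
    "write_occurrences",
    "read_recordset_catalog",
    "read_media_table",
]


@dataclass
class SpecimenRecord:
    """One occurrence record (a lot: one jar/catalog entry, >= 1 individuals)."""

    record_id: str
    recordset_id: str
    institution_code: str | None = None
    collection_code: str | None = None
    family_verbatim: str | None = None
    scientific_name_verbatim: str | None = None
    preparations_verbatim: str | None = None
    individual_count_verbatim: str | None = None
    type_status_verbatim: str | None = None
    country_code_indexed: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    has_geopoint_indexed: bool = False
    media_record_count: int = 0
    is_fossil: bool = False
    is_living_stock: bool = False
    extras: dict = field(default_factory=dict)


@dataclass
class Recordset:
    """A published aggregation of specimen records."""

    recordset_id: str
    title: str
    description: str = ""
    publisher: str = ""
    record_count: int = 0


def compute_geopoint(latitude: float | None, longitude: float | None) -> bool:
    """A geopoint exists iff both coordinates are present and in range.

    (0, 0) counts: no null-island heuristic is applied.
    """
    return (
        latitude is not None
        and longitude is not None
        and -90.0 <= latitude <= 90.0
        and -180.0 <= longitude <= 180.0
    )


# ---------------------------------------------------------------------------
# Dialects: file column -> model field


@dataclass(frozen=True)
class Dialect:
    name: str
    column_map: dict[str, str]

    def columns_for(self, model_field: str) -> list[str]:
        return [c for c, f in self.column_map.items() if f == model_field]


#: Canonical dialect used by :func:`write_occurrences` (lossless round-trip).
CANONICAL = Dialect(
    "canonical",
    {
        "id": "record_id",
        "recordsetID": "recordset_id",
        "institutionCode": "institution_code",
        "collectionCode": "collection_code",
        "family": "family_verbatim",
        "scientificName": "scientific_name_verbatim",
        "preparations": "preparations_verbatim",
        "individualCount": "individual_count_verbatim",
        "typeStatus": "type_status_verbatim",
        "countryCode": "country_code_indexed",
        "decimalLatitude": "latitude",
        "decimalLongitude": "longitude",
        "hasGeopoint": "has_geopoint_indexed",
        "mediaRecordCount": "media_record_count",
        "isFossil": "is_fossil",
        "isLivingStock": "is_living_stock",
    },
)

#: Plain Darwin Core term headers.
PLAIN_DWC = Dialect(
    "plain_dwc",
    {
        "occurrenceID": "record_id",
        "datasetID": "recordset_id",
        "institutionCode": "institution_code",
        "collectionCode": "collection_code",
        "family": "family_verbatim",
        "scientificName": "scientific_name_verbatim",
        "preparations": "preparations_verbatim",
        "individualCount": "individual_count_verbatim",
        "typeStatus": "type_status_verbatim",
        "countryCode": "country_code_indexed",
        "decimalLatitude": "latitude",
        "decimalLongitude": "longitude",
    },
)

#: Aggregator raw-export style: verbatim terms prefixed ``dwc.``, indexed
#: terms carried under the aggregator's own names.
IDIGBIO_RAW = Dialect(
    "idigbio_raw",
    {
        "uuid": "record_id",
        "recordset": "recordset_id",
        "dwc.institutionCode": "institution_code",
        "dwc.collectionCode": "collection_code",
        "dwc.family": "family_verbatim",
        "dwc.scientificName": "scientific_name_verbatim",
        "dwc.preparations": "preparations_verbatim",
        "dwc.individualCount": "individual_count_verbatim",
        "dwc.typeStatus": "type_status_verbatim",
        "idigbio.isoCountryCode": "country_code_indexed",
        "dwc.decimalLatitude": "latitude",
        "dwc.decimalLongitude": "longitude",
        "idigbio.hasGeopoint": "has_geopoint_indexed",
        "idigbio.mediaRecords": "media_record_count",
    },
)

_DIALECTS = (CANONICAL, PLAIN_DWC, IDIGBIO_RAW)

_MODEL_FIELDS = [f.name for f in dc_fields(SpecimenRecord) if f.name != "extras"]


def detect_dialect(header: list[str]) -> Dialect:
    """Pick the known dialect with the largest header overlap."""
    best, best_hits = None, -1
    for d in _DIALECTS:
        hits = sum(1 for col in header if col in d.column_map)
        if hits > best_hits:
            best, best_hits = d, hits
    assert best is not None
    return best


def _sniff_delimiter(sample_line: str, override: str | None) -> str:
    if override:
        return override
    return "\t" if sample_line.count("\t") >= sample_line.count(",") else ","


def _parse_bool(value: str) -> bool:
    return value.strip().lower() in {"1", "true", "t", "yes", "y"}


def _parse_float(value: str) -> float | None:
    try:
        return float(value)
    except ValueError:
        return None


def _row_to_record(
    raw: dict[str, str], dialect: Dialect, source: str, rownum: int
) -> SpecimenRecord | None:
    vals: dict[str, str] = {}
    extras: dict[str, str] = {}
    for col, value in raw.items():
        if col is None:
            continue
        mf = dialect.column_map.get(col)
        if mf is None:
            if value not in (None, ""):
                extras[col] = value
        elif value is not None and value.strip() != "":
            vals[mf] = value.strip() if mf not in ("preparations_verbatim",) else value.strip()
    rid = vals.get("record_id", "")
    if not rid:
        log.warning("%s row %d: empty record id; row rejected", source, rownum)
        return None
    rec = SpecimenRecord(record_id=rid, recordset_id=vals.get("recordset_id", ""))
    for name in (
        "institution_code",
        "collection_code",
        "family_verbatim",
        "scientific_name_verbatim",
        "preparations_verbatim",
        "individual_count_verbatim",
        "type_status_verbatim",
    ):
        if name in vals:
            setattr(rec, name, vals[name])
    if "country_code_indexed" in vals:
        rec.country_code_indexed = vals["country_code_indexed"].upper()
    for name, limit in (("latitude", 90.0), ("longitude", 180.0)):
        if name in vals:
            parsed = _parse_float(vals[name])
            if parsed is None:
                log.warning(
                    "%s row %d: unparseable %s %r; geopoint left absent",
                    source, rownum, name, vals[name],
                )
            elif abs(parsed) > limit:
                log.warning(
                    "%s row %d: out-of-range %s %r; coordinate treated as absent",
                    source, rownum, name, vals[name],
                )
            else:
                setattr(rec, name, parsed)
    if "has_geopoint_indexed" in vals:
        rec.has_geopoint_indexed = _parse_bool(vals["has_geopoint_indexed"])
    else:
        rec.has_geopoint_indexed = compute_geopoint(rec.latitude, rec.longitude)
    if "media_record_count" in vals:
        try:
            rec.media_record_count = max(0, int(float(vals["media_record_count"])))
        except ValueError:
            log.warning("%s row %d: bad media count %r", source, rownum, vals["media_record_count"])
    if "is_fossil" in vals:
        rec.is_fossil = _parse_bool(vals["is_fossil"])
    if "is_living_stock" in vals:
        rec.is_living_stock = _parse_bool(vals["is_living_stock"])
    rec.extras = extras
    return rec


def _read_delimited(
    handle: io.TextIOBase,
    source: str,
    dialect: Dialect | None,
    delimiter: str | None,
    default_recordset: str | None = None,
) -> list[SpecimenRecord]:
    first = handle.readline()
    if not first:
        return []
    delim = _sniff_delimiter(first, delimiter)
    handle.seek(0)
    reader = csv.DictReader(handle, delimiter=delim)
    header = reader.fieldnames or []
    if dialect is None:
        dialect = detect_dialect(header)
    for required in ("record_id", "recordset_id"):
        cols = dialect.columns_for(required)
        if not any(c in header for c in cols):
            if required == "recordset_id" and default_recordset is not None:
                continue
            raise ValueError(
                f"{source}: missing required id column "
                f"(expected one of {cols!r} for {required})"
            )
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    n_rows = n_rejected = 0
    for rownum, raw in enumerate(reader, 2):
        n_rows += 1
        rec = _row_to_record(raw, dialect, source, rownum)
        if rec is None:
            n_rejected += 1
            continue
        if rec.record_id in seen:
            raise ValueError(f"{source}: duplicate record id {rec.record_id!r}")
        seen.add(rec.record_id)
        if not rec.recordset_id and default_recordset is not None:
            rec.recordset_id = default_recordset
        records.append(rec)
    assert n_rows == len(records) + n_rejected
    if n_rejected:
        log.warning("%s: rejected %d of %d rows", source, n_rejected, n_rows)
    return records


# ---------------------------------------------------------------------------
# Darwin Core Archive support (meta.xml + occurrence core)

_META_NS = "{http://rs.tdwg.org/dwc/text/}"


def _dwca_term_map() -> dict[str, str]:
    # Term URIs end with the plain DwC term name; reuse that mapping.
    m = {}
    for col, mf in PLAIN_DWC.column_map.items():
        m[col] = mf
    return m


def _read_dwca(path: Path, delimiter: str | None) -> list[SpecimenRecord]:
    def load(opener) -> list[SpecimenRecord]:
        meta = ET.fromstring(opener("meta.xml"))
        core = meta.find(f"{_META_NS}core")
        if core is None:
            raise ValueError(f"{path}: meta.xml has no <core> element")
        loc = core.find(f"{_META_NS}files/{_META_NS}location")
        if loc is None or not loc.text:
            raise ValueError(f"{path}: core file location missing in meta.xml")
        sep = core.get("fieldsTerminatedBy", "\\t").replace("\\t", "\t")
        skip = int(core.get("ignoreHeaderLines", "0"))
        term_map = _dwca_term_map()
        columns: dict[int, str] = {}
        idx = core.find(f"{_META_NS}id")
        if idx is not None:
            columns[int(idx.get("index", "0"))] = "occurrenceID"
        for f in core.findall(f"{_META_NS}field"):
            term = (f.get("term") or "").rsplit("/", 1)[-1]
            if f.get("index") is not None and term in term_map:
                columns[int(f.get("index"))] = term
        text = opener(loc.text)
        rows = list(csv.reader(io.StringIO(text), delimiter=sep))[skip:]
        width = (max(columns) + 1) if columns else 0
        header = [columns.get(i, f"col{i}") for i in range(width)]
        buf = io.StringIO()
        w = csv.writer(buf, delimiter="\t", lineterminator="\n")
        w.writerow(header)
        for row in rows:
            w.writerow(row[:width] + [""] * (width - len(row)))
        buf.seek(0)
        return _read_delimited(buf, str(path), PLAIN_DWC, "\t", default_recordset=path.stem)

    if path.is_dir():
        return load(lambda name: (path / name).read_text(encoding="utf-8"))
    with zipfile.ZipFile(path) as zf:
        return load(lambda name: zf.read(name).decode("utf-8"))


# ---------------------------------------------------------------------------
# Public readers/writers


def read_occurrences(
    source: str | Path,
    dialect: Dialect | None = None,
    *,
    delimiter: str | None = None,
    media_table: str | Path | None = None,
) -> list[SpecimenRecord]:
    """Load specimen records from a delimited file or Darwin Core Archive.

    ``dialect`` is auto-detected from the header when not given. When
    ``media_table`` (a record_id,media_uri table) is supplied, linked media
    are aggregated into ``media_record_count``.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"occurrence source not found: {path}")
    if path.is_dir() or path.suffix.lower() == ".zip":
        records = _read_dwca(path, delimiter)
    else:
        with open(path, newline="", encoding="utf-8") as handle:
            records = _read_delimited(handle, str(path), dialect, delimiter)
    if media_table is not None:
        counts = read_media_table(media_table)
        for rec in records:
            if rec.record_id in counts:
                rec.media_record_count = counts[rec.record_id]
    return records


def _format_value(rec: SpecimenRecord, mf: str) -> str:
    v = getattr(rec, mf)
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_occurrences(
    records: Iterable[SpecimenRecord],
    dest: str | Path,
    dialect: Dialect = CANONICAL,
    *,
    delimiter: str = ",",
) -> None:
    """Write records as delimited text; round-trips losslessly with
    :func:`read_occurrences` for all modeled fields (``extras`` excluded)."""
    cols = list(dialect.column_map)
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, delimiter=delimiter, lineterminator="\n")
        writer.writerow(cols)
        for rec in records:
            writer.writerow([_format_value(rec, dialect.column_map[c]) for c in cols])


def read_recordset_catalog(source: str | Path) -> list[Recordset]:
    """Load the recordset catalog from CSV or JSON lines.

    Requires at least ``recordset_id`` and ``title``; description/publisher
    default to empty. Duplicate ids are a hard error.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"recordset catalog not found: {path}")
    entries: list[dict] = []
    if path.suffix.lower() in (".json", ".jsonl", ".ndjson"):
        text = path.read_text(encoding="utf-8").strip()
        if text.startswith("["):
            entries = json.loads(text)
        else:
            entries = [json.loads(line) for line in text.splitlines() if line.strip()]
    else:
        with open(path, newline="", encoding="utf-8") as handle:
            first = handle.readline()
            delim = _sniff_delimiter(first, None)
            handle.seek(0)
            entries = list(csv.DictReader(handle, delimiter=delim))
    out: list[Recordset] = []
    seen: set[str] = set()
    for entry in entries:
        rid = str(entry.get("recordset_id") or entry.get("uuid") or entry.get("id") or "").strip()
        if not rid:
            raise ValueError(f"{path}: catalog entry missing recordset_id: {entry!r}")
        if rid in seen:
            raise ValueError(f"{path}: duplicate recordset_id {rid!r}")
        seen.add(rid)
        rc = entry.get("record_count") or 0
        out.append(
            Recordset(
                recordset_id=rid,
                title=str(entry.get("title") or ""),
                description=str(entry.get("description") or ""),
                publisher=str(entry.get("publisher") or ""),
                record_count=int(rc),
            )
        )
    return out


def write_recordset_catalog(recordsets: Iterable[Recordset], dest: str | Path) -> None:
    with open(dest, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(["recordset_id", "title", "description", "publisher", "record_count"])
        for rs in recordsets:
            writer.writerow(
                [rs.recordset_id, rs.title, rs.description, rs.publisher, rs.record_count]
            )


def read_media_table(source: str | Path) -> dict[str, int]:
    """Aggregate a (record_id, media_uri) table to per-record media counts."""
    counts: dict[str, int] = {}
    with open(source, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            rid = (row.get("record_id") or "").strip()
            if rid:
                counts[rid] = counts.get(rid, 0) + 1
    return counts
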