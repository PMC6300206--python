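"""Per-collection and aggregate survey metrics.

For each collection the survey reports: number of records (lots), number of
individual specimens (sum of resolved counts), primary and secondary type
records, unique verbatim family and scientific-name entries, percent of
records with a geopoint, percent holdings by ISO country code, counts of
records with at least one cleared-and-stained / skeletal / tissue
preparation, and the two media measures — records whose preparations mention
media ("media") versus linked media records published separately
("mediarecords").

Percentages are rounded half-up to one decimal. Country percentages are
computed over records bearing a country code; the code-less share is exposed
via ``n_with_country`` rather than folded into an unknown bucket.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

from ._text import round_half_up
from .normalize import NormalizedRecord, classify_type_status, name_cardinality

log = logging.getLogger(__name__)

__all__ = ["CollectionSummary", "AggregateSummary", "summarize_collection", "summarize_aggregate"]

#: Integer metrics summed in the aggregate, in reporting order.
INT_METRICS = (
    "n_records",
    "n_specimens",
    "n_primary_types",
    "n_secondary_types",
    "n_unique_families",
    "n_unique_species",
    "n_records_cleared_stained",
    "n_records_skeletal",
    "n_records_tissue",
    "n_records_media_in_preps",
    "n_mediarecords",
)

#: Metrics for which top-k tables are produced.
RANKED_METRICS = INT_METRICS


@dataclass
class CollectionSummary:
    identity_id: str
    n_records: int = 0
    n_specimens: int = 0
    n_primary_types: int = 0
    n_secondary_types: int = 0
    n_unique_families: int = 0
    n_unique_species: int = 0
    pct_geopoint: float = 0.0
    n_geopoint: int = 0
    n_with_country: int = 0
    country_counts: dict[str, int] = field(default_factory=dict)
    country_pcts: dict[str, float] = field(default_factory=dict)
    n_records_cleared_stained: int = 0
    n_records_skeletal: int = 0
    n_records_tissue: int = 0
    n_records_media_in_preps: int = 0
    n_mediarecords: int = 0
    n_unresolved_counts: int = 0


@dataclass
class AggregateSummary:
    totals: dict[str, int]
    mean_specimens_per_record: float
    pct_geopoint: float
    country_ranking: list[tuple[str, int, float]]  # (code, records, percent)
    top: dict[str, list[tuple[str, int]]]
    n_collections: int


def summarize_collection(
    identity_id: str, normalized: list[NormalizedRecord]
) -> CollectionSummary:
    """Survey metrics for one collection's validated, normalized records."""
    s = CollectionSummary(identity_id=identity_id)
    if not normalized:
        log.warning("collection %s has no records; summary is all zeros", identity_id)
        return s
    records = [nr.record for nr in normalized]
    s.n_records = len(records)
    for nr in normalized:
        if nr.resolution.resolved_count is not None:
            s.n_specimens += nr.resolution.resolved_count
        else:
            s.n_unresolved_counts += 1
        kind = classify_type_status(nr.record.type_status_verbatim)
        if kind == "primary":
            s.n_primary_types += 1
        elif kind == "secondary":
            s.n_secondary_types += 1
        if nr.record.has_geopoint_indexed:
            s.n_geopoint += 1
        if nr.parse.has_category("cleared_and_stained"):
            s.n_records_cleared_stained += 1
        if nr.parse.has_category("skeleton"):
            s.n_records_skeletal += 1
        if nr.parse.has_category("tissue"):
            s.n_records_tissue += 1
        if nr.parse.media_mentioned:
            s.n_records_media_in_preps += 1
        s.n_mediarecords += nr.record.media_record_count
    s.n_unique_families = name_cardinality(records, "family_verbatim")
    s.n_unique_species = name_cardinality(records, "scientific_name_verbatim")
    s.pct_geopoint = round_half_up(100.0 * s.n_geopoint / s.n_records, 1)
    country = Counter(
        r.country_code_indexed for r in records if r.country_code_indexed
    )
    s.n_with_country = sum(country.values())
    s.country_counts = dict(sorted(country.items()))
    if s.n_with_country:
        s.country_pcts = {
            code: round_half_up(100.0 * n / s.n_with_country, 1)
            for code, n in s.country_counts.items()
        }
    return s


def summarize_aggregate(summaries: list[CollectionSummary], top_k: int = 5) -> AggregateSummary:
    """Aggregate over collections: totals by summation, mean specimens per
    record at one decimal, pooled country ranking, and top-k tables per
    metric (ties broken by identity id)."""
    if not summaries:
        raise ValueError("summarize_aggregate needs at least one collection summary")
    totals = {m: sum(getattr(s, m) for s in summaries) for m in INT_METRICS}
    mean = (
        round_half_up(totals["n_specimens"] / totals["n_records"], 1)
        if totals["n_records"]
        else 0.0
    )
    n_geo = sum(s.n_geopoint for s in summaries)
    pct_geo = round_half_up(100.0 * n_geo / totals["n_records"], 1) if totals["n_records"] else 0.0
    pooled: Counter = Counter()
    for s in summaries:
        pooled.update(s.country_counts)
    n_country = sum(pooled.values())
    ranking = [
        (code, n, round_half_up(100.0 * n / n_country, 1))
        for code, n in sorted(pooled.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    top = {
        m: [
            (s.identity_id, getattr(s, m))
            for s in sorted(summaries, key=lambda s: (-getattr(s, m), s.identity_id))[:top_k]
        ]
        for m in RANKED_METRICS
    }
    return AggregateSummary(
        totals=totals,
        mean_specimens_per_record=mean,
        pct_geopoint=pct_geo,
        country_ranking=ranking,
        top=top,
        n_collections=len(summaries),
    )
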