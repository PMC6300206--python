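"""Family-dictionary validation.

The survey keeps provider taxonomy verbatim, so erroneous records (reptiles,
birds, mammals mixed into institutionally mixed recordsets) cannot be removed
by name cleaning. Instead, a reference dictionary of ``dwc:family`` values is
built from the highest-quality collections — those at or above a percentile
(default 80th) on three criteria simultaneously: quantity of published
records, cardinality of families, and quantity of type records — and the full
dataset is filtered against it.

A record is dropped iff its family exactly matches the packaged non-fish
vertebrate blocklist, or its family is present, not in the dictionary, and
beyond a bounded Damerau-Levenshtein distance (default 2) from every
dictionary entry. Misspelled and outdated fish names therefore survive while
true contaminants are removed; records with no family at all are kept
(conservative) and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from ._text import bounded_min_distance
from .lexicons import nonfish_families
from .normalize import classify_type_status, name_cardinality

log = logging.getLogger(__name__)

__all__ = [
    "FamilyDictionary",
    "ValidationReport",
    "collection_quality_metrics",
    "select_reference_collections",
    "build_dictionary",
    "filter_records",
]


@dataclass
class FamilyDictionary:
    """Reference set of case-folded family strings from high-quality
    collections, used to validate the whole dataset."""

    entries: set[str]
    source_collections: list[str] = field(default_factory=list)
    percentile_threshold: float = 80.0


@dataclass
class ValidationReport:
    kept_count: int = 0
    dropped_count: int = 0
    fuzzy_matched_count: int = 0
    family_absent_count: int = 0
    dropped_examples: list[tuple[str, str]] = field(default_factory=list)  # (record_id, reason)


def collection_quality_metrics(records) -> tuple[int, int, int]:
    """(record count, family cardinality, type-record count) for one
    collection's records."""
    n_records = len(records)
    n_families = name_cardinality(records, "family_verbatim")
    n_types = sum(
        1 for r in records if classify_type_status(r.type_status_verbatim) != "none"
    )
    return n_records, n_families, n_types


def _percentile_threshold(values: list[int], percentile: float) -> int:
    """Nearest-rank style cut: the value at 0-based index floor(p/100 * n) of
    the ascending sort (clamped). Values >= this threshold are 'at or above
    the percentile'; ties at the boundary are included. With all values equal
    everything qualifies; with distinct values and p=80, n=5 exactly the
    maximum qualifies."""
    s = sorted(values)
    idx = min(int(math.floor(percentile / 100.0 * len(s))), len(s) - 1)
    return s[idx]


def select_reference_collections(
    records_by_identity: dict[str, list],
    percentile: float = 80.0,
) -> list[str]:
    """Identities at or above ``percentile`` on all three quality criteria.

    Falls back (with a warning) to identities qualifying on at least two of
    the three criteria if the triple intersection is empty.
    """
    if len(records_by_identity) < 2:
        raise ValueError("reference selection needs at least two collections")
    ids = sorted(records_by_identity)
    metrics = {i: collection_quality_metrics(records_by_identity[i]) for i in ids}
    thresholds = tuple(
        _percentile_threshold([metrics[i][k] for i in ids], percentile) for k in range(3)
    )
    qualifying = {
        i: sum(metrics[i][k] >= thresholds[k] for k in range(3)) for i in ids
    }
    selected = [i for i in ids if qualifying[i] == 3]
    if not selected:
        log.warning(
            "no collection is at the %gth percentile on all three criteria; "
            "falling back to 2-of-3", percentile,
        )
        selected = [i for i in ids if qualifying[i] >= 2]
    if not selected:
        # Distinct leaders per metric can leave even 2-of-3 empty on small
        # surveys; the per-metric leaders always qualify on one.
        log.warning("2-of-3 fallback empty; using per-metric leaders (1-of-3)")
        selected = [i for i in ids if qualifying[i] >= 1]
    return selected


def build_dictionary(
    reference_records,
    source_collections: list[str] | None = None,
    percentile_threshold: float = 80.0,
    blocklist: list[str] | None = None,
) -> FamilyDictionary:
    """Distinct case-folded, trimmed family values from the reference
    collections, minus exact blocklist matches."""
    block = {b.casefold() for b in (blocklist if blocklist is not None else nonfish_families())}
    entries = {
        v.strip().casefold()
        for r in reference_records
        if (v := r.family_verbatim) is not None and v.strip()
    }
    entries -= block
    if not entries:
        raise ValueError("reference records yield an empty family dictionary")
    return FamilyDictionary(
        entries=entries,
        source_collections=source_collections or [],
        percentile_threshold=percentile_threshold,
    )


def filter_records(
    records,
    dictionary: FamilyDictionary,
    max_edit_distance: int = 2,
    blocklist: list[str] | None = None,
    n_example_drops: int = 20,
):
    """Filter erroneous records against the family dictionary.

    Returns ``(kept_records, ValidationReport)``; kept + dropped partition
    the input exactly.
    """
    if max_edit_distance < 0:
        raise ValueError("max_edit_distance must be >= 0")
    records = list(records)
    block = {b.casefold() for b in (blocklist if blocklist is not None else nonfish_families())}
    kept = []
    report = ValidationReport()
    fuzzy_cache: dict[str, bool] = {}
    for rec in records:
        fam = rec.family_verbatim
        if fam is None or not fam.strip():
            kept.append(rec)
            report.kept_count += 1
            report.family_absent_count += 1
            continue
        key = fam.strip().casefold()
        if key in block:
            report.dropped_count += 1
            if len(report.dropped_examples) < n_example_drops:
                report.dropped_examples.append((rec.record_id, f"blocklisted family {fam!r}"))
            continue
        if key in dictionary.entries:
            kept.append(rec)
            report.kept_count += 1
            continue
        near = fuzzy_cache.get(key)
        if near is None:
            near = (
                bounded_min_distance(key, dictionary.entries, max_edit_distance)
                <= max_edit_distance
            )
            fuzzy_cache[key] = near
        if near:
            kept.append(rec)
            report.kept_count += 1
            report.fuzzy_matched_count += 1
        else:
            report.dropped_count += 1
            if len(report.dropped_examples) < n_example_drops:
                report.dropped_examples.append(
                    (rec.record_id, f"family {fam!r} beyond distance {max_edit_distance}")
                )
    assert report.kept_count + report.dropped_count == len(records)
    return kept, report
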