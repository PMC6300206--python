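"""Fish-collection discovery and identity reconciliation.

Taxon-specific collections hide inside heterogeneous recordsets, so two
complementary approaches are used and their union taken:

1. metadata keywords — recordsets whose title/description/publisher contain
   "fish" or "ichthy" (case-insensitive substring; false positives such as
   "catfish survey" are tolerated here and eliminated downstream by the
   fish-collection definition and the family-dictionary filter);
2. indicator taxon — recordsets holding records of a family assumed present
   in every fish collection (default Centrarchidae), aggregated by
   (collection code, institution code, recordset id).

Flagged recordsets are folded into collection identities, reconciled against
a registry of standardized symbolic codes (exact code match first, then
aliases; institution codes alone are never used for discovery), with
declarative merge rules for the cases aggregators publish one collection as
several recordsets (or several collections as one code family).
"""

from __future__ import annotations

import csv
import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

from ._text import bounded_min_distance, round_half_up
from .dwc import Recordset, SpecimenRecord
from .lexicons import fish_families, nonfish_families

log = logging.getLogger(__name__)

__all__ = [
    "CollectionIdentity",
    "RegistryEntry",
    "MOBILIZATION_STATUSES",
    "DEFAULT_KEYWORDS",
    "flag_by_metadata",
    "flag_by_indicator_taxon",
    "reconcile",
    "apply_fish_collection_definition",
    "drop_excluded_records",
    "classify_registry_coverage",
    "read_registry",
    "load_merge_rules",
]

DEFAULT_KEYWORDS = ("fish", "ichthy")

MOBILIZATION_STATUSES = (
    "idigbio",
    "gbif_only",
    "fishnet_or_vertnet_only",
    "grbio_metadata_only",
    "multiple_other",
    "none",
)


@dataclass
class CollectionIdentity:
    identity_id: str
    institution_code: str | None = None
    collection_code: str | None = None
    registry_code: str | None = None
    member_recordset_ids: set[str] = field(default_factory=set)
    discovered_by: set[str] = field(default_factory=set)
    merged_from: list[str] = field(default_factory=list)


@dataclass
class RegistryEntry:
    symbolic_code: str
    institution_name: str = ""
    known_aliases: list[str] = field(default_factory=list)
    country: str = "US"
    mobilization_status: str = "none"


def read_registry(source: str | Path) -> list[RegistryEntry]:
    """Registry CSV: symbolic_code, institution_name, aliases (pipe-separated),
    country, mobilization_status."""
    entries: list[RegistryEntry] = []
    seen: set[str] = set()
    with open(source, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            code = (row.get("symbolic_code") or "").strip()
            if not code:
                raise ValueError(f"{source}: registry row missing symbolic_code: {row!r}")
            if code in seen:
                raise ValueError(f"{source}: duplicate symbolic_code {code!r}")
            seen.add(code)
            status = (row.get("mobilization_status") or "none").strip()
            if status not in MOBILIZATION_STATUSES:
                raise ValueError(f"{source}: unknown mobilization_status {status!r}")
            aliases = [a.strip() for a in (row.get("aliases") or "").split("|") if a.strip()]
            entries.append(
                RegistryEntry(
                    symbolic_code=code,
                    institution_name=(row.get("institution_name") or "").strip(),
                    known_aliases=aliases,
                    country=(row.get("country") or "US").strip().upper(),
                    mobilization_status=status,
                )
            )
    return entries


def load_merge_rules(source: str | Path | None) -> dict:
    """Merge rules JSON: {"merges": [{"identity_id": ..., "recordset_ids":
    [...], "labels": [...]}], "exclude_recordsets": [...]}"""
    if source is None:
        return {"merges": [], "exclude_recordsets": []}
    rules = json.loads(Path(source).read_text(encoding="utf-8"))
    rules.setdefault("merges", [])
    rules.setdefault("exclude_recordsets", [])
    return rules


# ---------------------------------------------------------------------------
# Approach 1: metadata keywords


def flag_by_metadata(
    catalog: list[Recordset],
    keywords: tuple[str, ...] = DEFAULT_KEYWORDS,
    search_fields: tuple[str, ...] = ("title", "description", "publisher"),
) -> set[str]:
    """Recordset ids whose metadata contain any keyword (case-insensitive
    substring over the configured fields)."""
    if not keywords:
        raise ValueError("keywords must be non-empty")
    kws = [k.lower() for k in keywords]
    flagged: set[str] = set()
    for rs in catalog:
        text = " ".join(getattr(rs, f, "") or "" for f in search_fields).lower()
        if any(k in text for k in kws):
            flagged.add(rs.recordset_id)
    return flagged


# ---------------------------------------------------------------------------
# Approach 2: indicator taxon


def flag_by_indicator_taxon(
    records: list[SpecimenRecord], family: str = "Centrarchidae"
) -> list[dict]:
    """Aggregate indicator-family records by (collection_code,
    institution_code, recordset_id); one row per distinct triple with its
    record count."""
    if not family:
        raise ValueError("indicator family must be non-empty")
    fam = family.casefold()
    counts: Counter = Counter()
    for rec in records:
        if rec.family_verbatim and rec.family_verbatim.strip().casefold() == fam:
            counts[(rec.collection_code, rec.institution_code, rec.recordset_id)] += 1
    return [
        {
            "collection_code": k[0],
            "institution_code": k[1],
            "recordset_id": k[2],
            "record_count": n,
        }
        for k, n in sorted(counts.items(), key=lambda kv: (str(kv[0]), kv[1]))
    ]


# ---------------------------------------------------------------------------
# Reconciliation


def _modal_codes(records: list[SpecimenRecord]) -> tuple[str | None, str | None]:
    """Most frequent (institution_code, collection_code) pair, case-folded;
    providers report codes inconsistently so the mode is used."""
    counter: Counter = Counter()
    for r in records:
        inst = r.institution_code.strip().casefold() if r.institution_code else None
        coll = r.collection_code.strip().casefold() if r.collection_code else None
        if inst or coll:
            counter[(inst, coll)] += 1
    if not counter:
        return None, None
    (inst, coll), _ = max(counter.items(), key=lambda kv: (kv[1], str(kv[0])))
    return inst, coll


def _display_codes(records: list[SpecimenRecord]) -> tuple[str | None, str | None]:
    """Most frequent original-case codes (for reporting)."""
    inst = Counter(r.institution_code.strip() for r in records if r.institution_code)
    coll = Counter(r.collection_code.strip() for r in records if r.collection_code)
    return (
        inst.most_common(1)[0][0] if inst else None,
        coll.most_common(1)[0][0] if coll else None,
    )


def _registry_match(
    inst: str | None, coll: str | None, registry: list[RegistryEntry]
) -> str | None:
    by_code = {e.symbolic_code.casefold(): e.symbolic_code for e in registry}
    # Exact symbolic-code match, collection code preferred over institution.
    for code in (coll, inst):
        if code and code.casefold() in by_code:
            return by_code[code.casefold()]
    alias_hits: set[str] = set()
    for e in registry:
        aliases = {a.casefold() for a in e.known_aliases}
        for code in (coll, inst):
            if code and code.casefold() in aliases:
                alias_hits.add(e.symbolic_code)
    if len(alias_hits) > 1:
        raise ValueError(
            f"codes ({inst!r}, {coll!r}) match multiple registry entries via "
            f"aliases: {sorted(alias_hits)}"
        )
    return alias_hits.pop() if alias_hits else None


def reconcile(
    flagged: dict[str, set[str]],
    records: list[SpecimenRecord],
    registry: list[RegistryEntry],
    merge_rules: dict | None = None,
) -> list[CollectionIdentity]:
    """Fold flagged recordsets into collection identities.

    ``flagged`` maps approach name ("metadata_keyword"/"indicator_taxon") to
    the recordset ids it flagged. Each flagged recordset lands in exactly one
    identity: explicit merge rules first, then grouping by the recordset's
    modal (institution, collection) code pair, then one identity per
    code-less recordset. Unmatched identities keep ``registry_code`` absent.
    """
    rules = merge_rules or {"merges": [], "exclude_recordsets": []}
    excluded = set(rules.get("exclude_recordsets", []))
    all_flagged = sorted(set().union(*flagged.values()) - excluded) if flagged else []
    flagged_set = set(all_flagged)
    by_recordset: dict[str, list[SpecimenRecord]] = defaultdict(list)
    for rec in records:
        by_recordset[rec.recordset_id].append(rec)

    assigned: dict[str, CollectionIdentity] = {}
    identities: list[CollectionIdentity] = []

    def approaches_for(rsid: str) -> set[str]:
        return {name for name, ids in flagged.items() if rsid in ids}

    for merge in rules.get("merges", []):
        ident = CollectionIdentity(identity_id=merge["identity_id"])
        labels = merge.get("labels") or []
        for i, rsid in enumerate(merge.get("recordset_ids", [])):
            if rsid not in flagged_set:
                continue
            ident.member_recordset_ids.add(rsid)
            ident.discovered_by |= approaches_for(rsid)
            ident.merged_from.append(labels[i] if i < len(labels) else rsid)
            assigned[rsid] = ident
        if ident.member_recordset_ids:
            member_recs = [r for rsid in ident.member_recordset_ids for r in by_recordset[rsid]]
            ident.institution_code, ident.collection_code = _display_codes(member_recs)
            ident.registry_code = _registry_match(
                ident.institution_code, ident.collection_code, registry
            )
            if ident.registry_code is None:
                # The rule's identity label itself may be a registry code.
                ident.registry_code = _registry_match(ident.identity_id, None, registry)
            identities.append(ident)

    by_codes: dict[tuple, CollectionIdentity] = {}
    for rsid in all_flagged:
        if rsid in assigned:
            continue
        recs = by_recordset.get(rsid, [])
        inst_k, coll_k = _modal_codes(recs)
        if inst_k is None and coll_k is None:
            ident = CollectionIdentity(identity_id=rsid)
            ident.member_recordset_ids.add(rsid)
            ident.discovered_by |= approaches_for(rsid)
            identities.append(ident)
            assigned[rsid] = ident
            continue
        key = (inst_k, coll_k)
        ident = by_codes.get(key)
        if ident is None:
            ident = CollectionIdentity(identity_id="")
            by_codes[key] = ident
            identities.append(ident)
        ident.member_recordset_ids.add(rsid)
        ident.discovered_by |= approaches_for(rsid)
        assigned[rsid] = ident

    for key, ident in by_codes.items():
        member_recs = [r for rsid in ident.member_recordset_ids for r in by_recordset[rsid]]
        ident.institution_code, ident.collection_code = _display_codes(member_recs)
        ident.registry_code = _registry_match(
            ident.institution_code, ident.collection_code, registry
        )
        if ident.registry_code:
            ident.identity_id = ident.registry_code
        else:
            ident.identity_id = "@".join(
                c for c in (ident.institution_code, ident.collection_code) if c
            ) or sorted(ident.member_recordset_ids)[0]
    return identities


# ---------------------------------------------------------------------------
# Fish-collection definition


def _is_fish_family(
    value: str,
    fish_set: set[str],
    block_set: set[str],
    max_edit_distance: int = 2,
) -> bool:
    key = value.strip().casefold()
    if not key or key in block_set:
        return False
    if key in fish_set:
        return True
    return bounded_min_distance(key, fish_set, max_edit_distance) <= max_edit_distance


def apply_fish_collection_definition(
    identities: list[CollectionIdentity],
    records: list[SpecimenRecord],
    fish_lexicon: list[str] | None = None,
    blocklist: list[str] | None = None,
) -> list[CollectionIdentity]:
    """Keep only identities that are real fish collections: non-fossilized,
    non-living-stock preserved specimens with at least one fish-family record.
    Identities of mixed content are kept (the definition applies per record
    downstream); drop reasons are logged."""
    fish_set = {f.casefold() for f in (fish_lexicon if fish_lexicon is not None else fish_families())}
    block_set = {b.casefold() for b in (blocklist if blocklist is not None else nonfish_families())}
    by_recordset: dict[str, list[SpecimenRecord]] = defaultdict(list)
    for rec in records:
        by_recordset[rec.recordset_id].append(rec)
    kept: list[CollectionIdentity] = []
    for ident in identities:
        recs = [r for rsid in sorted(ident.member_recordset_ids) for r in by_recordset[rsid]]
        if not recs:
            log.info("dropping %s: no records", ident.identity_id)
            continue
        if all(r.is_fossil for r in recs):
            log.info("dropping %s: all records are fossils", ident.identity_id)
            continue
        if all(r.is_living_stock for r in recs):
            log.info("dropping %s: living stock, not preserved specimens", ident.identity_id)
            continue
        fish_values = {
            r.family_verbatim.strip().casefold()
            for r in recs
            if r.family_verbatim and not r.is_fossil and not r.is_living_stock
        }
        if not any(_is_fish_family(v, fish_set, block_set) for v in fish_values):
            log.info("dropping %s: contains no fish-family records", ident.identity_id)
            continue
        kept.append(ident)
    return kept


def drop_excluded_records(records: list[SpecimenRecord]) -> list[SpecimenRecord]:
    """Per-record application of the fish-collection definition: fossil and
    living-stock records are excluded from survey tallies."""
    return [r for r in records if not r.is_fossil and not r.is_living_stock]


# ---------------------------------------------------------------------------
# Registry coverage


def classify_registry_coverage(
    registry: list[RegistryEntry], discovered: list[CollectionIdentity]
) -> list[dict]:
    """Mobilization-status breakdown of registry entries NOT matched by any
    discovered identity; percentages over the not-discovered denominator,
    one decimal."""
    matched = {i.registry_code for i in discovered if i.registry_code}
    remaining = [e for e in registry if e.symbolic_code not in matched]
    if not remaining:
        return []
    counts = Counter(e.mobilization_status for e in remaining)
    n = len(remaining)
    return [
        {
            "mobilization_status": status,
            "count": counts[status],
            "percent": round_half_up(100.0 * counts[status] / n, 1),
        }
        for status in MOBILIZATION_STATUSES
        if counts[status]
    ]
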