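"""Survey-to-survey comparison against a historical baseline.

The baseline is a per-collection table in the style of the 1995 printed
survey: registry code, year, and counts of lots, specimens, species, primary
and secondary types (blank = not reported). Collections are joined strictly
on registry code — historical tables use the same standardized symbolic
codes, so no fuzzy institution-name matching is attempted.

Deltas are current − baseline per shared metric; negative deltas are legal
and flagged (1995 holdings were staff estimates and several collections
overestimated). Aggregate percent growth is computed from summed matched
totals, not as a mean of per-collection growth rates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

from ._text import round_half_up
from .discovery import RegistryEntry
from .summarize import CollectionSummary

log = logging.getLogger(__name__)

__all__ = [
    "BaselineEntry",
    "SurveyComparison",
    "RegistryHistoryReport",
    "read_baseline",
    "compare_surveys",
    "reconcile_registry_history",
]

#: baseline column -> CollectionSummary metric
METRIC_MAP = {
    "lots": "n_records",
    "specimens": "n_specimens",
    "species": "n_unique_species",
    "primary_types": "n_primary_types",
    "secondary_types": "n_secondary_types",
}


@dataclass
class BaselineEntry:
    registry_code: str
    baseline_year: int = 1995
    lots: int | None = None
    specimens: int | None = None
    species: int | None = None
    primary_types: int | None = None
    secondary_types: int | None = None

    def metric(self, name: str) -> int | None:
        return getattr(self, name)


@dataclass
class SurveyComparison:
    #: registry_code -> metric -> delta (current - baseline); absent metrics omitted
    deltas: dict[str, dict[str, int]]
    #: registry_code -> metric -> percent growth (1 decimal) or None for zero baselines
    growth: dict[str, dict[str, float | None]]
    #: metric -> summed delta over matched collections
    added_totals: dict[str, int]
    #: metric -> aggregate percent growth from summed matched totals
    pct_growth: dict[str, float | None]
    #: metric -> [(registry_code, delta)] sorted by greatest change
    rankings: dict[str, list[tuple[str, int]]]
    matched: list[str] = field(default_factory=list)
    unmatched_current: list[str] = field(default_factory=list)
    unmatched_baseline: list[str] = field(default_factory=list)
    negative_deltas: list[tuple[str, str, int]] = field(default_factory=list)


def read_baseline(source: str | Path) -> list[BaselineEntry]:
    """Baseline CSV: registry_code, year, lots, specimens, species,
    primary_types, secondary_types (blank cells = metric not reported)."""
    entries: list[BaselineEntry] = []
    seen: set[str] = set()

    def opt_int(v: str | None) -> int | None:
        v = (v or "").strip()
        return int(v) if v else None

    with open(source, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            code = (row.get("registry_code") or "").strip()
            if not code:
                raise ValueError(f"{source}: baseline row missing registry_code")
            if code in seen:
                raise ValueError(f"{source}: duplicate registry_code {code!r}")
            seen.add(code)
            entries.append(
                BaselineEntry(
                    registry_code=code,
                    baseline_year=int((row.get("year") or "1995").strip()),
                    lots=opt_int(row.get("lots")),
                    specimens=opt_int(row.get("specimens")),
                    species=opt_int(row.get("species")),
                    primary_types=opt_int(row.get("primary_types")),
                    secondary_types=opt_int(row.get("secondary_types")),
                )
            )
    return entries


def compare_surveys(
    summaries: list[CollectionSummary], baseline: list[BaselineEntry]
) -> SurveyComparison:
    """Join current summaries to the baseline on registry code and compute
    per-collection deltas, aggregate added totals and percent growth."""
    current = {s.identity_id: s for s in summaries}
    base = {b.registry_code: b for b in baseline}
    matched = sorted(current.keys() & base.keys())
    unmatched_current = sorted(current.keys() - base.keys())
    unmatched_baseline = sorted(base.keys() - current.keys())

    deltas: dict[str, dict[str, int]] = {}
    growth: dict[str, dict[str, float | None]] = {}
    negative: list[tuple[str, str, int]] = []
    added: dict[str, int] = {m: 0 for m in METRIC_MAP}
    base_totals: dict[str, int] = {m: 0 for m in METRIC_MAP}
    have_metric: dict[str, bool] = {m: False for m in METRIC_MAP}

    for code in matched:
        s, b = current[code], base[code]
        deltas[code] = {}
        growth[code] = {}
        for bm, sm in METRIC_MAP.items():
            bval = b.metric(bm)
            if bval is None:
                continue
            have_metric[bm] = True
            delta = getattr(s, sm) - bval
            deltas[code][bm] = delta
            if delta < 0:
                negative.append((code, bm, delta))
            added[bm] += delta
            base_totals[bm] += bval
            if bval > 0:
                growth[code][bm] = round_half_up(100.0 * delta / bval, 1)
            else:
                growth[code][bm] = None
                log.warning(
                    "baseline %s for %s is zero; per-collection growth undefined", bm, code
                )

    pct_growth = {
        m: (
            round_half_up(100.0 * added[m] / base_totals[m], 1)
            if base_totals[m] > 0
            else None
        )
        for m in METRIC_MAP
        if have_metric[m]
    }
    added_totals = {m: added[m] for m in METRIC_MAP if have_metric[m]}
    rankings = {
        m: sorted(
            ((code, deltas[code][m]) for code in matched if m in deltas[code]),
            key=lambda kv: (-kv[1], kv[0]),
        )
        for m in METRIC_MAP
        if have_metric[m]
    }
    return SurveyComparison(
        deltas=deltas,
        growth=growth,
        added_totals=added_totals,
        pct_growth=pct_growth,
        rankings=rankings,
        matched=matched,
        unmatched_current=unmatched_current,
        unmatched_baseline=unmatched_baseline,
        negative_deltas=negative,
    )


@dataclass
class RegistryHistoryReport:
    n_surveyed: int
    n_non_domestic: int
    n_transferred: int
    n_extant: int


def reconcile_registry_history(
    surveyed: list[RegistryEntry],
    transfers: list[tuple[str, str]],
    home_country: str = "US",
) -> RegistryHistoryReport:
    """Count extant domestic collections from a historical survey list.

    ``transfers`` are (from_code, to_code) pairs for collections whose
    specimens moved to another institution; both codes must be known.
    extant = surveyed − non-domestic − transferred.
    """
    codes = {e.symbolic_code for e in surveyed}
    n_non_domestic = sum(1 for e in surveyed if e.country.upper() != home_country.upper())
    transferred: set[str] = set()
    for from_code, to_code in transfers:
        if from_code not in codes:
            raise ValueError(f"transfer references unknown source code {from_code!r}")
        if to_code not in codes:
            raise ValueError(f"transfer references unknown destination code {to_code!r}")
        transferred.add(from_code)
    n = len(surveyed)
    n_transferred = len(transferred)
    return RegistryHistoryReport(
        n_surveyed=n,
        n_non_domestic=n_non_domestic,
        n_transferred=n_transferred,
        n_extant=n - n_non_domestic - n_transferred,
    )
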