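"""Normalization of verbatim specimen fields.

Providers fill ``dwc:preparations`` with free text such as ``"EtOH -15,
Skeleton—1"``: a comma/semicolon-separated list of preparation tokens, each
optionally carrying a count of individuals separated by a hyphen, en/em dash,
colon or space. :func:`parse_preparations` lumps tokens into canonical
categories via the synonym grammar and extracts those embedded counts (the
example above parses to ethanol: 15 + skeleton: 1 = 16 individuals).

:func:`resolve_count` then synthesizes one individual count per lot with a
strict precedence: a usable ``dwc:individualCount`` always wins, then counts
parsed from preparations, then a configurable default of one individual for
any record that shows lot evidence (a preparation or a family). Placeholder
counts providers use for uncounted lots (0, 9999, 99999 by default) are
treated as absent.

Verbatim taxonomy is deliberately NOT cleaned: :func:`name_cardinality`
counts distinct values after surrounding-whitespace trim only, case-sensitive,
so misspelled or outdated names each count as what providers published.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

from .dwc import SpecimenRecord
from .lexicons import load_grammar

__all__ = [
    "PreparationParse",
    "CountPolicy",
    "CountSource",
    "CountResolution",
    "parse_preparations",
    "resolve_count",
    "classify_type_status",
    "name_cardinality",
    "NormalizedRecord",
    "normalize_records",
    "PRIMARY_TYPE_TERMS",
    "SECONDARY_TYPE_TERMS",
]

#: Sentinel meaning "category mentioned, but with no numeric count".
PRESENT = None


@dataclass
class PreparationParse:
    """Normalized view of one verbatim preparations string.

    ``category_counts`` maps canonical categories to an integer count or
    ``None`` for present-without-count. ``total_individuals`` is the sum of
    the numeric counts, or ``None`` when no token carried a number.
    """

    category_counts: dict[str, int | None] = field(default_factory=dict)
    media_mentioned: bool = False
    unrecognized_tokens: list[str] = field(default_factory=list)

    @property
    def total_individuals(self) -> int | None:
        nums = [v for v in self.category_counts.values() if v is not None]
        return sum(nums) if nums else None

    def has_category(self, category: str) -> bool:
        return category in self.category_counts


_TOKEN_SPLIT = re.compile(r"[,;]")
# Trailing integer separated by hyphen/en dash/em dash/colon/space. Hyphens
# adjacent to digits are separators, never minus signs: counts are >= 0.
_TRAILING_COUNT = re.compile(r"^(?P<label>.*?)(?:\s*[-–—:]\s*|\s+)(?P<num>\d+)\s*$")
_BARE_COUNT = re.compile(r"^\s*(?P<num>\d+)\s*$")
_WS = re.compile(r"\s+")

_DEFAULT_GRAMMAR: dict[str, str] | None = None


def _default_grammar() -> dict[str, str]:
    global _DEFAULT_GRAMMAR
    if _DEFAULT_GRAMMAR is None:
        _DEFAULT_GRAMMAR = load_grammar()
    return _DEFAULT_GRAMMAR


def _normalize_label(label: str) -> str:
    t = label.strip().strip(".,:;-–—()[]").strip()
    return _WS.sub(" ", t).lower()


def _match_category(label_norm: str, grammar: dict[str, str], by_length: list[str]) -> str | None:
    if label_norm in grammar:
        return grammar[label_norm]
    # Fall back to containment for compound labels ("dry skeleton prep");
    # only synonyms of length >= 4 participate, to keep "cs"/"alc" exact-only.
    for syn in by_length:
        if len(syn) >= 4 and syn in label_norm:
            return grammar[syn]
    return None


def parse_preparations(
    prep_string: str | None, grammar: dict[str, str] | None = None
) -> PreparationParse:
    """Parse one verbatim preparations string. Total function: never raises."""
    parse = PreparationParse()
    if prep_string is None or not prep_string.strip():
        return parse
    if grammar is None:
        grammar = _default_grammar()
    by_length = sorted(grammar, key=len, reverse=True)
    for raw_token in _TOKEN_SPLIT.split(prep_string):
        token = raw_token.strip()
        if not token:
            continue
        count: int | None = None
        label = token
        if m := _BARE_COUNT.match(token):
            label, count = "", int(m.group("num"))
        elif m := _TRAILING_COUNT.match(token):
            label, count = m.group("label"), int(m.group("num"))
        label_norm = _normalize_label(label)
        category = _match_category(label_norm, grammar, by_length) if label_norm else None
        if category is None:
            category = "other"
            parse.unrecognized_tokens.append(token)
        if category == "media":
            parse.media_mentioned = True
        prev = parse.category_counts.get(category, PRESENT)
        if count is not None:
            parse.category_counts[category] = (prev or 0) + count
        elif category not in parse.category_counts:
            parse.category_counts[category] = PRESENT
    return parse


# ---------------------------------------------------------------------------
# Individual-count synthesis


class CountSource(str, Enum):
    individual_count_field = "individual_count_field"
    parsed_from_preparations = "parsed_from_preparations"
    default_one = "default_one"
    unresolved = "unresolved"


@dataclass(frozen=True)
class CountPolicy:
    """How missing/placeholder counts are handled.

    ``placeholders`` are provider values meaning "uncounted lot" and are
    treated as absent. With ``default_one`` every record showing lot evidence
    (any preparation or family) resolves to one individual; switched off,
    such records stay unresolved and add nothing to specimen totals.
    """

    placeholders: frozenset[int] = frozenset({0, 9999, 99999})
    default_one: bool = True


@dataclass
class CountResolution:
    resolved_count: int | None
    source: CountSource


_INT_RE = re.compile(r"^\+?\d+(?:\.0+)?$")


def _parse_count_field(value: str | None, placeholders: frozenset[int]) -> int | None:
    if value is None:
        return None
    v = value.strip()
    if not _INT_RE.match(v):
        return None
    n = int(float(v))
    if n <= 0 or n in placeholders:
        return None
    return n


def resolve_count(
    record: SpecimenRecord,
    parse: PreparationParse,
    policy: CountPolicy = CountPolicy(),
) -> CountResolution:
    """Resolve the number of individuals in a lot (strict precedence)."""
    n = _parse_count_field(record.individual_count_verbatim, policy.placeholders)
    if n is not None:
        return CountResolution(n, CountSource.individual_count_field)
    total = parse.total_individuals
    if total is not None and total > 0:
        return CountResolution(total, CountSource.parsed_from_preparations)
    has_evidence = bool(record.preparations_verbatim) or bool(record.family_verbatim)
    if policy.default_one and has_evidence:
        return CountResolution(1, CountSource.default_one)
    return CountResolution(None, CountSource.unresolved)


# ---------------------------------------------------------------------------
# Type status

#: Name-bearing types.
PRIMARY_TYPE_TERMS = ("holotype", "lectotype", "neotype", "syntype")
#: Non-name-bearing types.
SECONDARY_TYPE_TERMS = ("paralectotype", "paratype", "allotype", "topotype", "cotype")


def classify_type_status(
    type_status_verbatim: str | None,
    primary_terms: tuple[str, ...] = PRIMARY_TYPE_TERMS,
    secondary_terms: tuple[str, ...] = SECONDARY_TYPE_TERMS,
) -> str:
    """Classify a verbatim type-status string as primary/secondary/none.

    Substring scan, longest vocabulary term first, so "paralectotype" is
    secondary rather than matching its embedded "lectotype".
    """
    if not type_status_verbatim:
        return "none"
    s = type_status_verbatim.lower()
    ranked = sorted(
        [(t, "primary") for t in primary_terms] + [(t, "secondary") for t in secondary_terms],
        key=lambda kv: len(kv[0]),
        reverse=True,
    )
    for term, kind in ranked:
        if term in s:
            return kind
    return "none"


# ---------------------------------------------------------------------------
# Verbatim name cardinality


def name_cardinality(records, field_name: str) -> int:
    """Distinct verbatim values of ``field_name`` after trim only.

    Case-sensitive by design: verbatim taxonomy is reported as published,
    with no cleaning, so "Lepomis" and "lepomis" are two entries.
    """
    if field_name not in ("family_verbatim", "scientific_name_verbatim"):
        raise ValueError(f"unsupported cardinality field {field_name!r}")
    values = {
        v.strip()
        for rec in records
        if (v := getattr(rec, field_name)) is not None and v.strip()
    }
    return len(values)


# ---------------------------------------------------------------------------
# Batch normalization (what the pipeline's normalize stage runs)


@dataclass
class NormalizedRecord:
    record: SpecimenRecord
    parse: PreparationParse
    resolution: CountResolution


def normalize_records(
    records,
    grammar: dict[str, str] | None = None,
    policy: CountPolicy = CountPolicy(),
) -> list[NormalizedRecord]:
    if grammar is None:
        grammar = _default_grammar()
    out = []
    for rec in records:
        parse = parse_preparations(rec.preparations_verbatim, grammar)
        out.append(NormalizedRecord(rec, parse, resolve_count(rec, parse, policy)))
    return out
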