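"""Packaged lexicons: valid fish family names and the non-fish vertebrate
family blocklist, plus the preparation-category synonym grammar.

All three ship as plain-text resources and can be overridden by path, so new
provider dialects or taxon scopes never require code changes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

__all__ = [
    "load_name_list",
    "fish_families",
    "nonfish_families",
    "load_grammar",
    "CATEGORIES",
]

#: Canonical preparation categories the parser lumps synonyms into.
CATEGORIES = (
    "ethanol",
    "skeleton",
    "cleared_and_stained",
    "tissue",
    "formalin",
    "dried",
    "media",
    "other",
)


def _resource_text(name: str) -> str:
    return (resources.files("fishsurvey") / "data" / name).read_text(encoding="utf-8")


def load_name_list(path: str | Path | None = None, *, resource: str | None = None) -> list[str]:
    """Read a one-name-per-line lexicon, skipping blanks and ``#`` comments."""
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    elif resource is not None:
        text = _resource_text(resource)
    else:
        raise ValueError("either path or resource is required")
    names = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            names.append(line)
    return names


def fish_families(path: str | Path | None = None) -> list[str]:
    """Valid fish family names (includes Centrarchidae, the indicator taxon)."""
    return load_name_list(path, resource="fish_families.txt")


def nonfish_families(path: str | Path | None = None) -> list[str]:
    """Tetrapod contaminant families removed by the validation filter."""
    return load_name_list(path, resource="nonfish_families.txt")


def load_grammar(path: str | Path | None = None) -> dict[str, str]:
    """Load the preparation grammar as a synonym -> category map.

    The table is TAB-separated ``category<TAB>synonym``; synonyms are stored
    lower-cased. Unknown categories raise so a typo in a user grammar fails
    loudly rather than silently routing tokens to ``other``.
    """
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = _resource_text("prep_grammar.tsv")
    grammar: dict[str, str] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            category, synonym = line.split("\t")
        except ValueError as exc:
            raise ValueError(f"grammar line {lineno}: expected 'category<TAB>synonym'") from exc
        category = category.strip()
        if category not in CATEGORIES:
            raise ValueError(f"grammar line {lineno}: unknown category {category!r}")
        grammar[synonym.strip().lower()] = category
    return grammar
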