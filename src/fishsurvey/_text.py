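"""Small text utilities shared across the pipeline.

Edit distance is the optimal-string-alignment (restricted Damerau-Levenshtein)
variant: substitutions, insertions, deletions and adjacent transpositions each
cost 1, and a substring is never edited twice. That is the distance the
misspelling tolerance of the family filter is defined in.
"""

from __future__ import annotations

import re
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["damerau_levenshtein", "round_half_up", "normalize_token"]


def damerau_levenshtein(a: str, b: str) -> int:
    """Optimal-string-alignment distance between ``a`` and ``b``."""
    if a == b:
        return 0
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        for j in range(1, lb + 1):
            cost = 0 if a[i - 1] == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
                cur[j] = min(cur[j], prev2[j - 2] + 1)
        prev2, prev = prev, cur
    return prev[lb]


def bounded_min_distance(query: str, candidates, bound: int) -> int:
    """Minimum OSA distance from ``query`` to any candidate, short-circuiting
    once a candidate at or under ``bound`` is found. Length pre-filtering keeps
    this cheap on large lexicons."""
    best = bound + 1
    lq = len(query)
    for cand in candidates:
        if abs(len(cand) - lq) > bound:
            continue
        d = damerau_levenshtein(query, cand)
        if d < best:
            best = d
            if best <= bound:
                break
    return best


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting style:
    66.15 -> 66.2), avoiding banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


_WS = re.compile(r"\s+")


def normalize_token(token: str) -> str:
    """Case-fold, trim surrounding punctuation and collapse whitespace."""
    t = token.strip().strip(".,:;-–—()[]").strip()
    return _WS.sub(" ", t).lower()
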