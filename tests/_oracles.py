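"""Independent reference implementations used only to cross-check the
package: textbook recursive edit distance, count-based percentile
qualification, and brute-force group-bys. Deliberately naive."""

from functools import lru_cache
import math


def osa_reference(a: str, b: str) -> int:
    """Optimal-string-alignment distance by memoized textbook recursion."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        cost = 0 if a[i - 1] == b[j - 1] else 1
        best = min(d(i - 1, j) + 1, d(i, j - 1) + 1, d(i - 1, j - 1) + cost)
        if i > 1 and j > 1 and a[i - 1] == b[j - 2] and a[i - 2] == b[j - 1]:
            best = min(best, d(i - 2, j - 2) + 1)
        return best

    return d(len(a), len(b))


def percentile_qualifiers(values: list[int], percentile: float) -> list[bool]:
    """Qualification by counting, no sorting: value v is at-or-above the
    percentile iff fewer than n - floor(p/100*n) values are strictly
    greater."""
    n = len(values)
    allowed_above = n - 1 - min(int(math.floor(percentile / 100.0 * n)), n - 1)
    return [sum(1 for u in values if u > v) <= allowed_above for v in values]


def group_counts(items: list[str]) -> dict[str, int]:
    out: dict[str, int] = {}
    for item in items:
        out[item] = out.get(item, 0) + 1
    return out
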