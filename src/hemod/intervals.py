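"""Half-open-free interval algebra on closed [start, end] pairs.

All functions are generic over any totally ordered endpoint type with
subtraction (datetimes with timedeltas, or plain numbers in tests).
Touching intervals (end == next start) count as overlapping everywhere:
zero-gap fragmentation of episodes is never meaningful clinically.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TypeVar

T = TypeVar("T")
Interval = tuple[T, T]


def merge_touching(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals; overlapping or touching intervals coalesce."""
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def merge_with_gap(intervals: Iterable[Interval], gap) -> list[Interval]:
    """Merge consecutive intervals whose separation is strictly below ``gap``.

    Applied transitively; the result is disjoint with all gaps >= ``gap``.
    With a zero gap this reduces to :func:`merge_touching`.
    """
    ivs = sorted(intervals)
    out: list[Interval] = []
    for s, e in ivs:
        if out and s - out[-1][1] < gap:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def subtract(intervals: Sequence[Interval], holes: Sequence[Interval]) -> list[Interval]:
    """Set difference ``intervals - holes``; empty remainders are dropped.

    Partial overlaps truncate the interval rather than deleting it.
    """
    holes = merge_touching(holes)
    out: list[Interval] = []
    for s, e in merge_touching(intervals):
        cur = s
        for hs, he in holes:
            if he <= cur or hs >= e:
                continue
            if hs > cur:
                out.append((cur, hs))
            cur = max(cur, he)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> list[Interval]:
    """Pairwise intersection of two disjoint-ified interval sets."""
    a = merge_touching(a)
    b = merge_touching(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_duration(intervals: Iterable[Interval]):
    """Sum of lengths of the merged union (double counting excluded)."""
    merged = merge_touching(intervals)
    if not merged:
        return 0
    total = None
    for s, e in merged:
        d = e - s
        total = d if total is None else total + d
    return total


__all__ = ["merge_touching", "merge_with_gap", "subtract", "intersect", "total_duration"]
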