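"""Half-open interval arithmetic shared across the pipeline.

All coordinates in this package are 0-based, half-open ``[start, end)``.
Functions here operate on plain ``(start, end)`` tuples on a single
sequence; chromosome-aware callers group by chromosome first.
"""

from __future__ import annotations

from typing import Iterable, Sequence


def merge(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching intervals into maximal disjoint ones."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s > e:
            raise ValueError(f"invalid interval ({s}, {e})")
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length(intervals: Iterable[tuple[int, int]]) -> int:
    """Total number of bases covered by the union of the intervals."""
    return sum(e - s for s, e in merge(intervals))


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def subtract(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Set-difference a \\ b as maximal disjoint intervals."""
    a_m = merge(a)
    b_m = merge(b)
    out: list[tuple[int, int]] = []
    for s, e in a_m:
        cur = s
        for bs, be in b_m:
            if be <= cur or bs >= e:
                continue
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
        if cur < e:
            out.append((cur, e))
    return out


def gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Genomic gap between two intervals; <= 0 when they overlap or touch."""
    lo, hi = (a, b) if a[0] <= b[0] else (b, a)
    return hi[0] - lo[1]
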