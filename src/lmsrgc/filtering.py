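"""Filtering of longest matched substrings into a disjoint target cover.

Two stages:

1. ``remove_contained`` — walk records by ascending target position and drop
   any whose target interval ends at or before the furthest end seen among
   retained records (it is contained in an earlier, longer match), plus any
   shorter than ``kmerlength``. Overlapping-but-not-contained records stay.

2. ``resolve_overlaps`` — repeatedly record the longest remaining match and
   truncate every overlapping candidate to its uncovered part (left cuts
   advance both the target and reference starts; a mid-split keeps the
   single longest uncovered contiguous piece); truncated candidates shorter
   than ``kmerlength`` are discarded. The loop is implemented with a lazy
   max-heap, which produces the same output as literally re-sorting the
   survivors by length each round.

The final records are sorted by target start, pairwise disjoint, each at
least ``kmerlength`` long, and truncation preserves the substring identity
(target and reference starts shift together).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

from .search import LmsRecord

__all__ = [
    "FilterParams",
    "remove_contained",
    "truncate_once",
    "resolve_overlaps",
    "filter_lms",
]


@dataclass(frozen=True)
class FilterParams:
    """``kmerlength``: minimum match length kept by either stage (>= 1)."""

    kmerlength: int = 21

    def __post_init__(self) -> None:
        if self.kmerlength < 1:
            raise ValueError("kmerlength must be >= 1")


def remove_contained(
    records: list[LmsRecord], params: FilterParams
) -> list[LmsRecord]:
    """Drop contained and sub-``kmerlength`` records in one ascending pass."""
    kept: list[LmsRecord] = []
    max_end = -1
    for rec in sorted(records, key=lambda r: r.tar):
        if rec.lms_len < params.kmerlength:
            continue
        end = rec.tar + rec.lms_len
        if end <= max_end:
            continue
        kept.append(rec)
        max_end = end
    return kept


def truncate_once(
    tar: int, length: int, cover_start: int, cover_end: int
) -> tuple[int, int]:
    """Uncovered part of [tar, tar+length) after removing one covered interval.

    If the cover splits the interval, the longest remaining piece survives
    (leftmost on a tie). Returns (new_tar, new_length); length 0 when fully
    covered.
    """
    end = tar + length
    if cover_end <= tar or cover_start >= end:
        return tar, length
    left = (tar, max(0, cover_start - tar))
    right = (max(cover_end, tar), max(0, end - cover_end))
    return left if left[1] >= right[1] else right


def resolve_overlaps(
    records: list[LmsRecord], params: FilterParams
) -> list[LmsRecord]:
    """Greedy longest-first selection with truncation of overlaps.

    Ties on length break toward the smaller target start, then the smaller
    reference start (distinct candidates can truncate down to the same
    target interval). Each heap entry
    remembers how many recorded matches it has been truncated against; on
    pop, the missing truncations are replayed one recording at a time, which
    makes the lazy heap bit-identical to literally re-sorting the surviving
    candidates after every recording. Idempotent: a disjoint input is
    returned unchanged (sorted by target start).
    """
    k = params.kmerlength
    # (-len, tar, ref, len, version): version = recordings already applied
    heap: list[tuple[int, int, int, int, int]] = []
    for rec in records:
        if rec.lms_len >= k:
            heapq.heappush(heap, (-rec.lms_len, rec.tar, rec.ref, rec.lms_len, 0))

    recorded: list[tuple[int, int]] = []  # (start, end) in recording order
    final: list[LmsRecord] = []
    while heap:
        neg_len, tar, ref, length, version = heapq.heappop(heap)
        dropped = False
        while version < len(recorded):
            cs, ce = recorded[version]
            new_tar, new_len = truncate_once(tar, length, cs, ce)
            ref += new_tar - tar
            tar, length = new_tar, new_len
            version += 1
            if length < k:
                dropped = True
                break
        if dropped:
            continue
        if length < -neg_len:
            # replay shortened it: its rank changed, so re-enter the queue
            heapq.heappush(heap, (-length, tar, ref, length, version))
            continue
        final.append(LmsRecord(tar, ref, length))
        recorded.append((tar, tar + length))
    final.sort(key=lambda r: r.tar)
    return final


def filter_lms(records: list[LmsRecord], params: FilterParams) -> list[LmsRecord]:
    """Both stages composed: the final disjoint match set, sorted by target."""
    return resolve_overlaps(remove_contained(records, params), params)
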