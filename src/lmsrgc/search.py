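"""Longest-matched-substring search over the LCP array.

For every target position the goal is the longest substring starting there
that occurs anywhere in the extended reference. In suffix-array terms: for a
rank ``i`` whose suffix starts in the target, let ``rp1 < i < rp2`` be the
nearest ranks whose suffixes start in the reference. Then

    plcp_len = min(LCP[rp1+1 .. i])
    nlcp_len = min(LCP[i+1 .. rp2])
    lms_len  = max(plcp_len, nlcp_len)

and the match starts in the concatenation at ``SA[rp]`` of the winning
neighbor. The per-position reference start is stored as
``SA[rp] - tarlength``, which is 1-based inside the extended reference
because the '$' separator occupies offset ``tarlength`` of the
concatenation.

``scan_lms`` realises this with two O(n) sweeps (running minimum since the
last reference-origin rank); ``scan_lms_by_definition`` is the literal
rank-by-rank form kept as an internal cross-check, and segmented scanning
reproduces the serial result for any part count.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .index import ConcatIndex, SegmentPlan

__all__ = [
    "Origin",
    "LmsRecord",
    "NeighborScan",
    "classify_origin",
    "neighbor_scan",
    "scan_lms",
    "scan_lms_by_definition",
    "plan_scan_segments",
    "scan_lms_segmented",
    "brute_force_lms_oracle",
]

_INF = 1 << 60


class Origin(Enum):
    TARGET = "target"
    SEPARATOR = "separator"
    REFERENCE = "reference"


@dataclass(frozen=True)
class LmsRecord:
    """Longest match for one target position.

    ``ref`` is 1-based within the extended reference (``SA[rp] - tarlength``
    convention); a record with ``lms_len == 0`` means no match and carries
    ``ref == 0``.
    """

    tar: int
    ref: int
    lms_len: int


@dataclass(frozen=True)
class NeighborScan:
    """Intermediate quantities of the neighbor-minimum rule at one rank."""

    rp1: int | None
    rp2: int | None
    plcp_len: int
    nlcp_len: int
    lcs_len: int


def classify_origin(sa_value: int, tarlength: int) -> Origin:
    """Which part of the concatenation a suffix starts in."""
    if sa_value < tarlength:
        return Origin.TARGET
    if sa_value == tarlength:
        return Origin.SEPARATOR
    return Origin.REFERENCE


def neighbor_scan(
    index: ConcatIndex, rank: int, lo: int = 0, hi: int | None = None
) -> NeighborScan:
    """Literal neighbor-minimum evaluation at one rank (diagnostic form).

    ``lo``/``hi`` bound the neighbor search to ranks [lo, hi]; segmented
    scanning uses them with boundary ranks known to be reference-origin.
    """
    SA, LCP, tl, n = index.SA, index.LCP, index.tarlength, index.n
    if hi is None:
        hi = n - 1
    if classify_origin(int(SA[rank]), tl) is not Origin.TARGET:
        raise ValueError(f"rank {rank} is not a target-origin suffix")
    rp1 = None
    plcp = 0
    m = _INF
    for p in range(rank, lo, -1):
        m = min(m, int(LCP[p]))
        if classify_origin(int(SA[p - 1]), tl) is Origin.REFERENCE:
            rp1, plcp = p - 1, m
            break
    rp2 = None
    nlcp = 0
    m = _INF
    for q in range(rank + 1, hi + 1):
        m = min(m, int(LCP[q]))
        if classify_origin(int(SA[q]), tl) is Origin.REFERENCE:
            rp2, nlcp = q, m
            break
    return NeighborScan(rp1, rp2, plcp, nlcp, max(plcp, nlcp))


def scan_lms(index: ConcatIndex) -> list[LmsRecord]:
    """Per-target-position longest matches via two linear sweeps.

    Returns a list indexed by target position. Equal-length ties between the
    two neighbors resolve to the rp2 (lexicographically following) side.
    """
    SA = index.SA.tolist()
    LCP = index.LCP.tolist()
    tl, n = index.tarlength, index.n

    plcp = [0] * tl
    pref = [0] * tl  # SA[rp1] for each target position (0 if none)
    run_min = _INF
    last_ref = -1
    for i in range(n):
        if i > 0 and last_ref >= 0:
            run_min = min(run_min, LCP[i])
        v = SA[i]
        if v > tl:
            last_ref, run_min = v, _INF
        elif v < tl and last_ref >= 0:
            plcp[v] = run_min if run_min != _INF else 0
            pref[v] = last_ref

    nlcp = [0] * tl
    nref = [0] * tl
    run_min = _INF
    last_ref = -1
    for i in range(n - 1, -1, -1):
        if i < n - 1 and last_ref >= 0:
            run_min = min(run_min, LCP[i + 1])
        v = SA[i]
        if v > tl:
            last_ref, run_min = v, _INF
        elif v < tl and last_ref >= 0:
            nlcp[v] = run_min if run_min != _INF else 0
            nref[v] = last_ref

    records: list[LmsRecord] = []
    for pos in range(tl):
        if nlcp[pos] >= plcp[pos]:  # tie goes to the rp2 side
            length, src = nlcp[pos], nref[pos]
        else:
            length, src = plcp[pos], pref[pos]
        if length > 0:
            records.append(LmsRecord(pos, src - tl, length))
        else:
            records.append(LmsRecord(pos, 0, 0))
    return records


def scan_lms_by_definition(index: ConcatIndex) -> list[LmsRecord]:
    """Rank-by-rank evaluation of the neighbor rule (quadratic; cross-check)."""
    tl = index.tarlength
    records: list[LmsRecord] = [LmsRecord(p, 0, 0) for p in range(tl)]
    for rank in range(index.n):
        pos = int(index.SA[rank])
        if pos >= tl:
            continue
        ns = neighbor_scan(index, rank)
        if ns.lcs_len <= 0:
            continue
        rp = ns.rp2 if ns.nlcp_len >= ns.plcp_len else ns.rp1
        records[pos] = LmsRecord(pos, int(index.SA[rp]) - tl, ns.lcs_len)
    return records


def plan_scan_segments(index: ConcatIndex, parts: int) -> SegmentPlan:
    """Rank intervals for parallel scanning, boundaries on reference suffixes.

    Internal cut points are moved (start backward, end forward) until the
    boundary suffixes are reference-origin, so each segment sees the true
    nearest neighbors of its interior target ranks; segments whose span
    collapses merge into their neighbor.
    """
    if parts < 1:
        raise ValueError("parts must be >= 1")
    n, tl = index.n, index.tarlength
    SA = index.SA
    cuts = [round(n * p / parts) for p in range(parts + 1)]
    adjusted = [0]
    for c in cuts[1:-1]:
        c = min(max(c, 1), n - 1)
        # the segment ending at c takes SA[c-1] as its last suffix: move the
        # cut forward until that suffix is reference-origin
        while c < n and classify_origin(int(SA[c - 1]), tl) is not Origin.REFERENCE:
            c += 1
        if c >= n:
            break
        if c > adjusted[-1]:
            adjusted.append(c)
    adjusted.append(n)
    intervals = [(a, b) for a, b in zip(adjusted, adjusted[1:]) if a < b]
    return SegmentPlan(tuple(intervals))


def scan_lms_segmented(index: ConcatIndex, plan: SegmentPlan) -> list[LmsRecord]:
    """Run the neighbor rule independently per segment; equals the serial scan.

    Each internal boundary sits on a reference-origin suffix, so a segment
    owning ranks [a, b) only ever searches ranks [a-1, b-1] — one rank of
    shared context on the left — and still sees the true nearest neighbors
    of every target rank it owns.
    """
    tl, n = index.tarlength, index.n
    records: list[LmsRecord] = [LmsRecord(p, 0, 0) for p in range(tl)]
    for a, b in plan.boundaries:
        lo = max(a - 1, 0)
        hi = b - 1 if b < n else n - 1
        for rank in range(a, b):
            pos = int(index.SA[rank])
            if pos >= tl:
                continue
            ns = neighbor_scan(index, rank, lo=lo, hi=hi)
            if ns.lcs_len <= 0:
                continue
            rp = ns.rp2 if ns.nlcp_len >= ns.plcp_len else ns.rp1
            records[pos] = LmsRecord(pos, int(index.SA[rp]) - tl, ns.lcs_len)
    return records


def brute_force_lms_oracle(
    target: str, ext_ref: str, pos: int | None = None
) -> list[tuple[int, int]] | tuple[int, int]:
    """Longest match per target position by longest-common-extension DP.

    Independent of suffix arrays: ``lce[i, j]`` (match run length of
    target[i:] vs ext_ref[j:]) is filled backwards one target row at a time
    with vectorised comparisons. Returns ``(ref_pos0, length)`` — 0-based
    reference offset, leftmost occurrence on ties — for one ``pos`` or for
    every position when ``pos`` is None.
    """
    tn, rn = len(target), len(ext_ref)
    if tn * rn > 1_000_000:
        raise ValueError("oracle refuses inputs beyond 1e6 cell comparisons")
    r = np.frombuffer(ext_ref.encode("ascii"), dtype=np.uint8)
    t = np.frombuffer(target.encode("ascii"), dtype=np.uint8)
    nxt = np.zeros(rn + 1, dtype=np.int64)
    best: list[tuple[int, int]] = [(0, 0)] * tn
    for i in range(tn - 1, -1, -1):
        cur = np.zeros(rn + 1, dtype=np.int64)
        cur[:rn] = np.where(r == t[i], nxt[1:] + 1, 0)
        j = int(np.argmax(cur[:rn]))
        best[i] = (j, int(cur[j])) if cur[j] > 0 else (0, 0)
        nxt = cur
    if pos is not None:
        return best[pos]
    return best
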