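"""Suffix array and LCP array over the target/reference concatenation.

The matching stage works on S = target ++ '$' ++ extended_reference, where
'$' (byte 0x24) sorts strictly before A, C, G and T, so the concatenation
needs no further terminator: the lexicographically smallest suffix is the
one starting at the separator.

The suffix array is built by prefix doubling with vectorised numpy sorts
(O(n log^2 n)); any correct construction is acceptable since downstream
stages depend only on the defining order, which the naive oracles pin down.
The LCP array uses Kasai's linear algorithm. An LCP segmentation plan mirrors
multi-core construction: each segment carries one rank of left context, so
concatenating per-segment results reproduces the serial array exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import ExtendedReference, PreprocessedTarget

__all__ = [
    "ConcatIndex",
    "SegmentPlan",
    "SEPARATOR",
    "build_concatenation",
    "build_suffix_array",
    "build_lcp_array",
    "build_index",
    "plan_lcp_segments",
    "build_lcp_segmented",
    "naive_suffix_array_oracle",
    "naive_lcp_oracle",
]

SEPARATOR = "$"

#: refuse naive-oracle inputs longer than this (quadratic behaviour)
ORACLE_MAX_LEN = 10_000


@dataclass(frozen=True)
class ConcatIndex:
    """Concatenated sequence with its suffix array and LCP array.

    ``LCP[0]`` is the sentinel −1 (rank 0 has no predecessor).
    """

    S: str
    n: int
    tarlength: int
    SA: np.ndarray
    LCP: np.ndarray


@dataclass(frozen=True)
class SegmentPlan:
    """Contiguous half-open rank intervals covering a rank range exactly once."""

    boundaries: tuple[tuple[int, int], ...]


def build_concatenation(
    target: PreprocessedTarget, ref: ExtendedReference
) -> tuple[str, int, int]:
    """Return (S, n, tarlength) for S = target ++ '$' ++ extended reference."""
    if SEPARATOR in target.seq or SEPARATOR in ref.seq:
        raise ValueError("'$' must not occur in the input sequences")
    if not target.seq or not ref.seq:
        raise ValueError("target and reference must be non-empty")
    S = target.seq + SEPARATOR + ref.seq
    return S, len(S), len(target.seq)


def build_suffix_array(S: str) -> np.ndarray:
    """Suffix array of ``S`` by prefix doubling (numpy lexsort passes)."""
    if not S:
        raise ValueError("empty input")
    n = len(S)
    data = np.frombuffer(S.encode("ascii"), dtype=np.uint8)
    # initial ranks from single characters
    _, rank = np.unique(data, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    idx = np.argsort(rank, kind="stable")
    while rank[idx[-1]] != n - 1:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        idx = np.lexsort((key2, rank))
        changed = np.ones(n, dtype=np.int64)
        changed[1:] = (rank[idx[1:]] != rank[idx[:-1]]) | (
            key2[idx[1:]] != key2[idx[:-1]]
        )
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[idx] = np.cumsum(changed) - 1
        rank = new_rank
        k *= 2
    return idx.astype(np.int64)


def build_lcp_array(S: str, SA: np.ndarray) -> np.ndarray:
    """LCP array by Kasai's algorithm; ``LCP[0] = -1`` sentinel.

    Raises ``ValueError`` if ``SA`` is not a permutation of the offsets of S.
    """
    n = len(S)
    if sorted(SA.tolist()) != list(range(n)):
        raise ValueError("SA is not a permutation of sequence offsets")
    rank = np.empty(n, dtype=np.int64)
    rank[SA] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    lcp[0] = -1
    sa = SA.tolist()
    rk = rank.tolist()
    h = 0
    for i in range(n):
        r = rk[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and S[i + h] == S[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def build_index(target: PreprocessedTarget, ref: ExtendedReference) -> ConcatIndex:
    """Full index construction: concatenate, then SA, then LCP."""
    S, n, tarlength = build_concatenation(target, ref)
    SA = build_suffix_array(S)
    LCP = build_lcp_array(S, SA)
    return ConcatIndex(S=S, n=n, tarlength=tarlength, SA=SA, LCP=LCP)


def plan_lcp_segments(n: int, parts: int) -> SegmentPlan:
    """Split ranks [1, n) into ``parts`` contiguous intervals for LCP work.

    Each segment later reads the rank just before its start as left context
    (the last suffix of the previous segment), so the cross-boundary LCP
    value is produced by exactly one segment.
    """
    total = n - 1  # ranks 1 .. n-1 carry LCP values
    if parts < 1 or parts > max(total, 1):
        raise ValueError(f"parts must be in [1, {max(total, 1)}], got {parts}")
    bounds: list[tuple[int, int]] = []
    base, extra = divmod(total, parts)
    start = 1
    for p in range(parts):
        size = base + (1 if p < extra else 0)
        bounds.append((start, start + size))
        start += size
    return SegmentPlan(tuple(b for b in bounds if b[0] < b[1]))


def build_lcp_segmented(S: str, SA: np.ndarray, plan: SegmentPlan) -> np.ndarray:
    """LCP array assembled from independent per-segment computations.

    Each segment [a, b) computes LCP[i] for its own ranks by direct
    comparison of suffix(SA[i-1]) and suffix(SA[i]); rank a-1 is the one
    rank of left context shared with the previous segment. Output equals
    :func:`build_lcp_array` for any plan.
    """
    n = len(S)
    lcp = np.zeros(n, dtype=np.int64)
    lcp[0] = -1
    covered = sorted(plan.boundaries)
    expect = 1
    for a, b in covered:
        if a != expect:
            raise ValueError("segment plan does not tile ranks [1, n)")
        expect = b
    if expect != n:
        raise ValueError("segment plan does not tile ranks [1, n)")
    for a, b in covered:
        for i in range(a, b):
            x, y = int(SA[i - 1]), int(SA[i])
            h = 0
            while x + h < n and y + h < n and S[x + h] == S[y + h]:
                h += 1
            lcp[i] = h
    return lcp


def naive_suffix_array_oracle(S: str) -> np.ndarray:
    """Definitionally correct suffix array: sort all suffixes outright."""
    if len(S) > ORACLE_MAX_LEN:
        raise ValueError(f"oracle refuses inputs longer than {ORACLE_MAX_LEN}")
    order = sorted(range(len(S)), key=lambda i: S[i:])
    return np.asarray(order, dtype=np.int64)


def naive_lcp_oracle(S: str, SA: np.ndarray) -> np.ndarray:
    """Definitionally correct LCP array: compare adjacent suffixes directly."""
    if len(S) > ORACLE_MAX_LEN:
        raise ValueError(f"oracle refuses inputs longer than {ORACLE_MAX_LEN}")
    n = len(S)
    lcp = np.zeros(n, dtype=np.int64)
    lcp[0] = -1
    for r in range(1, n):
        x, y = int(SA[r - 1]), int(SA[r])
        h = 0
        while x + h < n and y + h < n and S[x + h] == S[y + h]:
            h += 1
        lcp[r] = h
    return lcp
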