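"""Synthetic reference/target genome pairs with controlled divergence.

The generator emulates the situation the compressor is built for: a target
genome that is a lightly mutated copy of a reference. Starting from a
uniform random ACGT reference it applies, per base, substitutions
(``snp_rate``) and indels (``indel_rate``, geometric lengths with mean 3 —
short indels dominate real resequencing differences), splices in segments
of the reference in reverse-complement orientation (exercising the
opposite-strand half of the extended reference), and finally decorates the
target with lowercase runs (soft-masking, as in UCSC genome builds) and 'N'
runs (assembly gaps). Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqio import FastaRecord, reverse_complement

__all__ = ["SynthSpec", "synth_pair"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: mean length of geometric indel-length draws
INDEL_MEAN_LEN = 3.0


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of one generated pair; generation is deterministic in ``seed``."""

    ref_length: int = 10_000
    snp_rate: float = 1e-3
    indel_rate: float = 1e-4
    revcomp_segment_count: int = 0
    revcomp_segment_length: tuple[int, int] = (100, 300)
    lowercase_run_rate: float = 0.0
    n_run_rate: float = 0.0
    run_length: tuple[int, int] = (5, 50)
    line_width: int = 60
    seed: int = 1

    def __post_init__(self) -> None:
        if self.ref_length < 1:
            raise ValueError("ref_length must be >= 1")
        for name in ("snp_rate", "indel_rate", "lowercase_run_rate", "n_run_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, ref: str, spec: SynthSpec) -> str:
    """Apply SNPs and indels base by base."""
    out: list[str] = []
    bases = "ACGT"
    i = 0
    n = len(ref)
    while i < n:
        if spec.indel_rate and rng.random() < spec.indel_rate:
            size = 1 + rng.geometric(1.0 / INDEL_MEAN_LEN)
            if rng.random() < 0.5:
                i += size  # deletion
                continue
            out.append(_random_seq(rng, size))  # insertion, then copy the base
        c = ref[i]
        if spec.snp_rate and rng.random() < spec.snp_rate:
            c = bases[(bases.index(c) + rng.integers(1, 4)) % 4]
        out.append(c)
        i += 1
    return "".join(out)


def _insert_revcomp_segments(
    rng: np.random.Generator, target: str, ref: str, spec: SynthSpec
) -> tuple[str, list[tuple[int, int]]]:
    """Splice reverse-complemented reference segments into the target.

    Returns the new target and the (position-in-final-target, length) of
    each inserted segment, for tests that check the matches land in the
    reverse-complement half of the extended reference.
    """
    placements: list[tuple[int, int]] = []
    lo, hi = spec.revcomp_segment_length
    for _ in range(spec.revcomp_segment_count):
        seg_len = int(rng.integers(lo, hi + 1))
        seg_len = min(seg_len, len(ref))
        src = int(rng.integers(0, len(ref) - seg_len + 1))
        seg = reverse_complement(ref[src : src + seg_len])
        at = int(rng.integers(0, len(target) + 1))
        target = target[:at] + seg + target[at:]
        placements = [
            (p + seg_len, l) if p >= at else (p, l) for p, l in placements
        ]
        placements.append((at, seg_len))
    return target, placements


def _decorate(rng: np.random.Generator, seq: str, spec: SynthSpec) -> str:
    """Overlay lowercase runs and N runs (N overwrites the bases beneath)."""
    chars = list(seq)
    lo, hi = spec.run_length
    for rate, action in (
        (spec.n_run_rate, "n"),
        (spec.lowercase_run_rate, "case"),
    ):
        if not rate:
            continue
        i = 0
        while i < len(chars):
            if rng.random() < rate:
                run = int(rng.integers(lo, hi + 1))
                for j in range(i, min(i + run, len(chars))):
                    if action == "n":
                        chars[j] = "N"
                    else:
                        chars[j] = chars[j].lower()
                i += run
            else:
                i += 1
    return "".join(chars)


def synth_pair(
    spec: SynthSpec, with_placements: bool = False
) -> tuple[FastaRecord, FastaRecord] | tuple[FastaRecord, FastaRecord, list]:
    """Generate a (reference, target) record pair from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    ref = _random_seq(rng, spec.ref_length)
    target = _mutate(rng, ref, spec)
    target, placements = _insert_revcomp_segments(rng, target, ref, spec)
    target = _decorate(rng, target, spec)
    if not target:
        target = _random_seq(rng, 1)  # degenerate spec deleted everything
    ref_rec = FastaRecord("synthetic reference", ref, spec.line_width)
    tar_rec = FastaRecord("synthetic target", target, spec.line_width)
    if with_placements:
        return ref_rec, tar_rec, placements
    return ref_rec, tar_rec
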