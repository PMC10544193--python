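"""FASTA input/output and sequence normalization.

Matching runs over the uppercase {A,C,G,T} alphabet only, so before indexing:

* the target is uppercased and stripped of ambiguity codes, with the
  lowercase runs and the removed letters recorded (in original coordinates)
  so decompression can restore the input byte-for-byte;
* the reference is uppercased, stripped of non-ACGT letters *without*
  recording anything (its metadata is never needed to decode), and extended
  with its own reverse complement so opposite-strand matches need no strand
  flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FastaRecord",
    "CaseRun",
    "AmbigRun",
    "PreprocessedTarget",
    "ExtendedReference",
    "FastaFormatError",
    "EmptySequenceError",
    "read_fasta",
    "write_fasta",
    "format_fasta",
    "reverse_complement",
    "preprocess_target",
    "preprocess_reference",
    "restore_target",
]

ACGT = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


class EmptySequenceError(ValueError):
    """A sequence is empty after cleaning (nothing left to compress/match)."""


@dataclass(frozen=True)
class FastaRecord:
    """One FASTA record plus the wrap width needed to re-emit it verbatim.

    ``line_width`` is the width of the first full sequence line; 0 means the
    sequence was on a single line.
    """

    header: str
    sequence: str
    line_width: int = 0

    def __post_init__(self) -> None:
        if self.line_width < 0:
            raise ValueError("line_width must be >= 0")
        if any(c.isspace() or c == ">" for c in self.sequence):
            raise ValueError("sequence must not contain whitespace or '>'")


@dataclass(frozen=True)
class CaseRun:
    """Run of lowercase letters, in coordinates of the original sequence."""

    start: int
    length: int


@dataclass(frozen=True)
class AmbigRun:
    """Run of one repeated non-ACGT letter (uppercased), original coordinates."""

    start: int
    length: int
    letter: str


@dataclass(frozen=True)
class PreprocessedTarget:
    """Cleaned target sequence plus everything needed to undo the cleaning."""

    seq: str
    case_runs: tuple[CaseRun, ...]
    ambig_runs: tuple[AmbigRun, ...]
    header: str
    line_width: int
    original_length: int


@dataclass(frozen=True)
class ExtendedReference:
    """Cleaned reference concatenated with its own reverse complement."""

    seq: str
    base_length: int


def read_fasta(path) -> list[FastaRecord]:
    """Parse a FASTA file into records, capturing per-record wrap width.

    Raises :class:`FastaFormatError` (naming the offending line) on sequence
    data before the first header or on a record with no sequence.
    """
    records: list[FastaRecord] = []
    header: str | None = None
    lines: list[str] = []
    header_lineno = 0

    def flush() -> None:
        if header is None:
            return
        if not lines:
            raise FastaFormatError(
                f"record {header!r} at line {header_lineno} has no sequence"
            )
        width = len(lines[0]) if len(lines) > 1 else 0
        records.append(FastaRecord(header, "".join(lines), width))

    with open(path, "r", encoding="ascii") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                header_lineno = lineno
                lines = []
            else:
                if header is None:
                    raise FastaFormatError(
                        f"sequence data before first '>' header at line {lineno}"
                    )
                lines.append(line)
    flush()
    if header is None:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return records


def format_fasta(records: list[FastaRecord]) -> str:
    """Render records back to FASTA text, honoring each record's wrap width."""
    parts: list[str] = []
    for rec in records:
        parts.append(f">{rec.header}\n")
        seq, w = rec.sequence, rec.line_width
        if w == 0:
            parts.append(seq + "\n")
        else:
            for i in range(0, len(seq), w):
                parts.append(seq[i : i + w] + "\n")
    return "".join(parts)


def write_fasta(records: list[FastaRecord], path) -> None:
    with open(path, "w", encoding="ascii", newline="") as fh:
        fh.write(format_fasta(records))


def reverse_complement(seq: str) -> str:
    """Reverse-complement an uppercase ACGT string (an involution)."""
    bad = set(seq) - ACGT
    if bad:
        raise ValueError(f"non-ACGT letters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def _lowercase_runs(seq: str) -> tuple[CaseRun, ...]:
    runs: list[CaseRun] = []
    start = -1
    for i, c in enumerate(seq):
        if c.islower():
            if start < 0:
                start = i
        elif start >= 0:
            runs.append(CaseRun(start, i - start))
            start = -1
    if start >= 0:
        runs.append(CaseRun(start, len(seq) - start))
    return tuple(runs)


def preprocess_target(record: FastaRecord) -> PreprocessedTarget:
    """Uppercase the target and strip non-ACGT letters, recording both edits.

    Lowercase runs and ambiguity runs are stored against the *original*
    coordinates: restoration first reinserts ambiguity letters, then
    re-lowercases, so a lowercase 'n' round-trips correctly.
    """
    orig = record.sequence
    case_runs = _lowercase_runs(orig)
    upper = orig.upper()

    kept: list[str] = []
    ambig: list[AmbigRun] = []
    run_start = -1
    run_letter = ""
    for i, c in enumerate(upper):
        if c in ACGT:
            if run_start >= 0:
                ambig.append(AmbigRun(run_start, i - run_start, run_letter))
                run_start = -1
            kept.append(c)
        else:
            if run_start >= 0 and c == run_letter:
                continue
            if run_start >= 0:
                ambig.append(AmbigRun(run_start, i - run_start, run_letter))
            run_start = i
            run_letter = c
    if run_start >= 0:
        ambig.append(AmbigRun(run_start, len(upper) - run_start, run_letter))

    seq = "".join(kept)
    if not seq:
        raise EmptySequenceError(
            f"target record {record.header!r} is empty after cleaning"
        )
    return PreprocessedTarget(
        seq=seq,
        case_runs=case_runs,
        ambig_runs=tuple(ambig),
        header=record.header,
        line_width=record.line_width,
        original_length=len(orig),
    )


def preprocess_reference(record: FastaRecord) -> ExtendedReference:
    """Clean the reference (no metadata kept) and append its reverse complement."""
    cleaned = "".join(c for c in record.sequence.upper() if c in ACGT)
    if not cleaned:
        raise EmptySequenceError(
            f"reference record {record.header!r} is empty after cleaning"
        )
    return ExtendedReference(
        seq=cleaned + reverse_complement(cleaned), base_length=len(cleaned)
    )


def restore_target(pre: PreprocessedTarget, decoded_seq: str) -> FastaRecord:
    """Invert :func:`preprocess_target`: reinsert ambiguity runs, re-lowercase."""
    if len(decoded_seq) != len(pre.seq):
        raise ValueError(
            f"decoded length {len(decoded_seq)} != expected {len(pre.seq)}"
        )
    out = [""] * pre.original_length
    for run in pre.ambig_runs:
        for i in range(run.start, run.start + run.length):
            out[i] = run.letter
    it = iter(decoded_seq)
    for i in range(pre.original_length):
        if not out[i]:
            out[i] = next(it)
    for run in pre.case_runs:
        for i in range(run.start, run.start + run.length):
            out[i] = out[i].lower()
    return FastaRecord(pre.header, "".join(out), pre.line_width)
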