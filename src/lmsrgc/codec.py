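"""Token encoding, serialization and the compress/decompress pipelines.

The final disjoint matches are turned into an ordered stream of tokens
walking the target left to right:

* a literal token for every stretch of target not covered by a match;
* a match token per match — its position field is the absolute extended-
  reference offset for the first match and a signed delta
  ``cur_ref - (prev_ref + prev_len)`` afterwards.

Two refinements from the coder: when a delta exceeds ``distance_threshold``,
a letter-by-letter run starting right after the previous match's reference
interval is tried, and if it reaches ``letterwise_fraction`` of the match it
replaces it (keeping deltas small); and when the delta equals the length of
the literal between two matches — the two matches are adjacent in both
sequences with equally many mismatching letters in between — the position
field is omitted entirely, because the decoder can infer it.

The serialized intermediate form is line-based ('<pos>,<len>' per match,
',<len>' when omitted, lowercase literal text otherwise, as in the worked
stream '2,23' / 'atccctaag' / ',23'), prefixed with a keyed metadata block.
A pluggable general-purpose block compressor (stdlib bz2 by default)
produces the final archive.
"""

from __future__ import annotations

import bz2
import hashlib
import json
import lzma
import struct as _struct
import zlib
from dataclasses import dataclass

from .filtering import FilterParams, filter_lms
from .index import build_index
from .search import LmsRecord, scan_lms
from .seqio import (
    AmbigRun,
    CaseRun,
    ExtendedReference,
    FastaRecord,
    PreprocessedTarget,
    format_fasta,
    preprocess_reference,
    preprocess_target,
    read_fasta,
    restore_target,
)

__all__ = [
    "MatchToken",
    "LiteralToken",
    "EncoderParams",
    "Archive",
    "CorruptionError",
    "WrongReferenceError",
    "letterwise_extend",
    "encode_matches",
    "decode_stream",
    "serialize_intermediate",
    "parse_intermediate",
    "compress_final",
    "decompress_final",
    "write_archive",
    "read_archive",
    "compress_pipeline",
    "decompress_pipeline",
    "stream_stats",
    "BACKENDS",
]

MAGIC = b"LMSZ"
FORMAT_VERSION = 1


class CorruptionError(ValueError):
    """Archive or token stream is internally inconsistent."""


class WrongReferenceError(ValueError):
    """The reference supplied for decoding is not the one used to encode."""


@dataclass(frozen=True)
class MatchToken:
    """``pos`` is absolute (first match), a signed delta, or None (omitted)."""

    pos: int | None
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("match length must be >= 1")


@dataclass(frozen=True)
class LiteralToken:
    text: str

    def __post_init__(self) -> None:
        if not self.text or set(self.text) - set("ACGT"):
            raise ValueError("literal must be nonempty uppercase ACGT")


Token = MatchToken | LiteralToken


@dataclass(frozen=True)
class EncoderParams:
    """Tunables of the coder.

    ``distance_threshold`` — delta magnitude above which the letterwise
    fallback is attempted; ``letterwise_fraction`` — how much of the match
    the letterwise run must reach to replace it; ``kmerlength`` — minimum
    match length (shared with filtering).
    """

    distance_threshold: int = 1000
    letterwise_fraction: float = 0.9
    kmerlength: int = 21

    def __post_init__(self) -> None:
        if self.distance_threshold < 0:
            raise ValueError("distance_threshold must be >= 0")
        if not (0 < self.letterwise_fraction <= 1):
            raise ValueError("letterwise_fraction must be in (0, 1]")
        if self.kmerlength < 1:
            raise ValueError("kmerlength must be >= 1")

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(kmerlength=self.kmerlength)


def letterwise_extend(
    target: str, tar_pos: int, ext_ref: str, ref_pos: int
) -> int:
    """Length of the maximal equal-character run at (tar_pos, ref_pos)."""
    n = 0
    tn, rn = len(target), len(ext_ref)
    while (
        tar_pos + n < tn
        and ref_pos + n < rn
        and target[tar_pos + n] == ext_ref[ref_pos + n]
    ):
        n += 1
    return n


def encode_matches(
    target: PreprocessedTarget,
    ext_ref: ExtendedReference,
    finals: list[LmsRecord],
    params: EncoderParams,
) -> list[Token]:
    """Delta-code the final matches into a token stream covering the target.

    Reference positions inside match records follow the 1-based convention
    (``ref - 1`` is the extended-reference offset); the stream stores 0-based
    absolute positions and deltas.
    """
    seq, ref_seq = target.seq, ext_ref.seq
    tokens: list[Token] = []
    pos = 0
    prev_end: int | None = None  # 0-based end of previous match in ext_ref
    for rec in finals:
        if rec.tar < pos:
            raise CorruptionError("final matches overlap or are unsorted")
        ref0, length = rec.ref - 1, rec.lms_len
        if seq[rec.tar : rec.tar + length] != ref_seq[ref0 : ref0 + length]:
            raise CorruptionError(
                f"match at target {rec.tar} fails substring identity"
            )
        gap = seq[pos : rec.tar]
        if prev_end is not None:
            delta = ref0 - prev_end
            if abs(delta) > params.distance_threshold:
                run = letterwise_extend(seq, rec.tar, ref_seq, prev_end)
                run = min(run, length)
                if run >= params.letterwise_fraction * length:
                    ref0, length, delta = prev_end, run, 0
        if gap:
            tokens.append(LiteralToken(gap))
        if prev_end is None:
            tokens.append(MatchToken(ref0, length))
        elif delta == len(gap):
            tokens.append(MatchToken(None, length))
        else:
            tokens.append(MatchToken(delta, length))
        pos = rec.tar + length
        prev_end = ref0 + length
    if pos < len(seq):
        tokens.append(LiteralToken(seq[pos:]))
    return tokens


def decode_stream(tokens: list[Token], ext_ref: ExtendedReference) -> str:
    """Invert :func:`encode_matches` against the rebuilt extended reference."""
    out: list[str] = []
    ref_seq = ext_ref.seq
    prev_end: int | None = None
    gap_len = 0
    for tok in tokens:
        if isinstance(tok, LiteralToken):
            out.append(tok.text)
            gap_len = len(tok.text)
            continue
        if prev_end is None:
            if tok.pos is None:
                raise CorruptionError("first match token has no position")
            start = tok.pos
        elif tok.pos is None:
            start = prev_end + gap_len
        else:
            start = prev_end + tok.pos
        if start < 0 or start + tok.length > len(ref_seq):
            raise CorruptionError(
                f"match [{start}, {start + tok.length}) outside reference"
            )
        out.append(ref_seq[start : start + tok.length])
        prev_end = start + tok.length
        gap_len = 0
    return "".join(out)


# ---------------------------------------------------------------------------
# intermediate serialization
# ---------------------------------------------------------------------------

_META_INT_KEYS = ("line_width", "tarlength", "original_length")


def _runs_to_str(runs) -> str:
    parts = []
    for r in runs:
        if isinstance(r, AmbigRun):
            parts.append(f"{r.start}:{r.length}:{r.letter}")
        else:
            parts.append(f"{r.start}:{r.length}")
    return " ".join(parts)


def _parse_case_runs(text: str) -> tuple[CaseRun, ...]:
    if not text:
        return ()
    out = []
    for item in text.split():
        s, l = item.split(":")
        out.append(CaseRun(int(s), int(l)))
    return tuple(out)


def _parse_ambig_runs(text: str) -> tuple[AmbigRun, ...]:
    if not text:
        return ()
    out = []
    for item in text.split():
        s, l, letter = item.split(":")
        out.append(AmbigRun(int(s), int(l), letter))
    return tuple(out)


def serialize_intermediate(tokens: list[Token], metadata: dict) -> bytes:
    """One record section: '@'-keyed metadata block, then one token per line.

    Match lines are '<pos>,<len>' (bare ',<len>' when the position is
    omitted); literal lines are the lowercase literal text.
    """
    lines = ["@record"]
    for key in ("header", *(k for k in _META_INT_KEYS if k in metadata)):
        if key in metadata:
            lines.append(f"@{key} {metadata[key]}")
    lines.append(f"@case_runs {_runs_to_str(metadata.get('case_runs', ()))}")
    lines.append(f"@ambig_runs {_runs_to_str(metadata.get('ambig_runs', ()))}")
    lines.append("@tokens")
    for tok in tokens:
        if isinstance(tok, MatchToken):
            lines.append(f"{'' if tok.pos is None else tok.pos},{tok.length}")
        else:
            lines.append(tok.text.lower())
    lines.append("@end")
    return ("\n".join(lines) + "\n").encode("ascii")


def _parse_section(
    lines: list[tuple[int, str]], base_offset: int
) -> tuple[list[Token], dict]:
    metadata: dict = {"case_runs": (), "ambig_runs": ()}
    tokens: list[Token] = []
    in_tokens = False
    closed = False
    for offset, line in lines:
        if closed or not line:
            continue
        if line == "@record":
            pass
        elif line == "@tokens":
            in_tokens = True
        elif line == "@end":
            closed = True
        elif line.startswith("@"):
            if in_tokens:
                raise CorruptionError(f"metadata after @tokens at byte {offset}")
            key, _, value = line[1:].partition(" ")
            if key in _META_INT_KEYS:
                metadata[key] = int(value)
            elif key == "case_runs":
                metadata[key] = _parse_case_runs(value)
            elif key == "ambig_runs":
                metadata[key] = _parse_ambig_runs(value)
            else:
                metadata[key] = value
        elif in_tokens:
            if line[0] in "0123456789-," :
                pospart, _, lenpart = line.partition(",")
                try:
                    pos = None if pospart == "" else int(pospart)
                    tokens.append(MatchToken(pos, int(lenpart)))
                except ValueError as exc:
                    raise CorruptionError(
                        f"bad match line {line!r} at byte {offset}"
                    ) from exc
            else:
                up = line.upper()
                if set(up) - set("ACGT"):
                    raise CorruptionError(
                        f"bad literal line {line!r} at byte {offset}"
                    )
                tokens.append(LiteralToken(up))
        else:
            raise CorruptionError(f"unexpected line {line!r} at byte {offset}")
    if not closed:
        raise CorruptionError(f"unterminated record section at byte {base_offset}")
    return tokens, metadata


def parse_intermediate(data: bytes) -> tuple[list[Token], dict]:
    """Inverse of :func:`serialize_intermediate` for a single section."""
    sections = split_sections(data)
    if len(sections) != 1:
        raise CorruptionError(f"expected one record section, got {len(sections)}")
    return sections[0]


def split_sections(data: bytes) -> list[tuple[list[Token], dict]]:
    """Parse a concatenation of record sections (line-delimited)."""
    text = data.decode("ascii")
    out = []
    section: list[tuple[int, str]] = []
    section_start = 0
    offset = 0
    for line in text.split("\n"):
        if line == "@record":
            if section:
                raise CorruptionError(
                    f"unterminated record section at byte {section_start}"
                )
            section_start = offset
        if line:
            section.append((offset, line))
        if line == "@end":
            out.append(_parse_section(section, section_start))
            section = []
        offset += len(line) + 1
    if section:
        raise CorruptionError(f"unterminated record section at byte {section_start}")
    if not out:
        raise CorruptionError("no record sections found")
    return out


# ---------------------------------------------------------------------------
# entropy backend and archive container
# ---------------------------------------------------------------------------

BACKENDS = {
    "store": (lambda b: b, lambda b: b),
    "zlib": (lambda b: zlib.compress(b, 9), zlib.decompress),
    "bz2": (lambda b: bz2.compress(b, 9), bz2.decompress),
    "lzma": (lzma.compress, lzma.decompress),
}

DEFAULT_BACKEND = "bz2"


@dataclass(frozen=True)
class Archive:
    """Self-describing container: entropy-compressed sections + metadata."""

    backend: str
    payload: bytes
    ref_checksum: str = ""
    trailing_newline: bool = True
    version: int = FORMAT_VERSION


def compress_final(
    data: bytes,
    backend: str = DEFAULT_BACKEND,
    ref_checksum: str = "",
    trailing_newline: bool = True,
) -> Archive:
    if backend not in BACKENDS:
        raise ValueError(
            f"unknown backend {backend!r}; available: {sorted(BACKENDS)}"
        )
    return Archive(
        backend=backend,
        payload=BACKENDS[backend][0](data),
        ref_checksum=ref_checksum,
        trailing_newline=trailing_newline,
    )


def decompress_final(archive: Archive) -> bytes:
    if archive.backend not in BACKENDS:
        raise ValueError(f"unknown backend {archive.backend!r}")
    return BACKENDS[archive.backend][1](archive.payload)


def write_archive(archive: Archive, path) -> None:
    header = json.dumps(
        {
            "version": archive.version,
            "backend": archive.backend,
            "ref_checksum": archive.ref_checksum,
            "trailing_newline": archive.trailing_newline,
        }
    ).encode("ascii")
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(_struct.pack(">I", len(header)))
        fh.write(header)
        fh.write(archive.payload)


def read_archive(path) -> Archive:
    with open(path, "rb") as fh:
        magic = fh.read(4)
        if magic != MAGIC:
            raise CorruptionError(f"{path}: not an lmsrgc archive")
        (hlen,) = _struct.unpack(">I", fh.read(4))
        header = json.loads(fh.read(hlen).decode("ascii"))
        payload = fh.read()
    if header.get("version") != FORMAT_VERSION:
        raise CorruptionError(f"unsupported archive version {header.get('version')}")
    return Archive(
        backend=header["backend"],
        payload=payload,
        ref_checksum=header["ref_checksum"],
        trailing_newline=header["trailing_newline"],
    )


# ---------------------------------------------------------------------------
# end-to-end pipelines
# ---------------------------------------------------------------------------


def _reference_from_fasta(ref_path) -> tuple[ExtendedReference, str]:
    """Extended reference over all records of the file, plus its checksum."""
    records = read_fasta(ref_path)
    merged = FastaRecord(
        records[0].header, "".join(r.sequence for r in records), 0
    )
    ext = preprocess_reference(merged)
    checksum = hashlib.sha256(
        ext.seq[: ext.base_length].encode("ascii")
    ).hexdigest()
    return ext, checksum


def compress_record(
    pre: PreprocessedTarget, ext_ref: ExtendedReference, params: EncoderParams
) -> tuple[list[Token], list[LmsRecord]]:
    """Index, scan, filter and encode one preprocessed target record."""
    index = build_index(pre, ext_ref)
    finals = filter_lms(scan_lms(index), params.filter_params)
    return encode_matches(pre, ext_ref, finals, params), finals


def compress_pipeline(
    target_path,
    ref_path,
    params: EncoderParams | None = None,
    backend: str = DEFAULT_BACKEND,
) -> Archive:
    """Compress a target FASTA against a reference FASTA into an Archive."""
    params = params or EncoderParams()
    ext_ref, checksum = _reference_from_fasta(ref_path)
    sections: list[bytes] = []
    for rec in read_fasta(target_path):
        pre = preprocess_target(rec)
        tokens, _ = compress_record(pre, ext_ref, params)
        metadata = {
            "header": pre.header,
            "line_width": pre.line_width,
            "tarlength": len(pre.seq),
            "original_length": pre.original_length,
            "case_runs": pre.case_runs,
            "ambig_runs": pre.ambig_runs,
        }
        sections.append(serialize_intermediate(tokens, metadata))
    with open(target_path, "rb") as fh:
        raw = fh.read()
    return compress_final(
        b"".join(sections),
        backend=backend,
        ref_checksum=checksum,
        trailing_newline=raw.endswith(b"\n"),
    )


def decompress_pipeline(archive: Archive, ref_path, out_path=None) -> str:
    """Decode an Archive back to FASTA text (optionally writing it).

    Raises :class:`WrongReferenceError` if ``ref_path`` does not hash to the
    reference recorded in the archive.
    """
    ext_ref, checksum = _reference_from_fasta(ref_path)
    if archive.ref_checksum and checksum != archive.ref_checksum:
        raise WrongReferenceError(
            f"reference {ref_path} does not match the archive's reference"
        )
    records: list[FastaRecord] = []
    for tokens, metadata in split_sections(decompress_final(archive)):
        seq = decode_stream(tokens, ext_ref)
        if len(seq) != metadata["tarlength"]:
            raise CorruptionError(
                f"decoded length {len(seq)} != recorded {metadata['tarlength']}"
            )
        pre = PreprocessedTarget(
            seq=seq,
            case_runs=metadata["case_runs"],
            ambig_runs=metadata["ambig_runs"],
            header=metadata.get("header", ""),
            line_width=metadata.get("line_width", 0),
            original_length=metadata["original_length"],
        )
        records.append(restore_target(pre, seq))
    text = format_fasta(records)
    if not archive.trailing_newline:
        text = text.rstrip("\n")
    if out_path is not None:
        with open(out_path, "w", encoding="ascii", newline="") as fh:
            fh.write(text)
    return text


def stream_stats(tokens: list[Token]) -> dict:
    """Match/literal accounting of one token stream (for logs and reports)."""
    match_lens = [t.length for t in tokens if isinstance(t, MatchToken)]
    literal_len = sum(len(t.text) for t in tokens if isinstance(t, LiteralToken))
    total = sum(match_lens) + literal_len
    return {
        "match_count": len(match_lens),
        "mean_match_length": (sum(match_lens) / len(match_lens)) if match_lens else 0.0,
        "literal_bases": literal_len,
        "literal_fraction": (literal_len / total) if total else 0.0,
        "total_bases": total,
    }
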