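import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lmsrgc import (
    Archive,
    CorruptionError,
    EncoderParams,
    ExtendedReference,
    FastaRecord,
    LiteralToken,
    LmsRecord,
    MatchToken,
    PreprocessedTarget,
    WrongReferenceError,
    compress_final,
    compress_pipeline,
    decode_stream,
    decompress_final,
    decompress_pipeline,
    encode_matches,
    letterwise_extend,
    parse_intermediate,
    read_archive,
    reverse_complement,
    serialize_intermediate,
    stream_stats,
    write_archive,
    write_fasta,
)
from lmsrgc.codec import split_sections
from conftest import random_seq
from lmsrgc.synth import SynthSpec, synth_pair


def _ext(ref: str) -> ExtendedReference:
    return ExtendedReference(ref + reverse_complement(ref), len(ref))


def _pre(seq: str) -> PreprocessedTarget:
    return PreprocessedTarget(seq, (), (), "t", 0, len(seq))


@pytest.fixture()
def omission_fixture():
    """Two 23-long matches whose 9-base reference gap equals the 9-letter
    literal between them: the second match's position can be omitted."""
    rng = np.random.default_rng(5)
    ref = random_seq(rng, 80)
    gap = "ATCCCTAAG"
    target = ref[2:25] + gap + ref[34:57]
    # make sure the literal really mismatches the reference gap
    assert ref[25:34] != gap
    finals = [LmsRecord(0, 3, 23), LmsRecord(32, 35, 23)]
    return _pre(target), _ext(ref), finals


def test_adjacent_match_position_is_omitted(omission_fixture):
    pre, ext, finals = omission_fixture
    tokens = encode_matches(pre, ext, finals, EncoderParams())
    assert tokens == [
        MatchToken(2, 23),
        LiteralToken("ATCCCTAAG"),
        MatchToken(None, 23),
    ]
    lines = serialize_intermediate(tokens, {"header": "t"}).decode().splitlines()
    i = lines.index("@tokens")
    assert lines[i + 1 : i + 4] == ["2,23", "atccctaag", ",23"]
    assert decode_stream(tokens, ext) == pre.seq


def test_full_cover_single_match_has_no_literals():
    rng = np.random.default_rng(6)
    ref = random_seq(rng, 60)
    pre, ext = _pre(ref[10:50]), _ext(ref)
    tokens = encode_matches(pre, ext, [LmsRecord(0, 11, 40)], EncoderParams())
    assert tokens == [MatchToken(10, 40)]
    assert decode_stream(tokens, ext) == pre.seq


def test_encoder_rejects_bad_substring_identity():
    rng = np.random.default_rng(7)
    ref = random_seq(rng, 60)
    pre, ext = _pre("ACGT" * 10), _ext(ref)
    with pytest.raises(CorruptionError, match="substring identity"):
        encode_matches(pre, ext, [LmsRecord(0, 1, 10)], EncoderParams())


def test_letterwise_extend_counts_equal_run():
    assert letterwise_extend("CCTAA", 0, "CCTGG", 0) == 3
    assert letterwise_extend("ACGT", 0, "CCGT", 0) == 0
    assert letterwise_extend("ACGT", 2, "ACGT", 2) == 2
    rng = np.random.default_rng(8)
    a, b = random_seq(rng, 50), random_seq(rng, 50)
    for i in range(0, 50, 7):
        n = 0
        while i + n < 50 and a[i + n] == b[i + n]:
            n += 1
        assert letterwise_extend(a, i, b, i) == n


def test_letterwise_fallback_replaces_distant_match():
    # target continues letter-by-letter right after the previous match's
    # reference end, but its recorded LMS points far away
    rng = np.random.default_rng(9)
    ref = random_seq(rng, 3000)
    target = ref[0:40] + ref[40:78] + "T" + ref[2500:2530]
    pre, ext = _pre(target), _ext(ref)
    # second match deliberately recorded at its distant duplicate position
    finals = [LmsRecord(0, 1, 40), LmsRecord(40, 2001, 38), LmsRecord(79, 2501, 30)]
    # plant the duplicate so the distant record satisfies substring identity
    ref2 = ref[:2000] + ref[40:78] + ref[2038:]
    ext2 = _ext(ref2)
    tgt2 = ref2[0:40] + ref2[40:78] + "T" + ref2[2500:2530]
    params = EncoderParams(distance_threshold=100, letterwise_fraction=0.9)
    tokens = encode_matches(_pre(tgt2), ext2, finals, params)
    # the distant delta was replaced by a zero-delta letterwise continuation
    assert tokens[1] == MatchToken(None, 38) or tokens[1] == MatchToken(0, 38)
    assert decode_stream(tokens, ext2) == tgt2


@given(
    st.lists(
        st.one_of(
            st.tuples(
                st.one_of(st.none(), st.integers(-(10**6), 10**6)),
                st.integers(1, 10**5),
            ),
            st.text(alphabet="ACGT", min_size=1, max_size=30),
        ),
        max_size=20,
    )
)
def test_serialize_parse_identity(items):
    tokens = []
    first_match = True
    for item in items:
        if isinstance(item, tuple):
            pos, length = item
            if first_match and pos is None:
                pos = 0
            tokens.append(MatchToken(pos, length))
            first_match = False
        else:
            tokens.append(LiteralToken(item))
    meta = {"header": "rec 1", "tarlength": 123, "line_width": 60}
    data = serialize_intermediate(tokens, meta)
    tokens2, meta2 = parse_intermediate(data)
    assert tokens2 == tokens
    assert meta2["header"] == "rec 1"
    assert meta2["tarlength"] == 123 and meta2["line_width"] == 60


def test_parse_errors_name_byte_offset():
    data = serialize_intermediate([MatchToken(1, 5)], {"header": "x"})
    broken = data.replace(b"1,5", b"1;5")
    with pytest.raises(CorruptionError, match="byte"):
        parse_intermediate(broken)


def test_multiple_sections_round_trip():
    a = serialize_intermediate([MatchToken(0, 3)], {"header": "a", "tarlength": 3})
    b = serialize_intermediate([LiteralToken("ACGT")], {"header": "b", "tarlength": 4})
    sections = split_sections(a + b)
    assert [m["header"] for _, m in sections] == ["a", "b"]


@pytest.mark.parametrize("backend", ["store", "zlib", "bz2", "lzma"])
def test_backend_round_trip(backend):
    rng = np.random.default_rng(10)
    for payload in (b"", rng.integers(0, 256, size=2000).astype("u1").tobytes()):
        archive = compress_final(payload, backend=backend)
        assert decompress_final(archive) == payload


def test_repetitive_payload_shrinks():
    payload = b"ACGTACGT" * 4000
    archive = compress_final(payload, backend="bz2")
    assert len(archive.payload) < len(payload)


def test_unknown_backend_rejected():
    with pytest.raises(ValueError, match="unknown backend"):
        compress_final(b"x", backend="brotli")


def test_archive_file_round_trip(tmp_path):
    archive = compress_final(b"payload", backend="zlib", ref_checksum="ab12",
                             trailing_newline=False)
    p = tmp_path / "a.lmsz"
    write_archive(archive, p)
    back = read_archive(p)
    assert back == archive


def test_decode_rejects_out_of_range():
    ext = _ext("ACGTACGT")
    with pytest.raises(CorruptionError, match="outside"):
        decode_stream([MatchToken(14, 5)], ext)


def test_pipeline_worked_micro_pair(tmp_path):
    write_fasta([FastaRecord("chr", "CCCTAG", 0)], tmp_path / "t.fa")
    write_fasta([FastaRecord("chr", "ACCTCT", 0)], tmp_path / "r.fa")
    params = EncoderParams(kmerlength=1)
    archive = compress_pipeline(tmp_path / "t.fa", tmp_path / "r.fa", params)
    out = decompress_pipeline(archive, tmp_path / "r.fa")
    assert out == (tmp_path / "t.fa").read_text()


def test_pipeline_identical_files_single_match_per_record(tmp_path):
    rng = np.random.default_rng(12)
    seq = random_seq(rng, 4000)
    write_fasta([FastaRecord("chr", seq, 70)], tmp_path / "t.fa")
    write_fasta([FastaRecord("chr", seq, 70)], tmp_path / "r.fa")
    archive = compress_pipeline(tmp_path / "t.fa", tmp_path / "r.fa")
    tokens, _ = parse_intermediate(decompress_final(archive))
    assert tokens == [MatchToken(0, 4000)]
    assert decompress_pipeline(archive, tmp_path / "r.fa") == (
        tmp_path / "t.fa"
    ).read_text()


def test_pipeline_wrong_reference_detected(tmp_path):
    rng = np.random.default_rng(14)
    write_fasta([FastaRecord("t", random_seq(rng, 500), 60)], tmp_path / "t.fa")
    write_fasta([FastaRecord("r", random_seq(rng, 500), 60)], tmp_path / "r.fa")
    write_fasta([FastaRecord("r2", random_seq(rng, 500), 60)], tmp_path / "r2.fa")
    archive = compress_pipeline(tmp_path / "t.fa", tmp_path / "r.fa")
    with pytest.raises(WrongReferenceError):
        decompress_pipeline(archive, tmp_path / "r2.fa")


def test_token_lengths_account_for_whole_target(tmp_path):
    ref, tar = synth_pair(SynthSpec(ref_length=3000, snp_rate=5e-3, seed=3))
    write_fasta([ref], tmp_path / "r.fa")
    write_fasta([tar], tmp_path / "t.fa")
    archive = compress_pipeline(tmp_path / "t.fa", tmp_path / "r.fa")
    tokens, meta = parse_intermediate(decompress_final(archive))
    assert stream_stats(tokens)["total_bases"] == meta["tarlength"]


def test_archive_size_decreases_with_divergence(tmp_path):
    sizes = []
    for snp in (1e-2, 1e-3, 0.0):
        ref, tar = synth_pair(
            SynthSpec(ref_length=20_000, snp_rate=snp, indel_rate=0.0, seed=5)
        )
        write_fasta([ref], tmp_path / "r.fa")
        write_fasta([tar], tmp_path / "t.fa")
        archive = compress_pipeline(tmp_path / "t.fa", tmp_path / "r.fa")
        sizes.append(len(archive.payload))
    assert sizes[0] >= sizes[1] >= sizes[2]
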