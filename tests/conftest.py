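import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lmsrgc import (
    FastaRecord,
    LmsRecord,
    PreprocessedTarget,
    build_index,
    preprocess_reference,
    preprocess_target,
    truncate_once,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

ALPHABET = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=length))


def make_pair(rng: np.random.Generator, tn: int, rn: int):
    """Random target/extended-reference pair plus its concatenation index."""
    target = random_seq(rng, tn)
    pre = PreprocessedTarget(target, (), (), "t", 0, tn)
    ext = preprocess_reference(FastaRecord("r", random_seq(rng, rn), 0))
    return pre, ext, build_index(pre, ext)


def literal_resolve(records, k):
    """Reference implementation of overlap resolution: full re-sort each
    round, truncating every overlapping candidate as soon as one is
    recorded. Ties: longest first, then smaller tar, then smaller ref."""
    cands = [(r.tar, r.ref, r.lms_len) for r in records if r.lms_len >= k]
    final = []
    while cands:
        cands.sort(key=lambda c: (-c[2], c[0], c[1]))
        tar, ref, ln = cands.pop(0)
        final.append(LmsRecord(tar, ref, ln))
        nxt = []
        for t, rf, l in cands:
            nt, nl = truncate_once(t, l, tar, tar + ln)
            rf += nt - t
            if nl >= k:
                nxt.append((nt, rf, nl))
        cands = nxt
    return sorted(final, key=lambda r: r.tar)


@pytest.fixture(scope="session")
def table1_index():
    """Index over 'CCCTAG$ACCTCTAGAGGT' (target CCCTAG vs reference ACCTCT)."""
    tar = preprocess_target(FastaRecord("t", "CCCTAG", 0))
    ref = preprocess_reference(FastaRecord("r", "ACCTCT", 0))
    return build_index(tar, ref)
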