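# Methods

## Problem and model

`lmsrgc` compresses a target genome relative to a reference genome by exact
substring matching. The underlying assumption is biological: two assemblies
of the same species are near-identical over long stretches, separated by
sparse substitutions, short indels and occasional rearrangements, some of
them strand-inverted. Exact matching against the reference concatenated
with its own reverse complement captures both strands without alignment or
strand flags: a match whose start position falls beyond the cleaned
reference length simply addresses the reverse-complement half, and the
decoder rebuilds the identical extended reference from the reference FASTA
alone.

For a target position `p`, the longest matched substring (LMS) is the
longest prefix of the target suffix at `p` occurring anywhere in the
extended reference — the maximal exact match anchored at `p`. All LMSs are
computed simultaneously from the suffix array and LCP array of
`S = T ++ '$' ++ R'`:
for a rank `i` holding a target-origin suffix, with `rp1`/`rp2` the nearest
reference-origin ranks below/above,

    plcp_len = min(LCP[rp1+1 .. i]),  nlcp_len = min(LCP[i+1 .. rp2]),
    lms_len = max(plcp_len, nlcp_len).

This is correct because in a suffix array the longest common prefix of two
suffixes is the minimum LCP over the ranks between them, and the common
prefix length is unimodal around rank `i`: the nearest reference neighbor
on each side realises the side's maximum. The '$' separator sorts before
A,C,G,T and guarantees matches never run past the end of the target.

## Algorithms and numerical choices

- **Suffix array**: vectorised prefix doubling (O(n log² n) with numpy
  sorts). Any correct construction would do; equivalence with a
  sort-all-suffixes oracle is asserted in tests over random inputs, and the
  worked 19-character example is pinned row by row.
- **LCP array**: Kasai's linear algorithm; `LCP[0] = -1` sentinel marks the
  undefined entry (distinct from a true 0).
- **Alphabet order**: `'$' < 'A' < 'C' < 'G' < 'T'` (byte order); no
  terminator beyond the single '$'.
- **Scan**: two O(n) sweeps maintain the running minimum LCP since the last
  reference-origin rank. When `plcp_len == nlcp_len` the following
  (`rp2`) neighbor supplies the match position; the separator rank counts
  as neither origin. Records store the reference start as
  `SA[rp] - tarlength`, 1-based inside the extended reference (the '$' at
  offset `tarlength` shifts by one); all other coordinates are 0-based
  half-open, and the codec converts once.
- **Filtering**: a record whose target interval ends at or before the
  running maximum end of retained records is contained and dropped, as are
  records shorter than `kmerlength`. Overlap resolution is greedy
  longest-first with truncation (a mid-split keeps the single longest
  uncovered piece, leftmost on a tie); ties on length break by smaller
  target start, then smaller reference start — distinct candidates can
  truncate down to the same target interval, and the third key makes the
  outcome independent of processing order. The production path uses a lazy
  max-heap that replays truncations in recording order; tests assert it is
  output-identical to the literal re-sort-every-round loop.
- **Encoding**: the first match stores its absolute 0-based extended-
  reference position; later matches store
  `delta = cur_ref - (prev_ref + prev_len)`, which is 0 for consecutive
  matches and makes the omission rule (`delta ==` length of the intervening
  literal, including the zero-length case) exactly the condition that the
  mismatched letters on both sequences count equally. A letterwise
  replacement run is clamped to the length of the match it replaces so the
  final cover stays disjoint. The serialized form is line-based — match
  lines `pos,len` (bare `,len` when omitted), literal lines in lowercase —
  because a separator-free stream is ambiguous when two matches are
  adjacent.
- **Degenerate inputs**: an empty target or reference after cleaning is an
  error; a target with no match ≥ `kmerlength` encodes as a single literal;
  a single-record FASTA with unwrapped sequence has `line_width = 0`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `kmerlength` | 21 | minimum match length kept (bases). Matches shorter than a `pos,len` token cost more than they save; 21 is a customary MEM seed length. |
| `distance_threshold` | 1000 | delta magnitude (bases) above which a letterwise continuation of the previous match is attempted. |
| `letterwise_fraction` | 0.9 | fraction of the match length the letterwise run must reach to replace it. |
| backend | `bz2` | entropy coder for the token stream (`store`, `zlib`, `bz2`, `lzma`); `bz2` is block-sorting, in the same family as dedicated BWT compressors. |

Lossless round-tripping holds for any parameter values; the parameters only
trade archive size against work.

## Losslessness bookkeeping

Lowercase runs and non-ACGT runs of the *target* are recorded against
original coordinates before cleaning (restoration reinserts ambiguity
letters, then re-lowercases, so a lowercase `n` round-trips). The
*reference* is cleaned without bookkeeping — decoding only needs the same
reference FASTA, whose cleaned-sequence SHA-256 is stored in the archive
and checked before decoding. Per-record header, wrap width and the file's
trailing-newline convention are stored so the output is byte-identical.
Multi-record targets are compressed record by record against the whole
extended reference; a multi-record reference is concatenated into one
sequence before extension.

## Synthetic data

The generator emulates an intra-species genome pair: uniform random ACGT
reference; per-base substitutions (`snp_rate`) and indels (`indel_rate`,
geometric lengths, mean 3); reverse-complemented reference segments spliced
in to exercise the opposite-strand half; lowercase runs (soft-masking) and
`N` runs (assembly gaps) overlaid last. It is a pure function of its seed.
It does not model repeat families, segmental duplications, GC skew or
chromosome-scale rearrangements, so passing tests demonstrate correctness
of the machinery (losslessness, maximality of matches, determinism) rather
than the compression ratios achievable on real genomes.

## Problem sizes in the test suite

Oracle-equivalence suites run 1000 random pairs up to 500 bp each (the
brute-force per-position oracle is a quadratic longest-common-extension
dynamic program, kept independent of the suffix-array path). Round-trip
suites cover reference lengths 100–10⁴ across substitution rates
{0, 10⁻³, 10⁻²} and wrap widths {0, 60, 80}, plus one 10⁵-base
multi-record case with every mutation and decoration feature enabled.
Segmented-construction contracts are checked for 1, 2, 3 and 7 parts.

## Limitations

- The whole concatenation is indexed in memory; human-chromosome inputs are
  feasible but the constant factors of the pure-Python scan make multi-
  megabase inputs minutes-scale. The segmentation plans define how the LCP
  and scan stages parallelise (output equality with the serial path is the
  contract); the default execution is serial.
- Only the anchored-maximality coordinate (one LMS per target position) is
  used; inter-genome or second-order matching across previously compressed
  genomes is out of scope.
- Compression ratios depend on the entropy backend; no claim of byte-level
  parity with any particular external compressor is made.
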