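# Methods

This note records the models, conventions and numerical choices behind
`dnastore`, and what the synthetic channel does and does not capture.

## Codec

**Symbol packing.** Bytes are split MSB-first into 2-bit pairs (byte `b` →
`b[7:6], b[5:4], b[3:2], b[1:0]`), so `H` = 0x48 = 01001000 → symbols
(1,0,2,0). The inverse packing is exact.

**Layout of the 26 data symbols.** 20 message symbols followed by 6 hash
symbols. The hash is SHA-256 over the 5 raw message bytes; the digest is
read as a big-endian 256-bit integer and its 12 least-significant bits are
emitted as six 2-bit symbols, most-significant pair first. Trailing
placement keeps the message contiguous; nothing in the code depends on the
placement beyond encoder/decoder agreement.

**Code construction.** `CodeSpec.standard()` builds G = (I | −Aᵀ) and
H = (A | I) from the fixed 5×26 binary template A and verifies at
construction, by brute force, that H·Gᵀ ≡ 0 (mod 4), that the 31 columns of
H are the distinct nonzero binary 5-vectors, and that the 93 single-error
syndromes m·hᵢ (i ∈ 1..31, m ∈ {1,2,3}) are nonzero and pairwise distinct.
Because the columns of H are binary, syndromes of different magnitude
classes take values in disjoint symbol sets ({0,1}, {0,2}, {0,3}); a
collision is impossible, and the constructor treats one as a fatal error
rather than tie-breaking.

**Decision table.** After pad removal, with syndrome s and checksum
discrepancy d = Σrᵢ mod 4:

| s | d | action |
|---|---|--------|
| 0 | 0 | accept as-is |
| 0 | ≠0 | error confined to the checksum base; accept data, count as corrected |
| ≠0 | 0 | double-error signature → uncorrectable |
| ≠0 | ≠0 | unique syndrome hit (i, m): if m = d subtract m at i; if m ≠ d the corrected word would still violate the checksum → checksum-invalid; no hit → uncorrectable |

Accepted words are finally gated on the embedded hash. A hash mismatch
withholds the bytes (corrected-hash-fail); this bucket also absorbs the
only-theoretically-reachable case of a clean-looking codeword with a wrong
hash (≥3 errors that land on another codeword), which the hash gate treats
identically. When a ground-truth message is supplied, accepted bytes that
differ from it are flagged wrong-message.

Exhaustive enumeration (4464 double corruptions of the "HELLO" word) is
kept as a first-class operation because the binary extended-Hamming
argument for "detects all double errors" does not transfer wholesale to
mod-4 magnitudes; the enumerator reports the true partition rather than
assuming the claim, and the test suite checks it case-by-case against a
brute-force oracle that re-derives every category without the lookup table.

**One-time pad.** The printed pads are 32 symbols long, which only matches
the finished codeword+checksum, so the default (`otp_stage="word"`) adds
the pad to the full 32-symbol word and removes it first in decoding — valid
because the code is linear. The alternative reading (pad added to the 26
data symbols before encoding) is implemented as `otp_stage="data"`.

## Constructs

The hairpin geometry — 4-base overhang, 32+P-base stem (coded region plus
padding), 5-base poly-T loop, complementary return stem — is reconstructed
from its two printed totals: 73 + 2P gives 99 bases at P=13 and 89 at P=8,
and a loop of 5 is the unique length satisfying both together with a 40-base
payload span at P=8. Padding bases are drawn from {A, C, G} so no spurious
poly-T run can mimic the loop. The adapter's extension segment is a seeded
uniform-random 1000-mer (a synthetic stand-in for a PCR-amplified genomic
fragment; the algorithms are indifferent to its origin), with sticky end
GCGT whose reverse complement ACGC is the hairpin overhang and, after
ligation, the scar on the read strand.

Scar-anchored coordinates are half-open and 0-based: position 0 is the
first coded base, the scar occupies −4..−1. This resolves the ambiguity
between overlapping "−3 to 0" / "0 to 39" span descriptions by decision in
favour of non-overlapping spans.

## Channel model

Errors are independent per-base Bernoulli events: deletion (default rate
0.015), substitution to a uniformly chosen different base (0.005), and
insertion of a uniform base after the position (0.001), matching a channel
characterised as "almost zero insertions, <1% substitutions, 1–2%
deletions"; the insertion default is a choice, since only "almost zero" is
characterised. Deletion probability ramps linearly across the payload to
`del_ramp` × (default 2×) at its 5′-most base, emulating the
steric-hindrance trend of column synthesis. The read population is a
mixture of adapter-only molecules (failed ligation, probability
1 − `ligation_rate`, default ligation 0.08), 1D payload traversals and 2D
traversals of the full hairpin (default 50/50 among ligated reads). Reads
stop prematurely from the 3′ end with geometric stopping, mean retained
length 1100 bases, which reproduces the loss of sub-kilobase molecules as a
filterable length phenomenon.

Not modelled: raw nanopore signal and k-mer-context error structure,
base-caller quality scores (a constant placeholder is emitted; the decoder
never reads them), reverse-complement read orientation, PCR bias, and
chimeric reads. Passing tests therefore demonstrate correctness of the
codec and decoder logic under a calibrated independent-error channel, not
performance on real nanopore data, whose errors are burstier and
context-dependent.

## Alignment

Semi-global affine-gap alignment, global in the read with free leading and
trailing reference gaps — the right shape for locating a (possibly
truncated) read along the longer construct reference. Scoring follows
NUC.4.4 values for ACGT (match +5, mismatch −4; N is scored −2 against
everything) with a length-L gap costing open + (L−1)·extend, open 8,
extend 4 — one of the two common readings of those penalty flags, fixed and
documented so scores are reproducible within this artifact (hand-checkable
anchors: 100 identical bases → 500, one substitution → 491, one deleted
base → 487). Traceback ties prefer diagonal, then a gap in the reference,
then a gap in the read, making alignments deterministic; the reported score
always equals the score recomputed from the traceback.

Payload extraction gates each read on (1) a minimum aligned reference span
of 20 bases (8 for profiling — the two minimum-length filters of the
original alignment workflow), (2) an adapter-window score > 400 over
scar-anchored positions −100..−1, a threshold calibrated to this scoring
convention, and (3) the strict length gate: exactly 32 read bases aligned
to the coded region with no interior indels (`indel_tolerance` is
configurable but defaults to strict, consistent with the very low
extractable-payload yield such a gate produces). A gap run clipped by the
scoring window is charged a fresh gap-open at its first in-window column.

The per-locus profiler classifies every traceback column as
match/substitution/deletion (reference-consuming) or insertion (counted at
the preceding reference position), so match + substitution + deletion
counts equal coverage at every position.

## Pipeline

Reads are decoded in batches (default 4000, the base-calling batch size of
the original instrument workflow). The funnel — total → adapter-aligned →
payload-extracted → decode categories — is conserved by construction and
checked by `FunnelReport.check_conservation()`. Adapter-only reads
typically clear the adapter window (their trailing reference gap is free)
but fail the length gate, so they count as aligned, mirroring the large
aligned-but-unextractable population seen in practice. Early termination
stops at the first read whose bytes pass the hash gate; exhaustive mode
decodes everything and must agree on the recovered message.

## Problem sizes and determinism

Every stochastic entry point takes an explicit seed and is deterministic
given it (byte-identical FASTQ/truth output). The test suite runs the
double-error enumeration exhaustively (4464 cases), checks the aligner
against an independent naive DP on 200 random pairs, profiles 10,000
simulated reads of a 160-base reference for rate recovery, and runs the
integration decode on 4000 full-construct reads — sizes chosen so the whole
suite completes in well under a minute on one CPU while keeping binomial
error bars tight enough for 3σ assertions.

## Known limitations

- The (31, 26)+checksum code is fixed; other sizes would require a new
  parity template (the matrix-driven implementation generalises, but no
  other template ships).
- Single-oligo payloads only: no multi-oligo files, addressing, or random
  access.
- The absolute alignment-score threshold (400) is meaningful only under
  this package's gap convention.
- The channel simulator's independence assumptions understate real nanopore
  error correlation; funnel proportions from simulation should not be read
  as predictions of wet-lab yield.
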