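"""Semi-global affine-gap alignment, payload extraction, per-locus profiling.

Alignment is semi-global in the sense used for locating a noisy read along a
longer construct reference: the read must be aligned end to end, while
unaligned reference flanks (leading and trailing) are free. Scoring follows
the NUC.4.4 nucleotide matrix (match +5, mismatch -4, N scored -2 against
everything) with affine gaps costing ``open + (L-1) * extend`` for a gap of
length ``L`` (open 8, extend 4). Traceback ties prefer diagonal, then a gap
in the reference, then a gap in the read, so alignments are deterministic.

The payload extractor gates a read on (i) a minimum aligned reference span,
(ii) the adapter-window score over scar-anchored positions -100..-1, and
(iii) a strict length gate: exactly 32 read bases aligned to the coded
region with no interior indels. The profiler aggregates traceback columns
into per-position insertion / deletion / substitution frequencies in
scar-anchored coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np
import pandas as pd

from .constructs import ReadReference

__all__ = [
    "AlignmentResult",
    "Column",
    "ErrorProfile",
    "PayloadResult",
    "ScoringScheme",
    "error_profile",
    "locate_payload",
    "semiglobal_align",
]

_NEG = np.int32(-(10**8))
_IDX = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _IDX[_b] = _i
    _IDX[_b + 32] = _i  # lower case


@dataclass(frozen=True)
class ScoringScheme:
    """NUC.4.4-style scoring with affine gap penalties (positive costs)."""

    match: int = 5
    mismatch: int = -4
    ambiguous: int = -2  # N against anything
    gap_open: int = 8
    gap_extend: int = 4
    adapter_window: int = 100  # scar-anchored window -window..-1
    adapter_score_threshold: int = 400
    min_span_decode: int = 20  # minimum aligned reference span, decoding
    min_span_profile: int = 8  # minimum aligned reference span, profiling

    def matrix(self) -> np.ndarray:
        m = np.full((5, 5), self.mismatch, dtype=np.int32)
        np.fill_diagonal(m, self.match)
        m[4, :] = self.ambiguous
        m[:, 4] = self.ambiguous
        return m


@dataclass(frozen=True)
class Column:
    """One traceback column: kind 'M' (diagonal), 'I' (insertion: read base
    with no reference partner, anchored at the preceding reference position)
    or 'D' (deletion: reference base skipped inside the read)."""

    kind: str
    ref_pos: int | None
    read_pos: int | None


@dataclass
class AlignmentResult:
    score: int
    columns: list[Column]
    read: str
    reference: str
    ref_start: int  # first reference position consumed (-1 if none)
    ref_end: int  # last reference position consumed (-1 if none)

    @property
    def aligned_span(self) -> int:
        return 0 if self.ref_start < 0 else self.ref_end - self.ref_start + 1

    def recompute_score(self, scheme: ScoringScheme) -> int:
        """Re-derive the score from the traceback (exact; used as invariant)."""
        return self._score_columns(self.columns, scheme)

    def score_in_window(self, lo: int, hi: int, scheme: ScoringScheme) -> int:
        """Score restricted to columns anchored at reference positions [lo, hi].

        A gap run clipped by the window boundary is charged a fresh open at
        its first in-window column.
        """
        cols = [c for c in self.columns if c.ref_pos is not None and lo <= c.ref_pos <= hi]
        return self._score_columns(cols, scheme)

    def _score_columns(self, cols, scheme: ScoringScheme) -> int:
        mat = scheme.matrix()
        score = 0
        prev_kind = "M"
        for c in cols:
            if c.kind == "M":
                score += int(mat[_IDX[ord(self.read[c.read_pos])], _IDX[ord(self.reference[c.ref_pos])]])
            else:
                if c.kind == prev_kind:
                    score -= scheme.gap_extend
                else:
                    score -= scheme.gap_open
            prev_kind = c.kind
        return score


@numba.njit(cache=True)
def _sg_fill(q, r, mat, gap_open, gap_ext):  # pragma: no cover - numba kernel
    m, n = q.shape[0], r.shape[0]
    NEG = _NEG
    # states: 0 = M (diagonal), 1 = X (gap in reference, consumes read),
    #         2 = Y (gap in read, consumes reference)
    ptr = np.zeros((3, m + 1, n + 1), dtype=np.uint8)
    prevM = np.zeros(n + 1, dtype=np.int32)  # row 0: leading reference skip free
    prevX = np.full(n + 1, NEG, dtype=np.int32)
    prevY = np.full(n + 1, NEG, dtype=np.int32)
    curM = np.empty(n + 1, dtype=np.int32)
    curX = np.empty(n + 1, dtype=np.int32)
    curY = np.empty(n + 1, dtype=np.int32)
    for i in range(1, m + 1):
        curM[0] = NEG
        a = prevM[0] - gap_open
        b = prevX[0] - gap_ext
        c = prevY[0] - gap_open
        best, st = a, 0
        if b > best:
            best, st = b, 1
        if c > best:
            best, st = c, 2
        curX[0] = best
        ptr[1, i, 0] = st
        curY[0] = NEG
        qi = q[i - 1]
        for j in range(1, n + 1):
            # M from (i-1, j-1)
            a, b, c = prevM[j - 1], prevX[j - 1], prevY[j - 1]
            best, st = a, 0
            if b > best:
                best, st = b, 1
            if c > best:
                best, st = c, 2
            curM[j] = best + mat[qi, r[j - 1]]
            ptr[0, i, j] = st
            # X from (i-1, j)
            a = prevM[j] - gap_open
            b = prevX[j] - gap_ext
            c = prevY[j] - gap_open
            best, st = a, 0
            if b > best:
                best, st = b, 1
            if c > best:
                best, st = c, 2
            curX[j] = best
            ptr[1, i, j] = st
            # Y from (i, j-1)
            a = curM[j - 1] - gap_open
            b = curX[j - 1] - gap_open
            c = curY[j - 1] - gap_ext
            best, st = a, 0
            if b > best:
                best, st = b, 1
            if c > best:
                best, st = c, 2
            curY[j] = best
            ptr[2, i, j] = st
        prevM, curM = curM, prevM
        prevX, curX = curX, prevX
        prevY, curY = curY, prevY
    # trailing reference skip free: best over j and states, prefer M > X > Y
    # then the smallest j (first maximum encountered)
    best = NEG
    end_j = 0
    end_st = 0
    for j in range(n + 1):
        for st in range(3):
            v = prevM[j] if st == 0 else (prevX[j] if st == 1 else prevY[j])
            if v > best:
                best, end_j, end_st = v, j, st
    return best, end_j, end_st, ptr


def _encode(seq: str) -> np.ndarray:
    return _IDX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def semiglobal_align(read: str, reference: str, scheme: ScoringScheme | None = None) -> AlignmentResult:
    """Optimal semi-global alignment of ``read`` against ``reference``."""
    scheme = scheme or ScoringScheme()
    if not read or not reference:
        raise ValueError("read and reference must be non-empty")
    q = _encode(read)
    r = _encode(reference)
    score, end_j, end_st, ptr = _sg_fill(q, r, scheme.matrix(), scheme.gap_open, scheme.gap_extend)

    columns: list[Column] = []
    i, j, st = len(read), int(end_j), int(end_st)
    while i > 0:
        if st == 0:
            columns.append(Column("M", j - 1, i - 1))
            st = int(ptr[0, i, j])
            i, j = i - 1, j - 1
        elif st == 1:
            columns.append(Column("I", j - 1 if j > 0 else None, i - 1))
            st = int(ptr[1, i, j])
            i -= 1
        else:
            columns.append(Column("D", j - 1, None))
            st = int(ptr[2, i, j])
            j -= 1
    columns.reverse()
    consumed = [c.ref_pos for c in columns if c.kind != "I" and c.ref_pos is not None]
    return AlignmentResult(
        score=int(score),
        columns=columns,
        read=read,
        reference=reference,
        ref_start=consumed[0] if consumed else -1,
        ref_end=consumed[-1] if consumed else -1,
    )


@dataclass(frozen=True)
class PayloadResult:
    """Outcome of payload extraction: 32 symbols, or a rejection reason."""

    status: str  # "OK" | "NO_ADAPTER" | "BAD_LENGTH"
    symbols: np.ndarray | None = None
    alignment: AlignmentResult | None = None

    @property
    def ok(self) -> bool:
        return self.status == "OK"


def locate_payload(
    read: str,
    reference: ReadReference,
    scheme: ScoringScheme | None = None,
    expected_len: int = 32,
    indel_tolerance: int = 0,
) -> PayloadResult:
    """Align a read and extract the coded region under the length gate.

    NO_ADAPTER: the aligned reference span is below the decoding minimum or
    the adapter-window score (scar-anchored -100..-1) does not clear the
    threshold. BAD_LENGTH: fewer or more than ``expected_len`` read bases
    align to the coded region, or interior indels exceed
    ``indel_tolerance`` (strict 0 by default — the "correct length" gate).
    """
    scheme = scheme or ScoringScheme()
    aln = semiglobal_align(read, reference.sequence, scheme)
    if aln.aligned_span < scheme.min_span_decode:
        return PayloadResult("NO_ADAPTER", alignment=aln)
    off = reference.payload_offset
    wscore = aln.score_in_window(off - scheme.adapter_window, off - 1, scheme)
    if wscore <= scheme.adapter_score_threshold:
        return PayloadResult("NO_ADAPTER", alignment=aln)

    lo, hi = off, off + expected_len - 1
    read_bases: list[str] = []
    indels = 0
    for c in aln.columns:
        if c.ref_pos is None or not lo <= c.ref_pos <= hi:
            continue
        if c.kind == "M":
            read_bases.append(read[c.read_pos])
        elif c.kind == "D":
            indels += 1
        elif c.kind == "I" and c.ref_pos < hi:  # interior insertion only
            indels += 1
    if len(read_bases) != expected_len or indels > indel_tolerance:
        return PayloadResult("BAD_LENGTH", alignment=aln)
    from .constructs import bases_to_symbols

    try:
        symbols = bases_to_symbols("".join(read_bases))
    except ValueError:
        return PayloadResult("BAD_LENGTH", alignment=aln)
    return PayloadResult("OK", symbols=symbols, alignment=aln)


@dataclass
class ErrorProfile:
    """Per-locus error frequencies in scar-anchored coordinates."""

    table: pd.DataFrame
    n_reads_used: int = 0

    def mean_freq(self, kind: str, lo: int, hi: int) -> float:
        """Coverage-weighted mean frequency of ``kind`` over positions [lo, hi]."""
        t = self.table
        sel = t[(t["position"] >= lo) & (t["position"] <= hi) & (t["coverage"] > 0)]
        if sel.empty:
            return float("nan")
        return float(sel[kind].sum() / sel["coverage"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def error_profile(
    reads,
    reference: ReadReference,
    scheme: ScoringScheme | None = None,
) -> ErrorProfile:
    """Aggregate traceback columns of many reads into per-locus frequencies.

    ``reads`` yields sequences, (name, sequence) pairs, or objects with a
    ``sequence`` attribute. Reads aligning fewer than ``min_span_profile``
    reference bases are excluded. At each reference-consuming position,
    match + substitution + deletion counts equal coverage; insertions are
    counted at the preceding reference position.
    """
    scheme = scheme or ScoringScheme()
    n = len(reference.sequence)
    counts = {k: np.zeros(n, dtype=np.int64) for k in ("matches", "subs", "dels", "ins")}
    used = 0
    for item in reads:
        seq = getattr(item, "sequence", None)
        if seq is None:
            seq = item[1] if isinstance(item, tuple) else str(item)
        if not seq:
            continue
        aln = semiglobal_align(seq, reference.sequence, scheme)
        if aln.aligned_span < scheme.min_span_profile:
            continue
        used += 1
        for c in aln.columns:
            if c.kind == "M":
                same = seq[c.read_pos].upper() == reference.sequence[c.ref_pos].upper()
                counts["matches" if same else "subs"][c.ref_pos] += 1
            elif c.kind == "D":
                counts["dels"][c.ref_pos] += 1
            elif c.ref_pos is not None:
                counts["ins"][c.ref_pos] += 1

    coverage = counts["matches"] + counts["subs"] + counts["dels"]
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = {
            k: np.where(coverage > 0, counts[k] / np.maximum(coverage, 1), 0.0)
            for k in ("matches", "subs", "dels", "ins")
        }
    table = pd.DataFrame(
        {
            "position": np.arange(n) - reference.payload_offset,
            "coverage": coverage,
            "matches": counts["matches"],
            "subs": counts["subs"],
            "dels": counts["dels"],
            "ins": counts["ins"],
            "match_freq": freq["matches"],
            "sub_freq": freq["subs"],
            "del_freq": freq["dels"],
            "ins_freq": freq["ins"],
        }
    )
    return ErrorProfile(table=table, n_reads_used=used)
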