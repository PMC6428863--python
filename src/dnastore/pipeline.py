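"""Batch decoding with funnel accounting and early termination.

Reads flow through a funnel: total -> adapter-aligned -> payload-extracted
-> decode category. Decoding runs in batches (default 4000 reads, the
base-calling batch size of the original instrument workflow) and, unless
exhaustive mode is requested, stops at the first read whose decoded bytes
pass the embedded hash gate — the point at which a live run would stop
sequencing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import islice

from . import codec
from .align import ScoringScheme, locate_payload
from .codec import ACCEPTED, CodeSpec, DecodeCategory
from .constructs import ReadReference

__all__ = ["DecodeContext", "FunnelReport", "iter_fastq", "process_batch", "run_decode"]


@dataclass
class FunnelReport:
    """Staged read accounting. Category counts partition the extracted reads."""

    total_reads: int = 0
    adapter_aligned: int = 0
    payload_extracted: int = 0
    categories: dict = field(
        default_factory=lambda: {c.value: 0 for c in DecodeCategory}
    )
    terminated_early: bool = False
    recovered_message: bytes | None = None

    def check_conservation(self) -> None:
        if sum(self.categories.values()) != self.payload_extracted:
            raise AssertionError("decode categories do not sum to payload_extracted")
        if not (self.payload_extracted <= self.adapter_aligned <= self.total_reads):
            raise AssertionError("funnel stages are not non-increasing")

    def to_dict(self) -> dict:
        msg = self.recovered_message
        return {
            "total_reads": self.total_reads,
            "adapter_aligned": self.adapter_aligned,
            "payload_extracted": self.payload_extracted,
            "categories": dict(self.categories),
            "terminated_early": self.terminated_early,
            "recovered_message_hex": msg.hex() if msg is not None else None,
            "recovered_message_text": (
                msg.decode("ascii", errors="replace") if msg is not None else None
            ),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class DecodeContext:
    """Everything a batch needs: reference, scoring, code and pad selection."""

    reference: ReadReference
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    spec: CodeSpec | None = None
    pad: str = "X1"
    otp_stage: str = "word"
    truth: bytes | None = None


def iter_fastq(path, on_error=None):
    """Yield (name, sequence) from a FASTQ file, skipping malformed records.

    A record with a bad header, a missing plus line, or a length mismatch
    between sequence and quality is skipped; ``on_error`` (if given) receives
    a message identifying the record and line number.
    """
    with open(path) as fh:
        lineno = 0
        while True:
            lines = [fh.readline() for _ in range(4)]
            if not lines[0]:
                return
            lineno += 4
            header, seq, plus, qual = (ln.rstrip("\n") for ln in lines)
            name = header[1:].split()[0] if header.startswith("@") and len(header) > 1 else None
            if (
                name is None
                or not plus.startswith("+")
                or not seq
                or len(seq) != len(qual)
            ):
                if on_error is not None:
                    on_error(f"malformed FASTQ record near line {lineno - 3} ({header[:40]!r})")
                continue
            yield name, seq


def process_batch(records, ctx: DecodeContext, report: FunnelReport, stop_on_accept: bool = False) -> bool:
    """Decode one batch of (name, sequence) records into ``report``.

    Returns True if ``stop_on_accept`` is set and a read passed the hash gate
    (processing stops immediately after that read).
    """
    for _name, seq in records:
        report.total_reads += 1
        result = locate_payload(seq, ctx.reference, ctx.scheme)
        if result.status == "NO_ADAPTER":
            continue
        report.adapter_aligned += 1
        if result.status != "OK":
            continue
        report.payload_extracted += 1
        outcome = codec.decode_word(
            result.symbols, pad=ctx.pad, spec=ctx.spec, truth=ctx.truth, otp_stage=ctx.otp_stage
        )
        report.categories[outcome.category.value] += 1
        if outcome.category in ACCEPTED:
            if report.recovered_message is None:
                report.recovered_message = outcome.message_bytes
            if stop_on_accept:
                return True
    return False


def run_decode(
    reads,
    ctx: DecodeContext,
    batch_size: int = 4000,
    exhaustive: bool = False,
) -> FunnelReport:
    """Consume FASTQ records (a path or an iterable of (name, seq) pairs)
    in batches; stop at the first hash-gate acceptance unless exhaustive."""
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        reads = iter_fastq(reads)
    report = FunnelReport()
    it = iter(reads)
    while True:
        batch = list(islice(it, batch_size))
        if not batch:
            break
        stopped = process_batch(batch, ctx, report, stop_on_accept=not exhaustive)
        if stopped:
            report.terminated_early = True
            break
    return report
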