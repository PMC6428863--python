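"""Write-to-read channel simulator: ligation, read types, errors, truncation.

Stands in for the synthesiser, preparation chemistry and nanopore: each
simulated read is an adapter-only molecule (failed ligation), a 1D traversal
(adapter, scar, payload stem) or a 2D traversal (the full hairpin including
loop and return stem), truncated from the 3' end with a geometric stopping
model and then corrupted by independent per-base substitution / deletion /
insertion events. Deletions ramp up linearly toward the payload's 5' end,
emulating the steric-hindrance trend of column synthesis. Every read
carries a ground-truth edit list from which its sequence is exactly
reconstructible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constructs import AdapterModel, HairpinConstruct, build_read_reference

__all__ = [
    "ChannelParams",
    "Edit",
    "SimulatedRead",
    "corrupt",
    "read_template",
    "replay_edits",
    "sample_read",
    "simulate_run",
]

_BASES = "ACGT"
READ_TYPES = ("unligated", "1d", "2d")


@dataclass(frozen=True)
class ChannelParams:
    """Per-base error rates and read-population model.

    Defaults reflect the characterised channel: near-zero insertions, <1%
    substitutions, 1-2% deletions, apparent ligation below 10%, and a read
    length distribution shaped by premature 3' truncation (mean retained
    length ~1100 bases, so sub-kilobase molecules are frequently lost).
    """

    sub_rate: float = 0.005
    del_rate: float = 0.015
    ins_rate: float = 0.001
    del_ramp: float = 2.0  # deletion multiplier at the 5'-most payload base
    ligation_rate: float = 0.08
    trunc_mean: float = 1100.0  # mean retained read length, geometric stopping
    read_mixture: tuple[float, float] = (0.5, 0.5)  # (1D, 2D) split among ligated

    def __post_init__(self):
        for name in ("sub_rate", "del_rate", "ins_rate", "ligation_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.del_ramp < 1.0:
            raise ValueError("del_ramp must be >= 1 (no relief toward 5')")
        if self.trunc_mean <= 0:
            raise ValueError("trunc_mean must be positive")
        w = self.read_mixture
        if len(w) != 2 or min(w) < 0 or sum(w) <= 0:
            raise ValueError("read_mixture must be two non-negative weights")


@dataclass(frozen=True)
class Edit:
    """One channel event. ``pos`` indexes the (truncated) template.

    kind 's': template base at pos read as ``base``;
    kind 'd': template base at pos dropped;
    kind 'i': ``base`` inserted after template position pos (-1 = before start).
    """

    kind: str
    pos: int
    base: str = ""

    def encode(self) -> str:
        return f"{self.kind}{self.pos}" + (f">{self.base}" if self.base else "")

    @classmethod
    def decode(cls, text: str) -> "Edit":
        kind, rest = text[0], text[1:]
        pos, _, base = rest.partition(">")
        return cls(kind, int(pos), base)


@dataclass(frozen=True)
class SimulatedRead:
    name: str
    sequence: str
    quality: str
    read_type: str
    template_len: int  # untruncated template length
    trunc_len: int  # retained template prefix length
    edits: tuple[Edit, ...] = field(default_factory=tuple)


def replay_edits(template: str, edits) -> str:
    """Reconstruct a read from its truncated template and edit list."""
    out = []
    ins: dict[int, list[str]] = {}
    skip = set()
    sub: dict[int, str] = {}
    for e in edits:
        if e.kind == "i":
            ins.setdefault(e.pos, []).append(e.base)
        elif e.kind == "d":
            skip.add(e.pos)
        elif e.kind == "s":
            sub[e.pos] = e.base
        else:
            raise ValueError(f"unknown edit kind {e.kind!r}")
    out.extend(ins.get(-1, []))
    for i, b in enumerate(template):
        if i not in skip:
            out.append(sub.get(i, b))
        out.extend(ins.get(i, []))
    return "".join(out)


def _ramp(params: ChannelParams, pos: int, payload_span: tuple[int, int] | None) -> float:
    if payload_span is None or params.del_ramp == 1.0:
        return 1.0
    lo, hi = payload_span
    if not lo <= pos < hi or hi - lo <= 1:
        return 1.0
    # linear: del_ramp at the 5'-most payload base (lo), 1.0 at the 3'-most
    frac = (pos - lo) / (hi - 1 - lo)
    return params.del_ramp + (1.0 - params.del_ramp) * frac


def corrupt(
    reference: str,
    params: ChannelParams,
    rng: np.random.Generator,
    payload_span: tuple[int, int] | None = None,
    name: str = "read",
    read_type: str = "fragment",
) -> SimulatedRead:
    """Apply independent per-base channel events to ``reference``.

    Per position: deletion with ``del_rate * ramp(pos)``, else substitution to
    a uniformly chosen different base with ``sub_rate``; independently, a
    uniform base is inserted after the position with ``ins_rate`` (and before
    the first position with the same rate).
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    edits: list[Edit] = []
    if rng.random() < params.ins_rate:
        edits.append(Edit("i", -1, _BASES[rng.integers(4)]))
    for i, b in enumerate(reference):
        if rng.random() < min(1.0, params.del_rate * _ramp(params, i, payload_span)):
            edits.append(Edit("d", i))
        elif rng.random() < params.sub_rate:
            choices = _BASES.replace(b, "") if b in _BASES else _BASES
            edits.append(Edit("s", i, choices[rng.integers(len(choices))]))
        if rng.random() < params.ins_rate:
            edits.append(Edit("i", i, _BASES[rng.integers(4)]))
    seq = replay_edits(reference, edits)
    return SimulatedRead(
        name=name,
        sequence=seq,
        quality="I" * len(seq),
        read_type=read_type,
        template_len=len(reference),
        trunc_len=len(reference),
        edits=tuple(edits),
    )


def read_template(
    adapter: AdapterModel, hairpin: HairpinConstruct, read_type: str
) -> tuple[str, tuple[int, int]]:
    """Untruncated template for a read type, plus its payload span.

    unligated: extension only; 1d: extension + scar + coded region + padding
    (inbound stem); 2d: the full ligated construct including loop and return
    stem. The payload span (absolute, half-open) covers coded region +
    padding, or is degenerate for unligated reads.
    """
    ref = build_read_reference(adapter, hairpin)
    lo = ref.payload_offset
    hi = lo + ref.payload_len
    if read_type == "unligated":
        return adapter.extension, (0, 0)
    if read_type == "1d":
        return ref.sequence[:hi], (lo, hi)
    if read_type == "2d":
        return ref.sequence, (lo, hi)
    raise ValueError(f"unknown read type {read_type!r}; expected one of {READ_TYPES}")


def sample_read(
    adapter: AdapterModel,
    hairpin: HairpinConstruct,
    params: ChannelParams,
    rng: np.random.Generator,
    name: str = "read",
) -> SimulatedRead:
    """Draw one read: type mixture, 3' geometric truncation, then errors."""
    if rng.random() >= params.ligation_rate:
        read_type = "unligated"
    else:
        w1, w2 = params.read_mixture
        read_type = "1d" if rng.random() < w1 / (w1 + w2) else "2d"
    template, span = read_template(adapter, hairpin, read_type)
    # geometric stopping from the 3' end: retained length ~ Geom(1/mean)
    keep = max(1, min(len(template), int(rng.geometric(1.0 / params.trunc_mean))))
    truncated = template[:keep]
    span = (min(span[0], keep), min(span[1], keep))
    if span[1] - span[0] <= 0:
        span = None
    read = corrupt(truncated, params, rng, payload_span=span, name=name, read_type=read_type)
    return replace(read, template_len=len(template), trunc_len=keep)


def simulate_run(
    n_reads: int,
    adapter: AdapterModel,
    hairpin: HairpinConstruct,
    params: ChannelParams,
    seed: int,
    fastq_path=None,
    truth_path=None,
) -> list[SimulatedRead]:
    """Simulate ``n_reads`` reads; optionally write FASTQ + TSV truth table.

    Deterministic given ``seed``: identical inputs produce byte-identical
    output files. Quality scores are a constant placeholder (the decoder
    never consults them).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    rng = np.random.default_rng(seed)
    width = len(str(n_reads))
    reads = [
        sample_read(adapter, hairpin, params, rng, name=f"read_{i:0{width}d}")
        for i in range(n_reads)
    ]
    if fastq_path is not None:
        with open(fastq_path, "w") as fh:
            for r in reads:
                fh.write(f"@{r.name} type={r.read_type}\n{r.sequence}\n+\n{r.quality}\n")
    if truth_path is not None:
        with open(truth_path, "w") as fh:
            fh.write("read_id\tread_type\ttemplate_len\ttrunc_len\tn_edits\tedits\n")
            for r in reads:
                ed = ";".join(e.encode() for e in r.edits)
                fh.write(
                    f"{r.name}\t{r.read_type}\t{r.template_len}\t{r.trunc_len}\t"
                    f"{len(r.edits)}\t{ed}\n"
                )
    return reads
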