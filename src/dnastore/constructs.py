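"""Physical sequence designs: payload hairpin, extended adapter, read reference.

The 32-base coded region is synthesised as a single oligo that folds into a
hairpin: a 4-base 5' sticky-end overhang, the coded region, 3' padding, a
poly-T loop, and a return stem that is the reverse complement of coded
region + padding. The sequencing adapter carries a ~1 kb extension segment
so the base caller does not drop the otherwise-too-short payload reads; its
sticky end ligates to the hairpin overhang, and the overhang bases become
the "ligation scar" on the read strand — the coordinate anchor used for
per-locus error profiles (scar at positions -4..-1, coded region starting
at 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import as_z4

__all__ = [
    "AdapterModel",
    "HairpinConstruct",
    "ReadReference",
    "bases_to_symbols",
    "build_adapter",
    "build_hairpin",
    "build_read_reference",
    "read_fasta",
    "revcomp",
    "symbols_to_bases",
    "write_fasta",
]

_BASES = "ACGT"
_SYMBOL_OF = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_STICKY_END = "GCGT"  # adapter bottom-strand 5' overhang
DEFAULT_LOOP_LEN = 5


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def symbols_to_bases(w) -> str:
    """Map symbols to bases: 0->A, 1->C, 2->G, 3->T."""
    return "".join(_BASES[int(x)] for x in as_z4(w))


def bases_to_symbols(seq: str) -> np.ndarray:
    """Inverse of :func:`symbols_to_bases`; rejects non-ACGT characters."""
    try:
        return np.array([_SYMBOL_OF[b] for b in seq.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence") from None


@dataclass(frozen=True)
class HairpinConstruct:
    """Payload hairpin oligo: overhang | coded | padding | loop | return stem.

    Total length is 73 + 2P for padding length P: 99 bases at the end-to-end
    configuration (P=13), 89 at the error-analysis configuration (P=8).
    """

    overhang: str
    coded_region: str
    padding: str
    loop: str
    stem_return: str

    @property
    def full_sequence(self) -> str:
        return self.overhang + self.interior

    @property
    def interior(self) -> str:
        """Everything 3' of the overhang (what follows the scar on a read)."""
        return self.coded_region + self.padding + self.loop + self.stem_return

    def __len__(self) -> int:
        return len(self.full_sequence)


@dataclass(frozen=True)
class AdapterModel:
    """Extended sequencing adapter: 1 kb extension segment + sticky end."""

    extension: str
    sticky_end: str = DEFAULT_STICKY_END

    @property
    def scar(self) -> str:
        """Ligation-junction bases as they appear on the read strand."""
        return revcomp(self.sticky_end)


@dataclass(frozen=True)
class ReadReference:
    """Reference sequence in sequencer traversal order, scar-anchored.

    Position 0 is the first coded base; the scar occupies -4..-1 and the
    extension segment everything before it. ``payload_offset`` converts
    between absolute and scar-anchored coordinates.
    """

    sequence: str
    payload_offset: int
    payload_len: int  # coded region + padding

    def to_scar_anchored(self, abs_pos: int) -> int:
        return abs_pos - self.payload_offset

    def to_absolute(self, rel_pos: int) -> int:
        return rel_pos + self.payload_offset

    def __len__(self) -> int:
        return len(self.sequence)


def build_hairpin(
    word32,
    padding_len: int = 13,
    seed: int = 0,
    loop_len: int = DEFAULT_LOOP_LEN,
    sticky_end: str = DEFAULT_STICKY_END,
) -> HairpinConstruct:
    """Assemble the hairpin for a 32-symbol coded word.

    Padding bases are drawn uniformly from {A, C, G} (no T, so no spurious
    poly-T loop mimic) with a seeded generator; the overhang is the reverse
    complement of the adapter sticky end so the two anneal.
    """
    if padding_len < 0:
        raise ValueError("padding_len must be >= 0")
    coded = symbols_to_bases(as_z4(word32, 32))
    rng = np.random.default_rng(seed)
    padding = "".join(rng.choice(list("ACG"), size=padding_len))
    loop = "T" * loop_len
    stem = coded + padding
    return HairpinConstruct(
        overhang=revcomp(sticky_end),
        coded_region=coded,
        padding=padding,
        loop=loop,
        stem_return=revcomp(stem),
    )


def build_adapter(
    seed: int = 0, length: int = 1000, sticky_end: str = DEFAULT_STICKY_END
) -> AdapterModel:
    """Seeded random extension segment (uniform bases, ~50% GC)."""
    rng = np.random.default_rng(seed)
    extension = "".join(rng.choice(list(_BASES), size=length))
    return AdapterModel(extension=extension, sticky_end=sticky_end)


def build_read_reference(adapter: AdapterModel, hairpin: HairpinConstruct) -> ReadReference:
    """Concatenate adapter and ligated hairpin in read-strand order."""
    if hairpin.overhang != revcomp(adapter.sticky_end):
        raise ValueError(
            f"incompatible sticky ends: hairpin overhang {hairpin.overhang} "
            f"does not anneal to adapter {adapter.sticky_end}"
        )
    sequence = adapter.extension + hairpin.overhang + hairpin.interior
    offset = len(adapter.extension) + len(hairpin.overhang)
    payload_len = len(hairpin.coded_region) + len(hairpin.padding)
    return ReadReference(sequence=sequence, payload_offset=offset, payload_len=payload_len)


def write_fasta(records, path) -> None:
    """Write (name, sequence) pairs or SeqRecords as 60-column multi-FASTA."""
    seqrecords = []
    for rec in records:
        if isinstance(rec, SeqRecord):
            seqrecords.append(rec)
        else:
            name, seq = rec
            seqrecords.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(seqrecords, str(path), "fasta")


def read_fasta(path) -> list[SeqRecord]:
    """Read multi-FASTA; malformed leading content is reported with its line."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(f"{path}: line {lineno}: expected '>' header, got {line.strip()!r}")
            break
    return list(SeqIO.parse(str(path), "fasta"))
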