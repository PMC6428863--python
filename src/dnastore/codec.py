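"""Byte <-> quaternary-symbol codec with mod-4 Hamming error correction.

Five bytes of user data are stored in 32 DNA bases: 20 message symbols and
6 hash symbols form the 26 data symbols of a systematic (31, 26) Hamming
code over Z4 (A=0, C=1, G=2, T=3); a 32nd checksum symbol makes the word
sum to zero mod 4, extending single-error correction with double-error
detection (the SECDED pattern). A fixed one-time pad is added mod 4 to
whiten base composition.

Arithmetic is elementwise mod 4 throughout. The generator matrix is
``G = (I | -A^T)`` and the parity-check matrix ``H = (A | I)``, where the
columns of ``H``, read as binary 5-vectors, are the 31 distinct nonzero
5-bit patterns — the property that makes every single-symbol error produce
a unique syndrome.
"""

from __future__ import annotations

import enum
import hashlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CodeSpec",
    "DecodeCategory",
    "DecodeOutcome",
    "PADS",
    "PaddedWord",
    "append_checksum",
    "apply_otp",
    "as_z4",
    "bytes_to_symbols",
    "compute_hash_symbols",
    "decode_word",
    "encode_message",
    "enumerate_double_errors",
    "hamming_encode",
    "remove_otp",
    "symbols_to_bytes",
]

# 5x26 parity template: columns are the 26 binary 5-vectors of weight >= 2,
# completing the identity columns of H to all 31 nonzero 5-bit patterns.
_A_ROWS = [
    [1, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1],
    [1, 0, 1, 1, 0, 1, 1, 0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 1],
    [0, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1],
    [0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1],
    [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1],
]

#: Named one-time pads (length 32, symbols in Z4). ``X1`` was used for the
#: end-to-end run, ``X2`` for the error-characterisation run; ``none`` disables
#: whitening.
PADS: dict[str, np.ndarray] = {
    "X1": np.array(
        [1, 3, 0, 1, 0, 1, 1, 0, 3, 2, 2, 2, 1, 1, 3, 1,
         0, 2, 2, 2, 3, 2, 2, 2, 1, 1, 3, 2, 1, 3, 0, 0], dtype=np.uint8
    ),
    "X2": np.array(
        [3, 1, 1, 2, 2, 1, 1, 2, 3, 0, 2, 1, 1, 0, 3, 2,
         2, 0, 3, 3, 0, 2, 2, 0, 3, 3, 1, 0, 1, 3, 2, 2], dtype=np.uint8
    ),
    "none": np.zeros(32, dtype=np.uint8),
}


def as_z4(symbols, length: int | None = None) -> np.ndarray:
    """Validate and return ``symbols`` as a 1-D uint8 array over {0,1,2,3}."""
    v = np.asarray(symbols)
    if v.ndim != 1:
        raise ValueError(f"expected a 1-D symbol vector, got ndim={v.ndim}")
    if v.size and (not np.issubdtype(v.dtype, np.integer) or v.min() < 0 or v.max() > 3):
        raise ValueError("symbols must be integers in {0,1,2,3}")
    if length is not None and v.size != length:
        raise ValueError(f"expected {length} symbols, got {v.size}")
    return v.astype(np.uint8)


def _resolve_pad(pad) -> np.ndarray:
    if isinstance(pad, str):
        try:
            return PADS[pad]
        except KeyError:
            raise ValueError(f"unknown pad {pad!r}; choose from {sorted(PADS)}") from None
    return as_z4(pad, 32)


@dataclass(frozen=True)
class CodeSpec:
    """The fixed (31, 26) mod-4 Hamming code plus checksum/hash layout.

    Construction brute-force verifies that all 93 single-error syndromes
    ``m * h_i`` (position i in 1..31, magnitude m in {1,2,3}) are nonzero
    and pairwise distinct; a collision is a fatal configuration error.
    """

    A: np.ndarray
    G: np.ndarray
    H: np.ndarray
    n_code: int = 31
    n_data: int = 26
    n_parity: int = 5
    n_hash_symbols: int = 6
    n_hash_bits: int = 12
    n_message_bytes: int = 5
    syndrome_table: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def standard(cls) -> "CodeSpec":
        A = np.array(_A_ROWS, dtype=np.int64)
        G = np.hstack([np.eye(26, dtype=np.int64), (-A.T) % 4])
        H = np.hstack([A, np.eye(5, dtype=np.int64)])
        spec = cls(A=A, G=G, H=H)
        spec._check_invariants()
        return spec

    def _check_invariants(self) -> None:
        if ((self.H @ self.G.T) % 4).any():
            raise ValueError("H . G^T != 0 mod 4: G and H are not orthogonal")
        cols = {tuple(self.H[:, i]) for i in range(self.n_code)}
        if len(cols) != self.n_code or tuple([0] * self.n_parity) in cols:
            raise ValueError("columns of H are not 31 distinct nonzero binary 5-vectors")
        table: dict[tuple, tuple[int, int]] = {}
        for i in range(self.n_code):
            for m in (1, 2, 3):
                s = tuple((m * self.H[:, i]) % 4)
                if s == (0,) * self.n_parity or s in table:
                    raise ValueError(f"syndrome collision at position {i}, magnitude {m}")
                table[s] = (i, m)
        self.syndrome_table.update(table)

    def syndrome(self, codeword31) -> np.ndarray:
        return (self.H @ as_z4(codeword31, self.n_code).astype(np.int64)) % 4

    def lookup_single_error(self, syndrome) -> tuple[int, int] | None:
        """Return ``(position, magnitude)`` for a single-error syndrome, or None."""
        return self.syndrome_table.get(tuple(int(x) for x in syndrome))


@dataclass(frozen=True)
class PaddedWord:
    """A 32-symbol transmissible word: 31 codeword symbols + checksum symbol."""

    symbols: np.ndarray
    pad_id: str = "none"

    def __post_init__(self):
        object.__setattr__(self, "symbols", as_z4(self.symbols, 32))


class DecodeCategory(enum.Enum):
    PERFECT = "perfect"
    CORRECTED_HASH_OK = "corrected_hash_ok"
    CORRECTED_HASH_FAIL = "corrected_hash_fail"
    CHECKSUM_INVALID = "checksum_invalid"
    UNCORRECTABLE = "uncorrectable"
    WRONG_MESSAGE = "wrong_message"


#: Categories whose recovered bytes pass the hash gate (message accepted).
ACCEPTED = frozenset({DecodeCategory.PERFECT, DecodeCategory.CORRECTED_HASH_OK})


@dataclass(frozen=True)
class DecodeOutcome:
    category: DecodeCategory
    message_bytes: bytes | None = None
    corrected_position: int | None = None
    corrected_magnitude: int | None = None


def bytes_to_symbols(data: bytes) -> np.ndarray:
    """Split bytes MSB-first into 2-bit pairs: byte b -> (b>>6, b>>4, b>>2, b) & 3."""
    if len(data) == 0:
        raise ValueError("cannot encode an empty byte string")
    b = np.frombuffer(bytes(data), dtype=np.uint8)
    shifts = np.array([6, 4, 2, 0], dtype=np.uint8)
    return ((b[:, None] >> shifts) & 3).reshape(-1).astype(np.uint8)


def symbols_to_bytes(v) -> bytes:
    v = as_z4(v)
    if v.size % 4:
        raise ValueError(f"symbol count {v.size} is not a multiple of 4")
    quads = v.reshape(-1, 4).astype(np.uint8)
    weights = np.array([64, 16, 4, 1], dtype=np.uint8)
    return (quads * weights).sum(axis=1, dtype=np.uint8).tobytes()


def compute_hash_symbols(message: bytes, spec: CodeSpec | None = None) -> np.ndarray:
    """6 symbols holding the 12 least-significant bits of SHA-256(message).

    The digest is read as a big-endian 256-bit integer; its low 12 bits are
    emitted as six 2-bit symbols, most-significant pair first.
    """
    spec = spec or _STANDARD
    if len(message) != spec.n_message_bytes:
        raise ValueError(
            f"message must be {spec.n_message_bytes} bytes, got {len(message)}"
        )
    low = int.from_bytes(hashlib.sha256(bytes(message)).digest(), "big")
    low &= (1 << spec.n_hash_bits) - 1
    n = spec.n_hash_symbols
    return np.array([(low >> (2 * (n - 1 - k))) & 3 for k in range(n)], dtype=np.uint8)


def hamming_encode(data26, spec: CodeSpec | None = None) -> np.ndarray:
    """Systematic encoding: c = data26 . G mod 4 (first 26 symbols = data)."""
    spec = spec or _STANDARD
    d = as_z4(data26, spec.n_data)
    return ((d.astype(np.int64) @ spec.G) % 4).astype(np.uint8)


def append_checksum(c31, pad_id: str = "none") -> PaddedWord:
    """Append the checksum symbol -sum(c) mod 4 so the 32 symbols sum to 0."""
    c = as_z4(c31, 31)
    checksum = (-int(c.sum())) % 4
    return PaddedWord(np.append(c, checksum), pad_id=pad_id)


def apply_otp(w, pad) -> np.ndarray:
    """Elementwise (w + pad) mod 4."""
    w = as_z4(w)
    p = _resolve_pad(pad) if isinstance(pad, str) else as_z4(pad)
    if w.size != p.size:
        raise ValueError(f"length mismatch: word {w.size} vs pad {p.size}")
    return ((w.astype(np.int64) + p) % 4).astype(np.uint8)


def remove_otp(w, pad) -> np.ndarray:
    """Elementwise (w - pad) mod 4, inverse of :func:`apply_otp`."""
    w = as_z4(w)
    p = _resolve_pad(pad) if isinstance(pad, str) else as_z4(pad)
    if w.size != p.size:
        raise ValueError(f"length mismatch: word {w.size} vs pad {p.size}")
    return ((w.astype(np.int64) - p) % 4).astype(np.uint8)


def encode_message(
    message: bytes,
    pad: str = "X1",
    spec: CodeSpec | None = None,
    otp_stage: str = "word",
) -> np.ndarray:
    """Encode 5 bytes into the 32-symbol transmissible word.

    Pipeline: bytes -> 20 symbols, append 6 hash symbols, Hamming-encode to
    31 symbols, append checksum, add one-time pad. ``otp_stage`` selects where
    the pad enters: ``"word"`` adds the full 32-entry pad to the finished word
    (default); ``"data"`` adds the pad's first 26 entries to the data symbols
    before encoding (the code being linear, both decode cleanly as long as
    encoder and decoder agree).
    """
    spec = spec or _STANDARD
    if otp_stage not in ("word", "data"):
        raise ValueError("otp_stage must be 'word' or 'data'")
    padvec = _resolve_pad(pad)
    data26 = np.concatenate([bytes_to_symbols(message), compute_hash_symbols(message, spec)])
    if otp_stage == "data":
        data26 = ((data26.astype(np.int64) + padvec[: spec.n_data]) % 4).astype(np.uint8)
    word = append_checksum(hamming_encode(data26, spec)).symbols
    if otp_stage == "word":
        word = apply_otp(word, padvec)
    return word


def decode_word(
    r32,
    pad: str = "X1",
    spec: CodeSpec | None = None,
    truth: bytes | None = None,
    otp_stage: str = "word",
) -> DecodeOutcome:
    """Syndrome-decode a received 32-symbol word.

    After pad removal the syndrome ``s = H r[0:31]`` and checksum discrepancy
    ``d = sum(r) mod 4`` drive the decision table:

    * ``s=0, d=0`` — clean codeword, no correction.
    * ``s=0, d!=0`` — the error sits in the checksum symbol alone; the data
      symbols are accepted and the checksum corrected.
    * ``s!=0, d!=0`` — look up the unique ``(i, m)`` with ``m*h_i = s``; if it
      exists and ``m = d`` the error is subtracted at position ``i``. A hit
      with ``m != d`` means the corrected word would still violate the
      checksum: CHECKSUM_INVALID. No hit: UNCORRECTABLE.
    * ``s!=0, d=0`` — a double error signature: UNCORRECTABLE.

    Accepted words are finally gated on the embedded 12-bit hash; a mismatch
    yields CORRECTED_HASH_FAIL and withholds the bytes. When ``truth`` is
    given, accepted bytes that differ from it are flagged WRONG_MESSAGE.
    """
    spec = spec or _STANDARD
    if otp_stage not in ("word", "data"):
        raise ValueError("otp_stage must be 'word' or 'data'")
    r = as_z4(r32, 32)
    padvec = _resolve_pad(pad)
    if otp_stage == "word":
        r = remove_otp(r, padvec)
    r = r.astype(np.int64)

    s = spec.syndrome(r[:31] % 4)
    d = int(r.sum()) % 4
    corrected_position: int | None = None
    corrected_magnitude: int | None = None

    if not s.any():
        if d != 0:  # error confined to the checksum symbol
            corrected_position, corrected_magnitude = 31, d
            r[31] = (r[31] - d) % 4
    else:
        if d == 0:
            return DecodeOutcome(DecodeCategory.UNCORRECTABLE)
        hit = spec.lookup_single_error(s)
        if hit is None:
            return DecodeOutcome(DecodeCategory.UNCORRECTABLE)
        i, m = hit
        if m != d:
            return DecodeOutcome(DecodeCategory.CHECKSUM_INVALID)
        r[i] = (r[i] - m) % 4
        corrected_position, corrected_magnitude = i, m

    data26 = (r[: spec.n_data] % 4).astype(np.uint8)
    if otp_stage == "data":
        data26 = ((data26.astype(np.int64) - padvec[: spec.n_data]) % 4).astype(np.uint8)
    message = symbols_to_bytes(data26[: 4 * spec.n_message_bytes])
    embedded_hash = data26[4 * spec.n_message_bytes :]

    if not np.array_equal(compute_hash_symbols(message, spec), embedded_hash):
        return DecodeOutcome(
            DecodeCategory.CORRECTED_HASH_FAIL,
            corrected_position=corrected_position,
            corrected_magnitude=corrected_magnitude,
        )
    category = (
        DecodeCategory.PERFECT if corrected_position is None else DecodeCategory.CORRECTED_HASH_OK
    )
    if truth is not None and message != bytes(truth):
        category = DecodeCategory.WRONG_MESSAGE
    return DecodeOutcome(category, message, corrected_position, corrected_magnitude)


def enumerate_double_errors(
    word32,
    pad: str = "X1",
    spec: CodeSpec | None = None,
    truth: bytes | None = None,
) -> dict[DecodeCategory, int]:
    """Decode all C(32,2)*9 = 4464 two-position corruptions of a word.

    The exhaustive count is the ground truth for how far "detects all
    double-base errors" carries over mod-4 arithmetic, where the binary
    extended-Hamming argument does not directly apply.
    """
    spec = spec or _STANDARD
    w = as_z4(word32, 32).astype(np.int64)
    counts: dict[DecodeCategory, int] = {c: 0 for c in DecodeCategory}
    for i in range(32):
        for j in range(i + 1, 32):
            for ei in (1, 2, 3):
                for ej in (1, 2, 3):
                    r = w.copy()
                    r[i] = (r[i] + ei) % 4
                    r[j] = (r[j] + ej) % 4
                    out = decode_word(r.astype(np.uint8), pad=pad, spec=spec, truth=truth)
                    counts[out.category] += 1
    return counts


_STANDARD = CodeSpec.standard()
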