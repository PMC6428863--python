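"""Codec unit and property tests: symbol packing, hash, Hamming code, OTP,
syndrome decoding."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnastore import codec
from dnastore.codec import (
    DecodeCategory,
    PADS,
    append_checksum,
    apply_otp,
    bytes_to_symbols,
    compute_hash_symbols,
    decode_word,
    encode_message,
    hamming_encode,
    remove_otp,
    symbols_to_bytes,
)

# Low 12 bits of SHA-256("HELLO"), computed independently with hashlib and
# frozen: 0x4d5 -> MSB-pair-first symbols.
HELLO_HASH_SYMBOLS = (1, 0, 3, 1, 1, 1)


class TestSymbolPacking:
    @pytest.mark.parametrize(
        "data, expected",
        [
            (b"H", [1, 0, 2, 0]),  # 0x48 = 01 00 10 00, MSB-first pairs
            (b"\x00", [0, 0, 0, 0]),
            (b"\xff", [3, 3, 3, 3]),
        ],
    )
    def test_bytes_to_symbols(self, data, expected):
        assert bytes_to_symbols(data).tolist() == expected

    def test_hello_matches_bit_string(self):
        # "HELLO" = 01001000 01000101 01001100 01001100 01001111
        bits = "0100100001000101010011000100110001001111"
        expected = [int(bits[i : i + 2], 2) for i in range(0, 40, 2)]
        assert bytes_to_symbols(b"HELLO").tolist() == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bytes_to_symbols(b"")

    def test_non_multiple_of_four_rejected(self):
        with pytest.raises(ValueError):
            symbols_to_bytes([1, 0, 2])

    @given(st.binary(min_size=1, max_size=64))
    @settings(max_examples=100, derandomize=True)
    def test_round_trip(self, data):
        assert symbols_to_bytes(bytes_to_symbols(data)) == data


class TestHash:
    def test_hello_fixture(self):
        assert tuple(compute_hash_symbols(b"HELLO")) == HELLO_HASH_SYMBOLS

    def test_length_and_validation(self):
        assert compute_hash_symbols(b"WORLD").size == 6
        with pytest.raises(ValueError):
            compute_hash_symbols(b"TOO LONG")


class TestCodeSpec:
    def test_generator_parity_orthogonal(self, spec):
        assert not ((spec.H @ spec.G.T) % 4).any()

    def test_h_columns_are_all_nonzero_binary_5_vectors(self, spec):
        cols = {tuple(spec.H[:, i]) for i in range(31)}
        assert len(cols) == 31
        assert all(set(c) <= {0, 1} for c in cols)
        assert (0, 0, 0, 0, 0) not in cols

    def test_93_syndromes_distinct(self, spec):
        assert len(spec.syndrome_table) == 93


class TestEncoding:
    def test_zero_data_gives_zero_codeword(self, spec):
        assert not hamming_encode(np.zeros(26, dtype=int), spec).any()

    def test_systematic_and_valid(self, spec, rng):
        data = rng.integers(0, 4, size=26)
        c = hamming_encode(data, spec)
        assert c.size == 31
        assert np.array_equal(c[:26], data)
        assert not spec.syndrome(c).any()

    def test_parity_matches_row_dot_product_oracle(self, spec, rng):
        # independent oracle: parity_k = -sum_j A[k,j]*data[j] mod 4, plain loops
        data = rng.integers(0, 4, size=26)
        c = hamming_encode(data, spec)
        for k in range(5):
            expected = (-sum(int(spec.A[k, j]) * int(data[j]) for j in range(26))) % 4
            assert int(c[26 + k]) == expected

    def test_linearity_pre_checksum(self, spec, rng):
        m1, m2 = rng.integers(0, 4, size=(2, 26))
        lhs = hamming_encode((m1 + m2) % 4, spec)
        rhs = (hamming_encode(m1, spec).astype(int) + hamming_encode(m2, spec)) % 4
        assert np.array_equal(lhs, rhs)

    @pytest.mark.parametrize(
        "total_mod4, checksum", [(0, 0), (1, 3), (2, 2), (3, 1)]
    )
    def test_checksum_complements_sum(self, total_mod4, checksum):
        c = np.zeros(31, dtype=int)
        c[0] = total_mod4
        w = append_checksum(c)
        assert w.symbols.size == 32
        assert int(w.symbols[-1]) == checksum
        assert int(w.symbols.sum()) % 4 == 0


class TestOtp:
    def test_printed_pads(self):
        assert PADS["X1"].size == 32 and PADS["X2"].size == 32
        assert PADS["X1"][:5].tolist() == [1, 3, 0, 1, 0]

    def test_zero_pad_identity(self, rng):
        w = rng.integers(0, 4, size=32)
        assert np.array_equal(apply_otp(w, "none"), w)

    def test_apply_remove_inverse(self, rng):
        w = rng.integers(0, 4, size=32)
        assert np.array_equal(remove_otp(apply_otp(w, "X1"), "X1"), w)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            apply_otp([1, 2, 3], "X1")


class TestEncodeDecode:
    def test_hello_round_trip(self, hello_word):
        assert hello_word.size == 32
        out = decode_word(hello_word, pad="X1")
        assert out.category is DecodeCategory.PERFECT
        assert out.message_bytes == b"HELLO"

    def test_pads_give_different_words(self):
        w1 = encode_message(b"HELLO", pad="X1")
        w2 = encode_message(b"HELLO", pad="X2")
        assert not np.array_equal(w1, w2)

    @given(st.binary(min_size=5, max_size=5), st.sampled_from(["X1", "X2", "none"]))
    @settings(max_examples=200, derandomize=True)
    def test_random_messages_round_trip(self, message, pad):
        out = decode_word(encode_message(message, pad=pad), pad=pad)
        assert out.category is DecodeCategory.PERFECT
        assert out.message_bytes == message

    def test_otp_stage_data_round_trips(self):
        w = encode_message(b"WORLD", pad="X2", otp_stage="data")
        out = decode_word(w, pad="X2", otp_stage="data")
        assert out.category is DecodeCategory.PERFECT
        assert out.message_bytes == b"WORLD"

    def test_otp_neutrality(self, rng):
        """Same corruption pattern decodes identically with and without pad."""
        w_pad = encode_message(b"HELLO", pad="X1")
        w_raw = encode_message(b"HELLO", pad="none")
        for _ in range(50):
            pos = rng.integers(0, 32, size=2)
            mag = rng.integers(1, 4, size=2)
            rp, rr = w_pad.astype(int), w_raw.astype(int)
            for p, m in zip(pos, mag):
                rp[p] = (rp[p] + m) % 4
                rr[p] = (rr[p] + m) % 4
            a = decode_word(np.array(rp) % 4, pad="X1")
            b = decode_word(np.array(rr) % 4, pad="none")
            assert a.category == b.category
            assert a.message_bytes == b.message_bytes

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            decode_word(np.zeros(31, dtype=int))


class TestSingleErrors:
    def test_all_93_corrections(self, hello_word):
        for i in range(31):
            for m in (1, 2, 3):
                r = hello_word.astype(int)
                r[i] = (r[i] + m) % 4
                out = decode_word(np.array(r), pad="X1")
                assert out.category is DecodeCategory.CORRECTED_HASH_OK
                assert out.message_bytes == b"HELLO"
                assert out.corrected_position == i
                assert out.corrected_magnitude == m

    def test_checksum_base_corruption_accepted(self, hello_word):
        for m in (1, 2, 3):
            r = hello_word.astype(int)
            r[31] = (r[31] + m) % 4
            out = decode_word(np.array(r), pad="X1")
            assert out.category is DecodeCategory.CORRECTED_HASH_OK
            assert out.message_bytes == b"HELLO"
            assert out.corrected_position == 31

    def test_wrong_message_flagged_against_truth(self, hello_word):
        out = decode_word(hello_word, pad="X1", truth=b"WORLD")
        assert out.category is DecodeCategory.WRONG_MESSAGE
        assert out.message_bytes == b"HELLO"


def oracle_decode_category(r32, word_true, spec):
    """Independent brute-force syndrome oracle (plain loops, no lookup table).

    Tries every single-symbol correction exhaustively instead of using the
    precomputed syndrome table; categories follow the same decision
    semantics as the decoder under test.
    """
    r = [int(x) for x in r32]
    s = [sum(int(spec.H[k, i]) * r[i] for i in range(31)) % 4 for k in range(5)]
    d = sum(r) % 4
    if all(v == 0 for v in s):
        corrected = list(r)
        correction = None if d == 0 else (31, d)
        if d != 0:
            corrected[31] = (corrected[31] - d) % 4
    else:
        if d == 0:
            return "uncorrectable"
        hits = []
        for i in range(31):
            for m in (1, 2, 3):
                if all((m * int(spec.H[k, i])) % 4 == s[k] for k in range(5)):
                    hits.append((i, m))
        if not hits:
            return "uncorrectable"
        assert len(hits) == 1
        i, m = hits[0]
        if m != d:
            return "checksum_invalid"
        corrected = list(r)
        corrected[i] = (corrected[i] - m) % 4
        correction = (i, m)
    data26 = corrected[:26]
    message = symbols_to_bytes(np.array(data26[:20]))
    if not np.array_equal(compute_hash_symbols(message, spec), np.array(data26[20:26])):
        return "corrected_hash_fail"
    if message != word_true:
        return "wrong_message"
    return "perfect" if correction is None else "corrected_hash_ok"


class TestDoubleErrors:
    def test_enumeration_partitions_and_matches_oracle(self, spec, hello_word):
        """All 4464 double corruptions: exhaustive counts, no PERFECT, and
        case-by-case agreement with the brute-force oracle."""
        counts = codec.enumerate_double_errors(hello_word, pad="X1", spec=spec, truth=b"HELLO")
        assert sum(counts.values()) == 4464
        assert counts[DecodeCategory.PERFECT] == 0

        # case-by-case: oracle operates on the unpadded word
        w = remove_otp(hello_word, "X1").astype(int)
        oracle_counts = {c.value: 0 for c in DecodeCategory}
        for i in range(32):
            for j in range(i + 1, 32):
                for ei in (1, 2, 3):
                    for ej in (1, 2, 3):
                        r = list(w)
                        r[i] = (r[i] + ei) % 4
                        r[j] = (r[j] + ej) % 4
                        oracle_counts[oracle_decode_category(r, b"HELLO", spec)] += 1
        assert {c.value: n for c, n in counts.items()} == oracle_counts
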