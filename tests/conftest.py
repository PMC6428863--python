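import numpy as np
import pytest

from dnastore import (
    build_adapter,
    build_hairpin,
    build_read_reference,
    encode_message,
)
from dnastore.codec import CodeSpec


@pytest.fixture(scope="session")
def spec():
    return CodeSpec.standard()


@pytest.fixture(scope="session")
def hello_word():
    """The 32-symbol transmissible word for "HELLO" under pad X1."""
    return encode_message(b"HELLO", pad="X1")


@pytest.fixture(scope="session")
def hello_constructs(hello_word):
    """(adapter, hairpin, reference) for the end-to-end configuration (P=13)."""
    hairpin = build_hairpin(hello_word, padding_len=13, seed=0)
    adapter = build_adapter(seed=1)
    return adapter, hairpin, build_read_reference(adapter, hairpin)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
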