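import numpy as np
import pytest

from aqsurveil.corpus import Message, MessageCorpus


def random_corpus(
    rng: np.random.Generator,
    n_messages: int = 100,
    vocab: int = 30,
    n_cities: int = 5,
    max_len: int = 12,
    url_prob: float = 0.3,
) -> MessageCorpus:
    """Small unstructured corpus for oracle comparisons."""
    messages = []
    for i in range(n_messages):
        length = int(rng.integers(1, max_len + 1))
        tokens = [f"w{int(t):03d}" for t in rng.integers(0, vocab, size=length)]
        messages.append(
            Message(
                id=f"m{i:04d}",
                user_id=f"u{i:04d}",
                city=f"city_{int(rng.integers(0, n_cities)):02d}",
                account_type="individual",
                tokens=tokens,
                has_url=bool(rng.random() < url_prob),
            )
        )
    return MessageCorpus(messages)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_corpus(rng):
    return random_corpus(rng, n_messages=100, vocab=30)
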