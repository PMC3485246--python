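import random

import pytest
from hypothesis import HealthCheck, settings

from pairmotif.core import BASES, SequenceRecord

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=200,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def random_word(rng: random.Random, l: int) -> str:
    return "".join(rng.choice(BASES) for _ in range(l))


def word_at_distance(rng: random.Random, word: str, h: int) -> str:
    """A word differing from ``word`` in exactly h uniformly chosen positions."""
    positions = rng.sample(range(len(word)), h)
    out = list(word)
    for i in positions:
        out[i] = rng.choice([b for b in BASES if b != word[i]])
    return "".join(out)


def random_records(
    rng: random.Random, t: int, n: int, prefix: str = "s"
) -> list[SequenceRecord]:
    return [
        SequenceRecord(identifier=f"{prefix}{i}", residues=random_word(rng, n))
        for i in range(t)
    ]


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20120)
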