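import numpy as np
import pytest

from minsupre import EntitySpan, RelationInstance


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_instance(i: int, rng: np.random.Generator, gold=None) -> RelationInstance:
    n = int(rng.integers(4, 12))
    tokens = tuple(f"tok{rng.integers(0, 50)}" for _ in range(n))
    s1 = int(rng.integers(0, n - 2))
    e1 = EntitySpan(s1, s1 + 1, tokens[s1])
    s2 = int(rng.integers(s1 + 1, n))
    e2 = EntitySpan(s2, s2 + 1, tokens[s2])
    return RelationInstance(
        id=f"inst{i}", tokens=tokens, e1=e1, e2=e2,
        gold_label=gold if gold is not None else int(rng.choice([1, -1])),
    )


@pytest.fixture
def random_instances(rng):
    return [make_instance(i, rng) for i in range(100)]
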