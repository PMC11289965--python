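import random

import pytest

from sparsefold import default_params

#: lengths 20-60, fixed seed — shared corpus for the equivalence suites
_CORPUS_SEED = 20260927


@pytest.fixture(scope="session")
def P():
    return default_params()


@pytest.fixture(scope="session")
def corpus():
    rng = random.Random(_CORPUS_SEED)
    return ["".join(rng.choice("ACGU") for _ in range(rng.randint(20, 60)))
            for _ in range(100)]


@pytest.fixture(scope="session")
def small_corpus(corpus):
    return corpus[:15]


@pytest.fixture(scope="session")
def vienna():
    """Optional external oracle (skipped gracefully when absent)."""
    try:
        import RNA
        return RNA
    except ImportError:
        pytest.skip("ViennaRNA python bindings not available")
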