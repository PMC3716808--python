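import numpy as np
import pytest

from patternsieve import (
    PatternDistribution,
    binarize_median,
    generate_scene,
    natural_like_specs,
    pattern_histogram,
)


@pytest.fixture(scope="session")
def pink_corpus_bits():
    """Binarized natural-like corpus (list of bit arrays), deterministic."""
    specs = natural_like_specs(12, size=(96, 96), seed=11)
    return [binarize_median(generate_scene(s)) for s in specs]


@pytest.fixture(scope="session")
def pink_corpus_dist(pink_corpus_bits):
    return pattern_histogram(pink_corpus_bits)


@pytest.fixture()
def random_distribution():
    """Factory for random small pattern distributions with distinct probs."""

    def make(n: int, rng: np.random.Generator) -> PatternDistribution:
        w = rng.dirichlet(np.ones(n) * 0.5)
        w = np.maximum(w, 1e-12)
        w = w / w.sum()
        return PatternDistribution(probs={int(i): float(p) for i, p in enumerate(w)})

    return make
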