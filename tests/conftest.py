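import numpy as np
import pytest

from screensim import GeneratorConfig, generate_corpus, separable_config


@pytest.fixture(scope="session")
def separable_corpus():
    """Perfectly separable, noise-free corpus: relevant and irrelevant
    records draw from disjoint vocabularies and every stage equals truth."""
    return generate_corpus(separable_config(n_records=150, prevalence=0.06, seed=42))


@pytest.fixture(scope="session")
def noisy_corpus():
    """Default noisy three-stage corpus with nested adjudication labels."""
    return generate_corpus(GeneratorConfig(n_records=200, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240711)


def write_csv(path, rows, header):
    lines = [",".join(header)]
    lines += [",".join(str(cell) for cell in row) for row in rows]
    path.write_text("\n".join(lines) + "\n")
    return path
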