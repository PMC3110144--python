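import pytest

from drugchar import (
    GeneratorConfig,
    build_drug_index,
    build_matrix,
    generate,
)


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic corpus: 200 drugs, planted rare/common/signal tokens."""
    return generate(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def index(dataset):
    return build_drug_index(dataset.records, dataset.lexicon)


@pytest.fixture(scope="session")
def cdf_matrix(dataset, index):
    return build_matrix(index, dataset.drugs, measure="cdf")


@pytest.fixture(scope="session")
def small_dataset():
    """Scaled-down corpus for fast cross-validation unit tests."""
    return generate(
        GeneratorConfig(
            n_drugs=80, n_pos=10, vocab_size=400, mean_abstract_len=40,
            abstracts_median=15.0, seed=11,
        )
    )


@pytest.fixture(scope="session")
def small_cdf_matrix(small_dataset):
    idx = build_drug_index(small_dataset.records, small_dataset.lexicon)
    return build_matrix(idx, small_dataset.drugs, measure="cdf")
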