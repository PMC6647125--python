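import pytest

from phylostream import (FixtureSpec, events_to_adapter, fixture_corpus,
                         generate_fixture)


@pytest.fixture(scope="session")
def corpus():
    """A varied fixture corpus: (spec, events) pairs spanning all content
    kinds the library models."""
    return [(spec, generate_fixture(spec)) for spec in fixture_corpus(30)]


@pytest.fixture(scope="session")
def rich_document():
    """One document exercising everything at once: two OTU lists, two
    matrices, trees, a network, deep metadata and sets."""
    spec = FixtureSpec(seed=7, n_otu_lists=2, n_otus=4, n_matrices=2,
                       n_sequences=4, seq_length=12, n_trees=2, n_networks=1,
                       metadata_depth=4, metadata_per_element=2, set_count=2)
    return generate_fixture(spec)


@pytest.fixture()
def rich_adapter(rich_document):
    return events_to_adapter(rich_document)
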