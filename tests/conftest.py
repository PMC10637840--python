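import pytest

from theranorm import build_term_index, normalize_corpus
from theranorm.fixtures import all_records, imatinib_records


@pytest.fixture(scope="session")
def imatinib_corpus():
    return all_records(imatinib_records())


@pytest.fixture(scope="session")
def imatinib_concepts(imatinib_corpus):
    return normalize_corpus(imatinib_corpus)


@pytest.fixture(scope="session")
def imatinib_index(imatinib_concepts):
    return build_term_index(imatinib_concepts)
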