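import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from smpc2idmp.extraction import ExtractionConfig, extract_record
from smpc2idmp.normalize import normalize_record
from smpc2idmp.retrieval import RetrievalConfig
from smpc2idmp.synth import CorpusProfile, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Ten synthetic SmPC/gold pairs shared across tests (fixed seed)."""
    return generate_corpus(CorpusProfile(n_documents=10, seed=42))


@pytest.fixture(scope="session")
def recall_corpus():
    """The 50-document corpus used for retrieval-recall checks."""
    return generate_corpus(CorpusProfile(n_documents=50, seed=11))


@pytest.fixture()
def rule_based_config():
    return ExtractionConfig(retrieval=RetrievalConfig(mode="rule_based"))


@pytest.fixture(scope="session")
def extracted_pair(small_corpus):
    """(normalized prediction, normalized gold) for the first corpus doc,
    via the reference backend with rule-based retrieval."""
    doc, gold = small_corpus[0]
    config = ExtractionConfig(retrieval=RetrievalConfig(mode="rule_based"))
    record, _ = extract_record(doc, config)
    return normalize_record(record), normalize_record(gold)


@pytest.fixture()
def rng():
    return random.Random(12345)
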