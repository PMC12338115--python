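import pytest

from toxlitscore import (
    AnnotatedCorpus,
    DocumentAnnotation,
    GeneratorConfig,
    build_corpus,
    generate_corpus,
)


@pytest.fixture
def small_annotations() -> list[DocumentAnnotation]:
    """Five documents, two chemicals, one endpoint concept."""
    rows = [
        ("1", "chemical", "D002251", "carbon tetrachloride"),
        ("2", "chemical", "D002251", "carbon tetrachloride"),
        ("3", "chemical", "D002251", "carbon tetrachloride"),
        ("2", "disease", "D056486", "hepatotoxicity"),
        ("3", "disease", "D056486", "liver toxicity"),
        ("4", "disease", "D056486", "hepatotoxicity"),
        ("4", "chemical", "C000001", "inertol"),
        ("5", "chemical", "C000001", "inertol"),
    ]
    return [
        DocumentAnnotation(d, t, c, m, "TEST") for d, t, c, m in rows
    ]


@pytest.fixture
def small_corpus(small_annotations) -> AnnotatedCorpus:
    docs = {str(i): (f"title {i}", f"abstract {i}", False) for i in range(1, 6)}
    return build_corpus(small_annotations, docs)


@pytest.fixture(scope="session")
def default_corpus():
    """A modest planted corpus shared across read-only tests."""
    config = GeneratorConfig(n_compounds=20, n_documents=800, seed=11)
    corpus, truth = generate_corpus(config)
    return config, corpus, truth
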