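import pytest

from phenossu import (
    GeneratorConfig,
    default_lexicon,
    default_profiles,
    default_schema,
    generate_corpus,
    train_all_attributes,
)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def small_corpus(schema):
    """Seeded 10-document synthetic corpus under the default (skewed)
    prevalences."""
    return generate_corpus(
        GeneratorConfig(seed=42, n_documents=10, sentences_per_document=8), schema
    )


@pytest.fixture(scope="session")
def recovery_corpus(schema):
    """The unambiguous parameter-recovery corpus: 200 sentences, every
    attribute value observable (uniform prevalence 0.5), ambiguity 0."""
    prevalence = {a.name: 0.5 for a in schema}
    return generate_corpus(
        GeneratorConfig(
            seed=11, n_documents=20, sentences_per_document=10, prevalence=prevalence
        ),
        schema,
    )


@pytest.fixture(scope="session")
def trained_classifiers(recovery_corpus, schema):
    """Classifiers trained on the first 12 documents of the recovery corpus
    (6:4 train/test split)."""
    return train_all_attributes(recovery_corpus[:12], schema, seed=11)
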