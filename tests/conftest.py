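import pytest

import comorbex as cx


@pytest.fixture(scope="session")
def taxonomy():
    return cx.load_default_taxonomy()


@pytest.fixture(scope="session")
def lexicon_backend(taxonomy):
    return cx.LexiconBackend(taxonomy)


def make_clean_spec(n_documents, seed, **overrides):
    """Default study prevalences with the trap phenomena switched off."""
    base = cx.default_corpus_spec(n_documents=n_documents, seed=seed)
    kwargs = dict(
        n_documents=n_documents,
        seed=seed,
        prevalence=base.prevalence,
        child_given_parent=base.child_given_parent,
        cooccurrence_boost=base.cooccurrence_boost,
        negation_rate=0.0,
        temporality_rate=0.0,
        distractor_rate=0.0,
    )
    kwargs.update(overrides)
    return cx.CorpusSpec(**kwargs)


@pytest.fixture(scope="session")
def clean_corpus(taxonomy):
    """500 trap-free documents under the study prevalences."""
    return cx.generate_corpus(make_clean_spec(500, seed=11), taxonomy)


@pytest.fixture(scope="session")
def tiny_taxonomy():
    return cx.load_taxonomy(
        """
name: tiny
categories:
  - id: sdb
    name: Sleep-disordered breathing
    lexicon: [{term: sleep apnoea, kind: canonical}]
  - id: htn
    name: Hypertension
    lexicon: [{term: hypertension, kind: canonical}]
  - id: osa
    name: Obstructive sleep apnoea
    parent: sdb
    lexicon: [{term: obstructive sleep apnoea, kind: canonical}]
  - id: csa
    name: Central sleep apnoea
    parent: sdb
    lexicon: [{term: central sleep apnoea, kind: canonical}]
"""
    )
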