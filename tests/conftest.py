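"""Shared fixtures: hand-built transcripts and the synthetic lexicon bundle."""

from __future__ import annotations

import numpy as np
import pytest

from speechdims import pipeline, synthetic
from speechdims.corpus import Sentence, Token, Transcript


def make_token(surface, upos="NOUN", head=0, deprel="root", lemma=None,
               morph=0, pause=False, personal=False):
    return Token(surface=surface, lemma=lemma or surface.lower(), upos=upos,
                 morph_count=morph, head=head, deprel=deprel,
                 is_filled_pause=pause, is_personal_pronoun=personal)


def chain_sentence(words, index=0, upos="NOUN", pauses=()):
    """A flat chain parse: token i attaches to token i-1, first is root.

    ``pauses`` lists 0-based positions that become filled-pause tokens
    (excluded from the chain).
    """
    toks = []
    prev_content = 0
    for i, w in enumerate(words):
        if i in pauses:
            toks.append(make_token(w, upos="INTJ", head=0, deprel="discourse",
                                   pause=True))
            continue
        head = prev_content
        toks.append(make_token(w, upos=upos, head=head,
                               deprel="root" if head == 0 else "dep"))
        prev_content = len(toks)
    return Sentence(tokens=tuple(toks), index=index)


def simple_transcript(sentences, pid="t1"):
    return Transcript(participant_id=pid, sentences=tuple(sentences))


@pytest.fixture(scope="session")
def lexicon_bundle():
    lex, static, contextual = synthetic.build_lexicon()
    return {"lexicon": lex, "static": static, "contextual": contextual}


@pytest.fixture(scope="session")
def providers(lexicon_bundle):
    return pipeline.default_providers(lexicon_bundle["static"],
                                      lexicon_bundle["contextual"])


@pytest.fixture(scope="session")
def three_factor_design():
    """Canonical 18-feature, 3-factor loading design (primaries 0.5-0.8)."""
    return synthetic.table_like_loading_design()


@pytest.fixture(scope="session")
def small_cohort(providers):
    """One modest cohort with transcripts, reused across integration tests."""
    cfg = synthetic.CohortConfig.planted_correlation_study(rho=-0.3, n=150)
    cohort = synthetic.generate_cohort(cfg, seed=11)
    table = pipeline.feature_table(cohort["transcripts"], providers)
    return {"cohort": cohort, "features": table}


class ConstantEmbedding:
    """All words map to the same vector (for degenerate-case tests)."""

    def __init__(self, vec):
        self.vec = np.asarray(vec, dtype=float)
        self.dimension = len(self.vec)

    def word_vector(self, word):
        return self.vec

    def sentence_vector(self, sentence):
        return self.vec


class TableEmbedding:
    """Embedding provider backed by an explicit word -> vector table."""

    def __init__(self, table):
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}
        self.dimension = len(next(iter(self.table.values())))

    def word_vector(self, word):
        return self.table.get(word)

    def sentence_vector(self, sentence):
        vecs = [self.table[t.surface.lower()] for t in sentence.content_tokens()
                if t.surface.lower() in self.table]
        return np.mean(vecs, axis=0) if vecs else None
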