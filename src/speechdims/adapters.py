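"""Adapter contracts for the model-backed features.

The embedding, sentiment and grammar components of the feature set depend on
external models (word-vector tables, a sentiment classifier, a grammar
checker).  The pipeline talks to them only through the small contracts below,
so a production deployment can plug in FastText/BERT/spaCy-backed providers
while tests use deterministic fixtures.  All adapters must be deterministic:
the same input yields the same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .corpus import Sentence, Token, Transcript


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Maps words and sentences to fixed-dimension real vectors."""

    dimension: int

    def word_vector(self, word: str) -> np.ndarray | None:
        """Vector for a word, or None when the word is unknown."""
        ...

    def sentence_vector(self, sentence: Sentence) -> np.ndarray | None:
        """Vector for a sentence (default: mean of known word vectors)."""
        ...


@runtime_checkable
class SentimentModel(Protocol):
    def negative_probability(self, transcript: Transcript) -> float:
        """Probability in [0, 1] that the text carries negative sentiment."""
        ...


@runtime_checkable
class GrammarChecker(Protocol):
    def error_count(self, sentence: Sentence) -> int:
        """Nonnegative number of grammatical errors detected in a sentence."""
        ...


def mean_word_sentence_vector(
    provider: EmbeddingProvider, sentence: Sentence
) -> np.ndarray | None:
    """Default sentence embedding: mean of known non-pause word vectors."""
    vecs = [
        v for t in sentence.content_tokens()
        if (v := provider.word_vector(t.surface.lower())) is not None
    ]
    if not vecs:
        return None
    return np.mean(vecs, axis=0)


@dataclass
class LexiconSentimentModel:
    """Logistic sentiment fixture: p = logistic(alpha + beta * negative share).

    ``negative share`` is the fraction of non-pause tokens whose lemma is in
    the negative lexicon.  With the default ``alpha = -2`` a fully neutral
    text scores 1/(1+e^2) ~ 0.119.
    """

    negative_lexicon: frozenset[str]
    alpha: float = -2.0
    beta: float = 8.0

    def negative_probability(self, transcript: Transcript) -> float:
        toks = transcript.content_stream()
        share = (
            sum(t.lemma.lower() in self.negative_lexicon for t in toks) / len(toks)
            if toks else 0.0
        )
        return 1.0 / (1.0 + math.exp(-(self.alpha + self.beta * share)))


@dataclass
class MarkupGrammarChecker:
    """Grammar-checker fixture that counts error marks in the annotation.

    The synthetic generator tags ungrammatical tokens with the deprel suffix
    ``:err``; real deployments replace this adapter with a model-backed one.
    """

    mark: str = ":err"

    def error_count(self, sentence: Sentence) -> int:
        return sum(t.deprel.endswith(self.mark) for t in sentence.tokens)


@dataclass
class ConstantSentimentModel:
    """Degenerate sentiment adapter returning a fixed probability."""

    value: float = 0.5

    def negative_probability(self, transcript: Transcript) -> float:
        return self.value


@dataclass
class ZeroGrammarChecker:
    """Grammar checker that reports no errors (null adapter)."""

    def error_count(self, sentence: Sentence) -> int:
        return 0
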