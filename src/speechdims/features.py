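"""The 18 spontaneous-speech NLP features.

Lexical (TTR, MTLD, pronoun ratios), morphological (mean feature count),
syntactic (dependency-based complexity, subordination, readability,
connectives), semantic (embedding coherence at sentence/word level, content
word density, word-graph cohesion) and disfluency/sentiment measures.  Each
feature documents which token population enters its numerator and
denominator, in particular whether filled pauses count.

A value that cannot be computed for a transcript (e.g. the personal-pronoun
share of a transcript with no pronouns) is the NaN missing sentinel, never a
silent zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from . import lexicons
from .adapters import (
    EmbeddingProvider,
    GrammarChecker,
    SentimentModel,
    mean_word_sentence_vector,
)
from .corpus import FeatureVector, MISSING, Sentence, Token, Transcript


class FeatureError(ValueError):
    """A feature's precondition is violated or an adapter broke its contract."""


# ---------------------------------------------------------------------------
# Lexical
# ---------------------------------------------------------------------------

def lexical_ratios(transcript: Transcript) -> dict[str, float]:
    """Type-token ratio and pronoun shares.

    TTR uses lowercased surface forms and excludes filled pauses from both
    numerator and denominator.  ``pronoun_ratio`` is PRON tokens over all
    non-pause tokens; ``personal_pronoun_ratio`` is personal pronouns over
    all pronouns (missing when the transcript has no pronouns).
    """
    toks = transcript.content_stream()
    if not toks:
        raise FeatureError("transcript has no non-filled-pause tokens")
    surfaces = [t.surface.lower() for t in toks]
    n_pron = sum(t.is_pronoun for t in toks)
    n_personal = sum(t.is_personal_pronoun for t in toks)
    return {
        "ttr": len(set(surfaces)) / len(surfaces),
        "pronoun_ratio": n_pron / len(toks),
        "personal_pronoun_ratio": n_personal / n_pron if n_pron else MISSING,
    }


@dataclass(frozen=True)
class MtldConfig:
    """MTLD parameters: factor-closing TTR threshold and production minimum."""

    threshold: float = 0.72
    min_tokens: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.threshold < 1:
            raise FeatureError(f"MTLD threshold must be in (0,1), got {self.threshold}")


def _mtld_directional(tokens: Sequence[str], threshold: float) -> float:
    """One directional MTLD pass; returns NaN if no factor ever closes."""
    factors = 0.0
    types: set[str] = set()
    count = 0
    for tok in tokens:
        count += 1
        types.add(tok)
        if len(types) / count < threshold:
            factors += 1.0
            types.clear()
            count = 0
    if count > 0:
        ttr_rem = len(types) / count
        if ttr_rem < 1.0:  # partial-factor correction
            factors += (1.0 - ttr_rem) / (1.0 - threshold)
    if factors == 0.0:
        return MISSING
    return len(tokens) / factors


def mtld(tokens: Sequence[str], config: MtldConfig = MtldConfig()) -> float:
    """Bidirectional measure of textual lexical diversity.

    Mean of the forward and reversed-sequence factor scores; the terminal
    partial factor counts as (1 - remaining TTR)/(1 - threshold).  Returns
    the missing sentinel when either direction never closes a factor (running
    TTR never drops below the threshold and ends at 1).
    """
    if not tokens:
        raise FeatureError("MTLD of an empty sequence")
    fwd = _mtld_directional(tokens, config.threshold)
    bwd = _mtld_directional(tokens[::-1], config.threshold)
    if np.isnan(fwd) or np.isnan(bwd):
        return MISSING
    return (fwd + bwd) / 2.0


def mtld_from_transcript(transcript: Transcript,
                         config: MtldConfig = MtldConfig()) -> float:
    return mtld([t.surface.lower() for t in transcript.content_stream()], config)


# ---------------------------------------------------------------------------
# Morphology & syntax
# ---------------------------------------------------------------------------

def morphological_complexity(transcript: Transcript) -> float:
    """Mean number of morphological attribute-value pairs per non-pause token."""
    toks = transcript.content_stream()
    if not toks:
        raise FeatureError("transcript has no non-filled-pause tokens")
    return float(np.mean([t.morph_count for t in toks]))


def syntactic_metrics(
    transcript: Transcript,
    connective_lexicon: frozenset[str] = lexicons.DISCOURSE_CONNECTIVES,
    subordinate_deprels: frozenset[str] = lexicons.SUBORDINATE_DEPRELS,
) -> dict[str, float]:
    """Subordination ratio and connective rate.

    Clauses per sentence = 1 (main) + number of subordinate-clause heads
    (tokens whose deprel, base form, is in ``subordinate_deprels``).
    Connectives are tokens with UPOS SCONJ/CCONJ or lemma in the lexicon;
    the rate is per sentence and may exceed 1.
    """
    if not connective_lexicon:
        raise FeatureError("empty connective lexicon")
    n_sent = len(transcript.sentences)
    sub = total = conn = 0
    for sent in transcript.sentences:
        heads = sum(
            lexicons.is_subordinate_deprel(t.deprel, subordinate_deprels)
            for t in sent.content_tokens()
        )
        sub += heads
        total += 1 + heads
        conn += sum(
            t.upos in ("SCONJ", "CCONJ") or t.lemma.lower() in connective_lexicon
            for t in sent.content_tokens()
        )
    return {
        "subordination_ratio": sub / total,
        "connective_ratio": conn / n_sent,
    }


@dataclass(frozen=True)
class ReadabilityCoefficients:
    """Linear reading-ease coefficients (German-adapted form).

    score = c0 - c1 * ASL - c2 * ASW with ASL the mean sentence length in
    tokens and ASW the mean syllables per word.  Higher = easier text.
    """

    c0: float = 180.0
    c1: float = 1.0
    c2: float = 58.5


def readability_index(
    transcript: Transcript,
    coefficients: ReadabilityCoefficients = ReadabilityCoefficients(),
    syllable_counter: Callable[[str], int] = lexicons.count_syllables,
) -> float:
    toks = transcript.content_stream()
    if not transcript.sentences or not toks:
        raise FeatureError("readability needs at least one sentence with words")
    asl = len(toks) / len(transcript.sentences)
    asw = float(np.mean([syllable_counter(t.surface) for t in toks]))
    c = coefficients
    return c.c0 - c.c1 * asl - c.c2 * asw


@dataclass(frozen=True)
class CorpusNorms:
    """Reference mean/sd of per-transcript mean sentence length and depth."""

    length_mean: float
    length_sd: float
    depth_mean: float
    depth_sd: float

    def __post_init__(self) -> None:
        if self.length_sd <= 0 or self.depth_sd <= 0:
            raise FeatureError("corpus norms need positive standard deviations")


def _length_depth_summary(transcript: Transcript) -> tuple[float, float]:
    lengths = [len(s.content_tokens()) for s in transcript.sentences]
    depths = [s.parse_depth() for s in transcript.sentences]
    return float(np.mean(lengths)), float(np.mean(depths))


def compute_corpus_norms(transcripts: Sequence[Transcript]) -> CorpusNorms:
    """Norms over a reference corpus (ddof=0; sd floor avoids degenerate 0)."""
    if len(transcripts) < 2:
        raise FeatureError("norms need at least 2 transcripts")
    summaries = np.array([_length_depth_summary(t) for t in transcripts])
    sds = summaries.std(axis=0)
    if np.any(sds <= 0):
        raise FeatureError("reference corpus has zero variance in length or depth")
    means = summaries.mean(axis=0)
    return CorpusNorms(length_mean=means[0], length_sd=sds[0],
                       depth_mean=means[1], depth_sd=sds[1])


def syntactic_complexity(transcript: Transcript, norms: CorpusNorms) -> float:
    """Mean of the z-scores of mean sentence length and mean max parse depth."""
    length, depth = _length_depth_summary(transcript)
    z_len = (length - norms.length_mean) / norms.length_sd
    z_dep = (depth - norms.depth_mean) / norms.depth_sd
    return (z_len + z_dep) / 2.0


# ---------------------------------------------------------------------------
# Semantic / embedding features
# ---------------------------------------------------------------------------

def _cosine(a: np.ndarray, b: np.ndarray) -> float | None:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return None
    return float(a @ b / (na * nb))


def _sentence_vectors(transcript: Transcript,
                      provider: EmbeddingProvider) -> list[np.ndarray]:
    vecs = []
    for sent in transcript.sentences:
        v = (provider.sentence_vector(sent)
             if hasattr(provider, "sentence_vector")
             else mean_word_sentence_vector(provider, sent))
        if v is None:
            v = mean_word_sentence_vector(provider, sent)
        if v is not None and np.linalg.norm(v) > 0:
            vecs.append(np.asarray(v, dtype=float))
    return vecs


def _mean_consecutive_cosine(vecs: list[np.ndarray]) -> float:
    if len(vecs) < 2:
        return MISSING
    M = np.vstack(vecs)
    norms = np.linalg.norm(M, axis=1)
    U = M / norms[:, None]
    sims = np.sum(U[:-1] * U[1:], axis=1)
    return float(np.mean(sims))


def coherence_features(
    transcript: Transcript,
    static_provider: EmbeddingProvider,
    contextual_provider: EmbeddingProvider,
) -> dict[str, float]:
    """Embedding-based coherence measures.

    - ``semantic_coherence_static``: mean cosine of consecutive sentence
      vectors from the static (word-vector averaging) provider.
    - ``sentence_coherence_contextual``: same with the contextual provider.
    - ``word_level_coherence``: mean cosine over consecutive embeddable
      non-pause word pairs in document order.
    - ``semantic_density``: mean cosine over all unordered pairs of
      embeddable content-word vectors.

    Unknown and zero-vector words are skipped from pairing; a measure with
    fewer than two usable units is the missing sentinel.
    """
    out: dict[str, float] = {}
    out["semantic_coherence_static"] = _mean_consecutive_cosine(
        _sentence_vectors(transcript, static_provider))
    out["sentence_coherence_contextual"] = _mean_consecutive_cosine(
        _sentence_vectors(transcript, contextual_provider))

    word_vecs = []
    for t in transcript.content_stream():
        v = static_provider.word_vector(t.surface.lower())
        if v is not None and np.linalg.norm(v) > 0:
            word_vecs.append(np.asarray(v, dtype=float))
    out["word_level_coherence"] = _mean_consecutive_cosine(word_vecs)

    content_vecs = []
    for t in transcript.content_stream():
        if t.is_content_word:
            v = static_provider.word_vector(t.surface.lower())
            if v is not None and np.linalg.norm(v) > 0:
                content_vecs.append(np.asarray(v, dtype=float))
    m = len(content_vecs)
    if m < 2:
        out["semantic_density"] = MISSING
    else:
        U = np.vstack(content_vecs)
        U = U / np.linalg.norm(U, axis=1)[:, None]
        s = U.sum(axis=0)
        # mean over all unordered pairs: (||sum u||^2 - m) / (m (m - 1))
        out["semantic_density"] = float((s @ s - m) / (m * (m - 1)))
    return out


# ---------------------------------------------------------------------------
# Word-graph cohesion
# ---------------------------------------------------------------------------

def build_word_graph(transcript: Transcript) -> nx.Graph:
    """Word-type adjacency graph.

    One node per lowercased non-pause word type; an undirected edge joins
    every pair of word types adjacent in the token stream within a sentence
    (filled pauses are transparent: their neighbours become adjacent).
    Immediate repetitions would be self-loops and are ignored.
    """
    g = nx.Graph()
    for sent in transcript.sentences:
        words = [t.surface.lower() for t in sent.content_tokens()]
        g.add_nodes_from(words)
        for a, b in zip(words, words[1:]):
            if a != b:
                g.add_edge(a, b)
    return g


def word_graph_cohesion(transcript: Transcript) -> float:
    """Average shortest path length of the word graph's largest component."""
    g = build_word_graph(transcript)
    if g.number_of_nodes() < 2:
        return MISSING
    component = max(nx.connected_components(g), key=len)
    if len(component) < 2:
        return MISSING
    sub = g.subgraph(component)
    adj = nx.to_scipy_sparse_array(sub, format="csr")
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    m = dist.shape[0]
    return float(dist.sum() / (m * (m - 1)))


# ---------------------------------------------------------------------------
# Disfluency & sentiment
# ---------------------------------------------------------------------------

def disfluency_features(
    transcript: Transcript,
    checker: GrammarChecker,
    repetition_skips_pauses: bool = True,
) -> dict[str, float]:
    """Filled-pause, repetition and grammatical-error rates.

    The filled-pause denominator includes the pauses themselves; the other
    two denominators count non-pause tokens only.  A repetition is a
    non-pause token equal (case-folded surface) to the previous non-pause
    token; with ``repetition_skips_pauses`` (default) an intervening filled
    pause does not break the pair.
    """
    all_toks = list(transcript.tokens())
    if not all_toks:
        raise FeatureError("transcript has no tokens")
    n_pause = sum(t.is_filled_pause for t in all_toks)
    stream = transcript.content_stream()
    if repetition_skips_pauses:
        pairs = zip(stream, stream[1:])
    else:  # pairs must be directly adjacent in the raw stream
        pairs = (
            (a, b) for a, b in zip(all_toks, all_toks[1:])
            if not a.is_filled_pause and not b.is_filled_pause
        )
    reps = sum(a.surface.lower() == b.surface.lower() for a, b in pairs)
    n_content = len(stream)
    errors = sum(checker.error_count(s) for s in transcript.sentences)
    return {
        "filled_pause_ratio": n_pause / len(all_toks),
        "repetition_ratio": reps / n_content if n_content else MISSING,
        "grammatical_error_ratio": errors / n_content if n_content else MISSING,
    }


def negative_sentiment(transcript: Transcript, model: SentimentModel) -> float:
    p = model.negative_probability(transcript)
    if not 0.0 <= p <= 1.0:
        raise FeatureError(
            f"sentiment adapter returned {p} outside [0,1] "
            f"for transcript {transcript.participant_id}"
        )
    return float(p)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """All tunables of the feature stage in one place."""

    mtld: MtldConfig = field(default_factory=MtldConfig)
    readability: ReadabilityCoefficients = field(default_factory=ReadabilityCoefficients)
    connective_lexicon: frozenset[str] = lexicons.DISCOURSE_CONNECTIVES
    subordinate_deprels: frozenset[str] = lexicons.SUBORDINATE_DEPRELS
    repetition_skips_pauses: bool = True


@dataclass
class FeatureProviders:
    """The three model adapters required by the semantic/disfluency features."""

    static_embeddings: EmbeddingProvider
    contextual_embeddings: EmbeddingProvider
    sentiment: SentimentModel
    grammar: GrammarChecker


def extract_features(
    transcript: Transcript,
    providers: FeatureProviders,
    norms: CorpusNorms,
    config: FeatureConfig | None = None,
) -> tuple[FeatureVector, dict[str, str]]:
    """Compute all 18 features; failures are recorded, not fatal.

    Returns the feature vector and a map feature-name -> error message for
    any feature whose computation failed (those fields hold the missing
    sentinel).  Deterministic given transcript, adapters and norms.
    """
    cfg = config or FeatureConfig()
    fv = FeatureVector()
    errors: dict[str, str] = {}

    def run(names: tuple[str, ...], fn: Callable[[], dict[str, float] | float]) -> None:
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - aggregate per-feature errors
            for n in names:
                errors[n] = str(exc)
            return
        if isinstance(result, dict):
            for n, v in result.items():
                setattr(fv, n, v)
        else:
            setattr(fv, names[0], result)

    run(("ttr", "pronoun_ratio", "personal_pronoun_ratio"),
        lambda: lexical_ratios(transcript))
    run(("mtld",), lambda: mtld_from_transcript(transcript, cfg.mtld))
    run(("morphological_complexity",),
        lambda: morphological_complexity(transcript))
    run(("subordination_ratio", "connective_ratio"),
        lambda: syntactic_metrics(transcript, cfg.connective_lexicon,
                                  cfg.subordinate_deprels))
    run(("readability",),
        lambda: readability_index(transcript, cfg.readability))
    run(("syntactic_complexity",),
        lambda: syntactic_complexity(transcript, norms))
    run(("semantic_coherence_static", "sentence_coherence_contextual",
         "word_level_coherence", "semantic_density"),
        lambda: coherence_features(transcript, providers.static_embeddings,
                                   providers.contextual_embeddings))
    run(("graph_cohesion",), lambda: word_graph_cohesion(transcript))
    run(("filled_pause_ratio", "repetition_ratio", "grammatical_error_ratio"),
        lambda: disfluency_features(transcript, providers.grammar,
                                    cfg.repetition_skips_pauses))
    run(("negative_sentiment",),
        lambda: negative_sentiment(transcript, providers.sentiment))
    return fv, errors
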