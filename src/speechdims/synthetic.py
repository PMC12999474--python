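"""Synthetic transcripts and cohorts with known latent structure.

The generator emulates the study design the pipeline targets: picture-elicited
spontaneous narratives of a few hundred to ~2500 words, a cohort of healthy
controls and patients with affective or psychotic disorders, three latent
speech dimensions (syntactic complexity; lexical diversity and fluency;
narrow thematic focus) correlated with three latent formal-thought-disorder
dimensions, and ROI-level brain measures with planted standardized effects.

The generated language is an abstract fixture language with German-like
structural knobs (subordination, connectives, filled pauses, Zipf
vocabulary), not German: feature extraction consumes only the gold
annotations, so no parser or embedding model is needed anywhere in the test
path.  Everything is a pure function of (config, master seed); per-participant
substreams are spawned by stable hashing of the participant id, so cohorts
are reproducible under subsetting.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import lexicons
from .corpus import (
    FTD_ITEMS,
    ParticipantRecord,
    Sentence,
    Token,
    Transcript,
)

SPEECH_FACTORS = ("syntactic_complexity", "lexical_diversity_fluency",
                  "narrow_thematic_focus")
FTD_FACTOR_NAMES = ("disorganization", "emptiness", "incoherence")


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def participant_rng(master_seed: int, participant_id: str) -> np.random.Generator:
    """Deterministic per-participant substream (stable across platforms)."""
    h = zlib.crc32(participant_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([master_seed, h]))


# ---------------------------------------------------------------------------
# Lexicon and embedding fixture
# ---------------------------------------------------------------------------

_SYLLABLES = ("ba", "de", "ki", "lo", "mu", "na", "po", "re", "si", "tu",
              "ve", "za", "fe", "go", "hi")


@dataclass(frozen=True)
class LexiconEntry:
    word: str
    upos: str
    topic: int            # -1 for topic-neutral function words
    morph_mean: float     # Poisson mean of the morphological feature count
    zipf_rank: int


@dataclass
class Lexicon:
    """Topic-structured synthetic vocabulary."""

    entries: list[LexiconEntry]
    n_topics: int
    connectives_cc: list[str]
    connectives_sc: list[str]
    filled_pauses: list[str]
    pronouns: list[str]
    personal_pronouns: list[str]
    negative_words: list[str]

    # per-topic content words sorted by zipf rank (built in __post_init__)
    topic_words: dict[int, list[LexiconEntry]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries or not self.connectives_cc or not self.filled_pauses:
            raise ValueError("lexicon lists must be nonempty")
        self.topic_words = {t: [] for t in range(self.n_topics)}
        for e in self.entries:
            if e.topic >= 0:
                self.topic_words[e.topic].append(e)
        for t in self.topic_words:
            self.topic_words[t].sort(key=lambda e: e.zipf_rank)

    def zipf_probs(self, topic: int, exponent: float) -> np.ndarray:
        ranks = np.arange(1, len(self.topic_words[topic]) + 1, dtype=float)
        w = ranks ** (-exponent)
        return w / w.sum()


class FixtureEmbedding:
    """Deterministic word-embedding fixture with topic geometry.

    ``vector(word) = normalize(topic_direction + sigma * noise(word))`` where
    the per-word noise is keyed by a stable hash of the word and the provider
    salt, and topic directions are mutually orthogonal basis vectors.  With
    ``sigma = 0`` same-topic words have cosine exactly 1 and cross-topic
    words cosine 0.
    """

    def __init__(self, lexicon: Lexicon, dimension: int = 50,
                 sigma: float = 0.5, salt: int = 0):
        if dimension < lexicon.n_topics + 1:
            raise ValueError("embedding dimension must exceed the topic count")
        self.dimension = dimension
        self.sigma = sigma
        self._vectors: dict[str, np.ndarray] = {}
        words: list[tuple[str, int]] = [(e.word, e.topic) for e in lexicon.entries]
        extra_topic = lexicon.n_topics  # shared direction for function words
        for wlist in (lexicon.connectives_cc, lexicon.connectives_sc,
                      lexicon.pronouns):
            words.extend((w, -1) for w in wlist)
        # negative words blend into the ordinary topic geometry so affect
        # sentiment without distorting the content-word similarity structure
        words.extend((w, i % lexicon.n_topics)
                     for i, w in enumerate(lexicon.negative_words))
        for word, topic in words:
            if word in self._vectors:
                continue
            direction = np.zeros(dimension)
            direction[topic if topic >= 0 else extra_topic] = 1.0
            wrng = np.random.default_rng(
                np.random.SeedSequence([salt, zlib.crc32(word.encode())]))
            noise = wrng.standard_normal(dimension) / np.sqrt(dimension)
            v = direction + sigma * noise
            n = np.linalg.norm(v)
            self._vectors[word] = v / n if n > 0 else direction

    def word_vector(self, word: str) -> np.ndarray | None:
        return self._vectors.get(word)

    def sentence_vector(self, sentence: Sentence) -> np.ndarray | None:
        vecs = [v for t in sentence.content_tokens()
                if (v := self._vectors.get(t.surface.lower())) is not None]
        if not vecs:
            return None
        return np.mean(vecs, axis=0)


@dataclass
class LexiconConfig:
    n_topics: int = 4             # one notional picture prompt per topic
    words_per_topic: int = 120
    embedding_dim: int = 50
    embedding_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.n_topics < 2:
            raise ValueError("need at least 2 topics")
        if self.n_topics * self.words_per_topic < 50:
            raise ValueError("vocabulary too small for the requested topic count")


_UPOS_CYCLE = ("NOUN", "VERB", "NOUN", "ADJ", "NOUN", "VERB", "ADV", "NOUN")
_MORPH_MEAN = {"NOUN": 2.2, "VERB": 3.0, "ADJ": 1.8, "ADV": 0.4,
               "PRON": 2.5, "SCONJ": 0.0, "CCONJ": 0.0, "INTJ": 0.0}


def build_lexicon(config: LexiconConfig | None = None, seed: int = 0
                  ) -> tuple[Lexicon, FixtureEmbedding, FixtureEmbedding]:
    """Deterministic lexicon plus a static and a contextual embedding fixture.

    The two embedding fixtures share the topic geometry but differ in salt
    and dimension, standing in for the static-word-vector and contextual
    sentence-embedding models of a real deployment.
    """
    cfg = config or LexiconConfig()
    rng = np.random.default_rng(seed)
    entries: list[LexiconEntry] = []
    for t in range(cfg.n_topics):
        for r in range(cfg.words_per_topic):
            n_syll = 1 + int(rng.integers(0, 3))
            word = f"t{t}" + "".join(
                _SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), n_syll))
            upos = _UPOS_CYCLE[r % len(_UPOS_CYCLE)]
            entries.append(LexiconEntry(
                word=word, upos=upos, topic=t,
                morph_mean=_MORPH_MEAN[upos], zipf_rank=r + 1))
    lex = Lexicon(
        entries=entries,
        n_topics=cfg.n_topics,
        connectives_cc=["und", "aber", "oder", "denn"],
        connectives_sc=["weil", "obwohl", "dass", "wenn", "während"],
        filled_pauses=list(lexicons.FILLED_PAUSES)[:4],
        pronouns=["er", "sie", "es", "ich", "wir", "man", "das"],
        personal_pronouns=["ich", "wir"],
        negative_words=sorted(lexicons.NEGATIVE_WORDS)[:12],
    )
    static = FixtureEmbedding(lex, dimension=cfg.embedding_dim,
                              sigma=cfg.embedding_sigma, salt=101)
    contextual = FixtureEmbedding(lex, dimension=max(16, cfg.embedding_dim // 2),
                                  sigma=cfg.embedding_sigma, salt=202)
    return lex, static, contextual


# ---------------------------------------------------------------------------
# Speaker profiles: latent factors -> generator parameters
# ---------------------------------------------------------------------------

@dataclass
class SpeakerProfile:
    """Generator parameters for one speaker.

    Derived from the three latent speech factors by monotone logistic /
    exponential links whose slopes are calibrated so a 1 SD latent shift
    moves each primary feature by roughly half of its cohort SD.
    """

    eta: np.ndarray                      # latent (A, B, C)
    mean_sentence_length: float          # tokens per main clause core
    chain_prob: float                    # P(attach to previous token): depth
    subordination_prob: float            # P(subordinate clause | slot)
    connective_rate: float               # expected connectives per sentence
    topic_drift_hazard: float            # P(switch topic at sentence start)
    vocab_exponent: float                # Zipf exponent s: P(rank) ~ rank^-s
    filled_pause_rate: float             # per-token insertion probability
    repetition_rate: float
    grammar_error_rate: float
    morph_scale: float                   # multiplier on morph-count means
    pronoun_sub_prob: float              # P(noun replaced by a pronoun)
    topic_concentration: float           # P(word drawn from current topic)
    negative_word_rate: float
    target_words_mean: float = 1139.0    # corpus calibration
    target_words_sd: float = 370.0
    target_words_range: tuple[float, float] = (250.0, 2400.0)

    @classmethod
    def from_latent(cls, eta: np.ndarray) -> "SpeakerProfile":
        a, b, c = (float(x) for x in eta)
        return cls(
            eta=np.asarray(eta, dtype=float),
            mean_sentence_length=float(np.clip(13.0 * np.exp(0.22 * a), 6, 36)),
            chain_prob=float(np.clip(_sigmoid(0.2 + 0.6 * a), 0.05, 0.95)),
            subordination_prob=_sigmoid(-0.4 + 0.9 * a),
            connective_rate=float(np.exp(0.2 + 0.55 * a)),
            topic_drift_hazard=_sigmoid(-0.8 - 0.5 * a),
            vocab_exponent=float(np.clip(1.05 - 0.28 * b, 0.3, 2.0)),
            filled_pause_rate=_sigmoid(-2.2 - 0.8 * b),
            repetition_rate=_sigmoid(-3.8 - 0.15 * b),
            grammar_error_rate=_sigmoid(-3.2 - 0.6 * b),
            morph_scale=float(np.exp(0.18 * b)),
            pronoun_sub_prob=_sigmoid(-1.1 + 0.9 * c),
            topic_concentration=float(np.clip(_sigmoid(1.0 + 1.4 * c), 0.3, 0.98)),
            negative_word_rate=0.03,
        )

    def validate(self) -> None:
        for name in ("chain_prob", "subordination_prob", "topic_drift_hazard",
                     "filled_pause_rate", "repetition_rate",
                     "grammar_error_rate", "pronoun_sub_prob",
                     "topic_concentration"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0,1]")
        if self.mean_sentence_length <= 0:
            raise ValueError("degenerate profile: zero sentence length")


# ---------------------------------------------------------------------------
# Transcript generation
# ---------------------------------------------------------------------------

def _sample_target_words(profile: SpeakerProfile,
                         rng: np.random.Generator) -> int:
    lo, hi = profile.target_words_range
    for _ in range(100):
        x = rng.normal(profile.target_words_mean, profile.target_words_sd)
        if lo <= x <= hi:
            return int(x)
    return int(np.clip(profile.target_words_mean, lo, hi))


def _generate_sentence(profile: SpeakerProfile, lexicon: Lexicon,
                       rng: np.random.Generator, topic: int,
                       index: int,
                       cum_probs: dict[int, np.ndarray] | None = None) -> Sentence:
    tokens: list[Token] = []
    last_content_idx = 0     # 1-based index of last non-pause token
    if cum_probs is None:
        cum_probs = {t: np.cumsum(lexicon.zipf_probs(t, profile.vocab_exponent))
                     for t in range(lexicon.n_topics)}

    def emit(tok: Token) -> int:
        tokens.append(tok)
        return len(tokens)

    def content_word(cur_topic: int) -> LexiconEntry:
        if rng.random() >= profile.topic_concentration:
            cur_topic = int(rng.integers(0, lexicon.n_topics))
        words = lexicon.topic_words[cur_topic]
        j = int(np.searchsorted(cum_probs[cur_topic], rng.random()))
        return words[min(j, len(words) - 1)]

    def morph(upos: str) -> int:
        base = _MORPH_MEAN.get(upos, 0.5)
        return int(rng.poisson(base * profile.morph_scale))

    def decorate(tok: Token) -> Token:
        """Apply error marks, then trailing pause/repetition insertions."""
        if rng.random() < profile.grammar_error_rate:
            tok = Token(**{**tok.__dict__, "deprel": tok.deprel + ":err"})
        return tok

    def maybe_insert_extras(prev_idx: int) -> None:
        nonlocal last_content_idx
        if rng.random() < profile.repetition_rate:
            prev = tokens[prev_idx - 1]
            head = prev.head if prev.head != 0 else prev_idx
            last_content_idx = emit(Token(
                surface=prev.surface, lemma=prev.lemma, upos=prev.upos,
                morph_count=prev.morph_count, head=head, deprel="reparandum",
                is_personal_pronoun=prev.is_personal_pronoun,
                topic_tag=prev.topic_tag))
        if rng.random() < profile.filled_pause_rate:
            pause = lexicon.filled_pauses[
                int(rng.integers(0, len(lexicon.filled_pauses)))]
            emit(Token(surface=pause, lemma=pause, upos="INTJ", head=0,
                       deprel="discourse", is_filled_pause=True))

    topic_str = str(topic)
    # --- main clause ---
    root_entry = content_word(topic)
    root_idx = emit(decorate(Token(
        surface=root_entry.word, lemma=root_entry.word, upos="VERB",
        morph_count=morph("VERB"), head=0, deprel="root",
        topic_tag=topic_str)))
    last_content_idx = root_idx
    maybe_insert_extras(root_idx)

    n_main = max(3, int(rng.poisson(0.72 * profile.mean_sentence_length)))
    conn_prob = min(0.9, profile.connective_rate /
                    max(profile.mean_sentence_length, 1.0))
    for _ in range(n_main - 1):
        if rng.random() < conn_prob:
            cc = lexicon.connectives_cc[
                int(rng.integers(0, len(lexicon.connectives_cc)))]
            last_content_idx = emit(decorate(Token(
                surface=cc, lemma=cc, upos="CCONJ", morph_count=0,
                head=root_idx, deprel="cc", topic_tag=topic_str)))
            maybe_insert_extras(last_content_idx)
            continue
        entry = content_word(topic)
        if entry.upos == "NOUN" and rng.random() < profile.pronoun_sub_prob:
            pron = lexicon.pronouns[int(rng.integers(0, len(lexicon.pronouns)))]
            tok = Token(surface=pron, lemma=pron, upos="PRON",
                        morph_count=morph("PRON"),
                        head=(last_content_idx if rng.random() < profile.chain_prob
                              else root_idx),
                        deprel="nsubj",
                        is_personal_pronoun=pron in lexicon.personal_pronouns,
                        topic_tag=topic_str)
        else:
            surface = entry.word
            lemma = entry.word
            upos = entry.upos
            if rng.random() < profile.negative_word_rate:
                neg = lexicon.negative_words[
                    int(rng.integers(0, len(lexicon.negative_words)))]
                surface = lemma = neg
                upos = "ADJ"
            tok = Token(surface=surface, lemma=lemma, upos=upos,
                        morph_count=morph(upos),
                        head=(last_content_idx if rng.random() < profile.chain_prob
                              else root_idx),
                        deprel="amod" if upos == "ADJ" else "dep",
                        topic_tag=topic_str)
        last_content_idx = emit(decorate(tok))
        maybe_insert_extras(last_content_idx)

    # --- subordinate clauses ---
    for _ in range(2):
        if rng.random() >= profile.subordination_prob:
            continue
        sc = lexicon.connectives_sc[
            int(rng.integers(0, len(lexicon.connectives_sc)))]
        emit(decorate(Token(surface=sc, lemma=sc, upos="SCONJ", morph_count=0,
                            head=root_idx, deprel="mark",
                            topic_tag=topic_str)))
        sub_entry = content_word(topic)
        sub_head = emit(decorate(Token(
            surface=sub_entry.word, lemma=sub_entry.word, upos="VERB",
            morph_count=morph("VERB"), head=last_content_idx,
            deprel="advcl", topic_tag=topic_str)))
        attach = sub_head
        for _ in range(2 + int(rng.poisson(0.18 * profile.mean_sentence_length))):
            entry = content_word(topic)
            attach = emit(decorate(Token(
                surface=entry.word, lemma=entry.word, upos=entry.upos,
                morph_count=morph(entry.upos),
                head=(attach if rng.random() < profile.chain_prob else sub_head),
                deprel="dep", topic_tag=topic_str)))
            maybe_insert_extras(attach)
        last_content_idx = attach

    return Sentence(tokens=tuple(tokens), index=index)


def generate_transcript(profile: SpeakerProfile, lexicon: Lexicon,
                        seed: int | np.random.Generator,
                        participant_id: str = "synthetic") -> Transcript:
    """Generate one gold-annotated transcript from a speaker profile."""
    profile.validate()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    target = _sample_target_words(profile, rng)
    cum_probs = {t: np.cumsum(lexicon.zipf_probs(t, profile.vocab_exponent))
                 for t in range(lexicon.n_topics)}
    sentences: list[Sentence] = []
    home = int(rng.integers(0, lexicon.n_topics))
    topic = home
    # narrow focus: on drift, the home topic attracts with this probability,
    # concentrating the global topic distribution of the narrative
    focus = profile.topic_concentration
    emitted = 0
    while emitted < target:
        if sentences and rng.random() < profile.topic_drift_hazard:
            if topic != home and rng.random() < focus:
                topic = home
            else:
                others = [t for t in range(lexicon.n_topics) if t != topic]
                topic = others[int(rng.integers(0, len(others)))]
        sent = _generate_sentence(profile, lexicon, rng, topic, len(sentences),
                                  cum_probs)
        sentences.append(sent)
        emitted += len(sent)
    return Transcript(participant_id=participant_id,
                      sentences=tuple(sentences))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

def _default_cross_corr() -> np.ndarray:
    # planted speech (rows) x FTD (cols) latent correlations, mirroring the
    # negative syntactic-complexity/FTD and diversity/emptiness pattern
    return np.array([
        [-0.30, -0.25, -0.22],
        [-0.10, -0.28, -0.10],
        [0.00, 0.00, 0.00],
    ])


def _default_planted_betas() -> dict[str, np.ndarray]:
    return {
        "gmv_right_posterior_insula": np.array([0.0, 0.0, -0.16]),
        "fa_left_atr": np.array([-0.18, -0.35, 0.0]),
        "fa_right_atr": np.array([0.0, -0.33, 0.0]),
        "fa_left_uf": np.array([-0.23, -0.30, 0.0]),
        "fa_right_ilf": np.array([0.0, -0.27, 0.0]),
        "fa_right_slf": np.array([0.0, -0.30, 0.0]),
        "fa_left_cst": np.array([0.0, 0.0, -0.21]),
        "fa_null_control": np.array([0.0, 0.0, 0.0]),
    }


@dataclass
class CohortConfig:
    """Everything the cohort generator needs to know."""

    group_sizes: dict[str, int] = field(default_factory=lambda: {
        "HC": 178, "affective": 146, "psychotic": 48})
    speech_corr: float = 0.30       # within-speech latent correlation
    ftd_corr: float = 0.40          # within-FTD latent correlation
    cross_corr: np.ndarray = field(default_factory=_default_cross_corr)
    #: additive latent mean shifts per group (speech 3 + FTD 3)
    group_shifts: dict[str, np.ndarray] = field(default_factory=lambda: {
        "HC": np.array([0.15, 0.15, -0.05, -0.45, -0.45, -0.45]),
        "affective": np.array([-0.10, -0.10, 0.00, 0.25, 0.30, 0.20]),
        "psychotic": np.array([-0.35, -0.35, 0.20, 0.95, 0.90, 1.00]),
    })
    planted_betas: dict[str, np.ndarray] = field(
        default_factory=_default_planted_betas)
    #: standardized covariate effects on every ROI outcome
    roi_covariate_effects: dict[str, float] = field(default_factory=lambda: {
        "age": -0.15, "sex_m": 0.10, "tiv": 0.20,
        "affective": -0.10, "psychotic": -0.20})
    sex_female_prob: dict[str, float] = field(default_factory=lambda: {
        "HC": 114 / 178, "affective": 91 / 146, "psychotic": 18 / 48})
    ftd_missing_prob: float = 8 / 372   # mirrors the study's missing-item rate
    #: graded-response category thresholds on the item latent; the default is
    #: floor-skewed, as clinical ratings are in a mixed cohort whose healthy
    #: majority scores 0
    item_thresholds: np.ndarray = field(
        default_factory=lambda: np.array([0.9, 1.6, 2.3, 3.0, 3.7]))
    generate_transcripts: bool = True

    def latent_covariance(self) -> np.ndarray:
        S = np.full((3, 3), self.speech_corr)
        np.fill_diagonal(S, 1.0)
        F = np.full((3, 3), self.ftd_corr)
        np.fill_diagonal(F, 1.0)
        C = np.asarray(self.cross_corr, dtype=float)
        top = np.hstack([S, C])
        bottom = np.hstack([C.T, F])
        return np.vstack([top, bottom])

    @classmethod
    def planted_correlation_study(cls, rho: float = -0.3, n: int = 300
                                  ) -> "CohortConfig":
        """A cohort whose only speech-FTD linkage is one planted correlation.

        Group mean shifts are zeroed so the marginal latent correlation
        equals the planted value exactly; the correlation is planted on the
        (syntactic complexity, disorganization) pair.
        """
        cross = np.zeros((3, 3))
        cross[0, 0] = rho
        sizes = {"HC": n - 2 * (n // 3), "affective": n // 3, "psychotic": n // 3}
        zero = np.zeros(6)
        # with zero group shifts the item latents are standard normal, so the
        # rating categories span the population range symmetrically (a
        # dimensional-rating design rather than a clinical floor)
        return cls(group_sizes=sizes, cross_corr=cross,
                   group_shifts={g: zero for g in sizes},
                   item_thresholds=np.array([-1.5, -0.75, 0.0, 0.75, 1.5]))


@dataclass
class CohortGroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    eta: np.ndarray                 # n x 3 speech latents
    ftd_latent: np.ndarray          # n x 3 FTD latents
    latent_covariance: np.ndarray   # the 6 x 6 generating covariance
    planted_betas: dict[str, np.ndarray]
    master_seed: int
    participant_ids: list[str]


_ITEM_FACTOR = {item: f for item, f in zip(
    FTD_ITEMS,
    # SANS items load on emptiness; SAPS split between disorganization
    # and incoherence (same default map the CFA uses)
    ["emptiness"] * 4
    + ["disorganization", "disorganization", "incoherence", "incoherence",
       "disorganization", "disorganization", "disorganization", "incoherence"],
)}
def _ordinal_item(latent: float, noise: float,
                  thresholds: np.ndarray) -> float:
    return float(np.searchsorted(thresholds, latent + noise))


def generate_cohort(config: CohortConfig | None = None, seed: int = 0,
                    lexicon_config: LexiconConfig | None = None
                    ) -> dict[str, object]:
    """Generate a full synthetic study.

    Returns a dict with ``transcripts`` (list, empty when disabled),
    ``records`` (ParticipantRecords with FTD items, covariates and ROI
    values), ``truth`` (CohortGroundTruth), and the embedding fixtures
    (``static_embeddings``, ``contextual_embeddings``) plus the ``lexicon``.
    """
    cfg = config or CohortConfig()
    cov = cfg.latent_covariance()
    eigmin = np.min(np.linalg.eigvalsh(cov))
    if eigmin < -1e-10:
        raise ValueError(
            f"latent covariance not positive semidefinite (min eig {eigmin:.3g})")
    lexicon, static, contextual = build_lexicon(lexicon_config, seed=12345)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(6))

    ids, groups = [], []
    for g, size in cfg.group_sizes.items():
        for i in range(size):
            ids.append(f"{g}-{i:03d}")
            groups.append(g)

    n = len(ids)
    latents = np.empty((n, 6))
    records: list[ParticipantRecord] = []
    transcripts: list[Transcript] = []
    gamma = cfg.roi_covariate_effects

    for i, (pid, g) in enumerate(zip(ids, groups)):
        prng = participant_rng(seed, pid)
        z = chol @ prng.standard_normal(6)
        z = z + cfg.group_shifts[g]
        latents[i] = z
        eta, ftd = z[:3], z[3:]

        # covariates
        age = float(np.clip(prng.normal(44.0, 13.0), 18, 69))
        sex = "f" if prng.random() < cfg.sex_female_prob[g] else "m"
        tiv = float(prng.normal(1545.0, 150.0))
        viq = float(np.clip(prng.normal(115.0, 14.0), 80, 160))
        med = 0.0 if g == "HC" else float(prng.lognormal(0.0, 0.6))

        # ordinal FTD items (graded thresholds; a few participants missing)
        items: dict[str, float] = {}
        missing = prng.random() < cfg.ftd_missing_prob
        for item in FTD_ITEMS:
            if missing:
                items[item] = float("nan")
                continue
            f_idx = FTD_FACTOR_NAMES.index(_ITEM_FACTOR[item])
            items[item] = _ordinal_item(0.9 * ftd[f_idx],
                                        float(prng.normal(0.0, 0.6)),
                                        cfg.item_thresholds)

        # ROI outcomes with planted standardized effects
        z_age = (age - 44.0) / 13.0
        z_tiv = (tiv - 1545.0) / 150.0
        z_sex = 1.0 if sex == "m" else 0.0
        brain: dict[str, float] = {}
        for roi, beta in cfg.planted_betas.items():
            fixed = (gamma["age"] * z_age + gamma["sex_m"] * z_sex
                     + gamma.get(g, 0.0))
            fixed += gamma["tiv"] * z_tiv
            explained = (gamma["age"] ** 2 + gamma["sex_m"] ** 2 * 0.25
                         + gamma["tiv"] ** 2
                         + float(beta @ cov[:3, :3] @ beta))
            sd_eps = float(np.sqrt(max(0.15, 1.0 - explained)))
            brain[roi] = fixed + float(beta @ eta) + sd_eps * float(prng.normal())

        rec = ParticipantRecord(
            participant_id=pid, group=g, age=age, sex=sex, tiv=tiv,
            verbal_iq=viq, medication_index=med, ftd_items=items, brain=brain)
        records.append(rec)

        if cfg.generate_transcripts:
            profile = SpeakerProfile.from_latent(eta)
            transcripts.append(
                generate_transcript(profile, lexicon, prng, participant_id=pid))

    truth = CohortGroundTruth(
        eta=latents[:, :3], ftd_latent=latents[:, 3:],
        latent_covariance=cov, planted_betas=dict(cfg.planted_betas),
        master_seed=seed, participant_ids=ids)
    return {
        "transcripts": transcripts,
        "records": records,
        "truth": truth,
        "lexicon": lexicon,
        "static_embeddings": static,
        "contextual_embeddings": contextual,
    }


#: Primary-marker link directions of the generator: feature -> (factor, sign).
#: Factor 0 = syntactic complexity, 1 = lexical diversity/fluency,
#: 2 = narrow thematic focus.
PRIMARY_MARKER_SIGNS: dict[str, tuple[int, float]] = {
    "subordination_ratio": (0, +1.0),
    "connective_ratio": (0, +1.0),
    "syntactic_complexity": (0, +1.0),
    "readability": (0, -1.0),
    "semantic_coherence_static": (0, +1.0),
    "ttr": (1, +1.0),
    "mtld": (1, +1.0),
    "graph_cohesion": (1, +1.0),
    "filled_pause_ratio": (1, -1.0),
    "pronoun_ratio": (2, +1.0),
    "semantic_density": (2, +1.0),
    "word_level_coherence": (2, +1.0),
}


def expected_sign_pattern(feature_names: list[str]) -> np.ndarray:
    """Target loading-sign matrix (rows = features) for alignment checks."""
    target = np.zeros((len(feature_names), 3))
    for i, name in enumerate(feature_names):
        if name in PRIMARY_MARKER_SIGNS:
            j, s = PRIMARY_MARKER_SIGNS[name]
            target[i, j] = s
    return target


def table_like_loading_design(p: int = 18, k: int = 3,
                              phi_offdiag: float = 0.3
                              ) -> tuple[np.ndarray, np.ndarray]:
    """A study-shaped loading design: p features, k factors, simple structure.

    Each factor owns ``p // k`` features with primary loadings spaced over
    0.5-0.8 and zero cross-loadings; factors correlate at ``phi_offdiag``.
    Returns (loadings, phi).
    """
    per = p // k
    L = np.zeros((p, k))
    for j in range(k):
        rows = slice(j * per, (j + 1) * per if j < k - 1 else p)
        n_rows = rows.stop - rows.start
        L[rows, j] = np.linspace(0.5, 0.8, n_rows)
    phi = np.full((k, k), phi_offdiag)
    np.fill_diagonal(phi, 1.0)
    return L, phi


def simulate_factor_model(loadings: np.ndarray, phi: np.ndarray, n: int,
                          seed: int) -> np.ndarray:
    """Draw an n x p data matrix exactly from a common-factor model.

    X = F L' + E with F ~ N(0, phi) and unique variances 1 - diag(L phi L').
    """
    L = np.asarray(loadings, dtype=float)
    phi = np.asarray(phi, dtype=float)
    rng = np.random.default_rng(seed)
    p, k = L.shape
    h2 = np.diag(L @ phi @ L.T)
    if np.any(h2 >= 1.0):
        raise ValueError("communalities must be < 1")
    F = rng.multivariate_normal(np.zeros(k), phi, size=n,
                                method="cholesky")
    E = rng.standard_normal((n, p)) * np.sqrt(1.0 - h2)
    return F @ L.T + E


def simulate_roi_study(beta: float, n: int, seed: int,
                       include_covariates: bool = True) -> dict[str, object]:
    """Minimal ROI calibration draw: one factor, covariates, one outcome.

    The factor is standard normal and independent of the covariates, so the
    planted ``beta`` is exactly the standardized adjusted coefficient.
    Returns plain arrays ready for :func:`speechdims.associations.roi_association`.
    """
    rng = np.random.default_rng(seed)
    eta = rng.standard_normal(n)
    age = rng.normal(44, 13, n)
    sex = rng.random(n) < 0.6
    tiv = rng.normal(1545, 150, n)
    group = rng.choice(["HC", "affective", "psychotic"], size=n,
                       p=[0.5, 0.37, 0.13])
    g_aff = (group == "affective").astype(float)
    g_psy = (group == "psychotic").astype(float)
    coefs = {"age": -0.15, "sex": 0.10, "tiv": 0.20,
             "aff": -0.10, "psy": -0.20} if include_covariates else \
            {"age": 0.0, "sex": 0.0, "tiv": 0.0, "aff": 0.0, "psy": 0.0}
    fixed = (coefs["age"] * (age - 44) / 13
             + coefs["sex"] * sex.astype(float)
             + coefs["tiv"] * (tiv - 1545) / 150
             + coefs["aff"] * g_aff + coefs["psy"] * g_psy)
    explained = (coefs["age"] ** 2 + coefs["sex"] ** 2 * 0.24
                 + coefs["tiv"] ** 2
                 + coefs["aff"] ** 2 * 0.37 * 0.63
                 + coefs["psy"] ** 2 * 0.13 * 0.87 + beta ** 2)
    sd_eps = np.sqrt(max(0.1, 1.0 - explained))
    y = fixed + beta * eta + sd_eps * rng.standard_normal(n)
    return {"y": y, "factor": eta, "age": age,
            "sex": np.where(sex, "m", "f"), "tiv": tiv, "group": group}
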