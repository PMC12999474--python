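"""Data model and I/O for annotated speech transcripts and cohort tables.

Transcripts are held as dependency-annotated token sequences (Universal
Dependencies conventions: 1-based token ids, ``HEAD == 0`` marks the root,
morphological features as ``Attr=Val`` pairs).  Filled pauses are real tokens
flagged via the MISC column (``FilledPause=Yes``); they are never deleted at
parse time — every downstream feature decides for itself whether to include
them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Open-class UPOS tags counted as content words.
CONTENT_UPOS = frozenset({"NOUN", "PROPN", "VERB", "ADJ", "ADV"})

#: Sentinel for a feature value that could not be computed for a transcript.
MISSING = float("nan")


def is_missing(value: float) -> bool:
    """True if ``value`` is the missing-value sentinel (NaN)."""
    return isinstance(value, float) and np.isnan(value)


class CorpusError(ValueError):
    """Malformed transcript input (parse or validation failure)."""


@dataclass(frozen=True)
class Token:
    """One token of a transcript with its gold linguistic annotation."""

    surface: str
    lemma: str
    upos: str
    morph_count: int = 0
    head: int = 0
    deprel: str = "root"
    is_filled_pause: bool = False
    is_personal_pronoun: bool = False
    topic_tag: str | None = None

    @property
    def is_pronoun(self) -> bool:
        return self.upos == "PRON"

    @property
    def is_content_word(self) -> bool:
        return self.upos in CONTENT_UPOS and not self.is_filled_pause

    def __post_init__(self) -> None:
        if self.morph_count < 0:
            raise CorpusError(f"negative morph_count for token {self.surface!r}")
        if self.is_personal_pronoun and self.upos != "PRON":
            raise CorpusError(
                f"token {self.surface!r} marked personal pronoun but UPOS is {self.upos}"
            )


@dataclass(frozen=True)
class Sentence:
    """An ordered token sequence forming one dependency tree.

    The tree is defined over non-filled-pause tokens; filled pauses attach
    nowhere (head 0, deprel ``discourse``) and are excluded from tree
    validation.
    """

    tokens: tuple[Token, ...]
    index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        self.validate()

    def validate(self) -> None:
        n = len(self.tokens)
        content_positions = [
            i for i, t in enumerate(self.tokens, start=1) if not t.is_filled_pause
        ]
        if not content_positions:
            return
        roots = 0
        for i, tok in enumerate(self.tokens, start=1):
            if tok.is_filled_pause:
                continue
            if tok.head == i:
                raise CorpusError(f"token {i} ({tok.surface!r}) is its own head")
            if not 0 <= tok.head <= n:
                raise CorpusError(f"token {i} has out-of-range head {tok.head}")
            if tok.head == 0:
                roots += 1
        if roots != 1:
            raise CorpusError(
                f"sentence {self.index}: expected exactly 1 root, found {roots}"
            )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        for i, tok in enumerate(self.tokens, start=1):
            if tok.is_filled_pause:
                continue
            seen = set()
            j, cur = i, tok
            while cur.head != 0:
                if cur.head in seen:
                    raise CorpusError(f"dependency cycle involving token {i}")
                seen.add(j)
                j = cur.head
                cur = self.tokens[j - 1]
                if cur.is_filled_pause:
                    raise CorpusError(f"token head {j} points at a filled pause")

    def content_tokens(self) -> list[Token]:
        """Tokens excluding filled pauses (the dependency-tree carriers)."""
        return [t for t in self.tokens if not t.is_filled_pause]

    def parse_depth(self) -> int:
        """Maximum root-to-leaf arc count of the dependency tree."""
        depths = {}
        for i, tok in enumerate(self.tokens, start=1):
            if tok.is_filled_pause:
                continue
            d, j = 0, i
            while self.tokens[j - 1].head != 0:
                j = self.tokens[j - 1].head
                d += 1
            depths[i] = d
        return max(depths.values(), default=0)

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class Transcript:
    """A participant's full (multi-picture) speech sample."""

    participant_id: str
    sentences: tuple[Sentence, ...]
    language: str = "de"
    picture_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sentences", tuple(self.sentences))
        if not self.sentences:
            raise CorpusError(f"transcript {self.participant_id}: no sentences")
        if self.n_tokens == 0:
            raise CorpusError(f"transcript {self.participant_id}: no tokens")

    @property
    def n_tokens(self) -> int:
        return sum(len(s) for s in self.sentences)

    def tokens(self) -> Iterable[Token]:
        for s in self.sentences:
            yield from s.tokens

    def content_stream(self) -> list[Token]:
        """All non-filled-pause tokens in document order."""
        return [t for t in self.tokens() if not t.is_filled_pause]


#: Canonical feature-column order of the extracted speech-feature table.
FEATURE_NAMES: tuple[str, ...] = (
    "ttr",
    "mtld",
    "pronoun_ratio",
    "personal_pronoun_ratio",
    "morphological_complexity",
    "syntactic_complexity",
    "subordination_ratio",
    "readability",
    "connective_ratio",
    "semantic_coherence_static",
    "sentence_coherence_contextual",
    "word_level_coherence",
    "semantic_density",
    "graph_cohesion",
    "filled_pause_ratio",
    "repetition_ratio",
    "grammatical_error_ratio",
    "negative_sentiment",
)


@dataclass
class FeatureVector:
    """The 18 per-participant speech metrics; NaN marks a missing value."""

    ttr: float = MISSING
    mtld: float = MISSING
    pronoun_ratio: float = MISSING
    personal_pronoun_ratio: float = MISSING
    morphological_complexity: float = MISSING
    syntactic_complexity: float = MISSING
    subordination_ratio: float = MISSING
    readability: float = MISSING
    connective_ratio: float = MISSING
    semantic_coherence_static: float = MISSING
    sentence_coherence_contextual: float = MISSING
    word_level_coherence: float = MISSING
    semantic_density: float = MISSING
    graph_cohesion: float = MISSING
    filled_pause_ratio: float = MISSING
    repetition_ratio: float = MISSING
    grammatical_error_ratio: float = MISSING
    negative_sentiment: float = MISSING

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


#: Clinical FTD item names (SANS negative items + SAPS positive items).
SANS_FTD_ITEMS = (
    "poverty_of_speech",
    "poverty_of_content",
    "blocking",
    "increased_latency",
)
SAPS_FTD_ITEMS = (
    "derailment",
    "tangentiality",
    "incoherence",
    "illogicality",
    "circumstantiality",
    "pressure_of_speech",
    "distractibility",
    "clanging",
)
FTD_ITEMS = SANS_FTD_ITEMS + SAPS_FTD_ITEMS

GROUPS_COARSE = ("HC", "affective", "psychotic")
GROUPS_FINE = ("HC", "MDD", "BD", "SZA", "SZ")
FINE_TO_COARSE = {"HC": "HC", "MDD": "affective", "BD": "affective",
                  "SZA": "psychotic", "SZ": "psychotic"}


@dataclass
class ParticipantRecord:
    """Features, clinical ratings, covariates and ROI measures for one person."""

    participant_id: str
    group: str = "HC"
    age: float = MISSING
    sex: str = "f"
    tiv: float = MISSING
    verbal_iq: float = MISSING
    medication_index: float = MISSING
    ftd_items: dict[str, float] = field(default_factory=dict)
    features: FeatureVector = field(default_factory=FeatureVector)
    brain: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, score in self.ftd_items.items():
            if not is_missing(score) and not 0 <= score <= 5:
                raise CorpusError(
                    f"{self.participant_id}: FTD item {item} score {score} outside 0-5"
                )

    @property
    def has_complete_ftd(self) -> bool:
        return all(
            item in self.ftd_items and not is_missing(self.ftd_items[item])
            for item in FTD_ITEMS
        )


# ---------------------------------------------------------------------------
# CoNLL-U I/O
# ---------------------------------------------------------------------------

_ID_RANGE = re.compile(r"^\d+[-.]\d+$")


def _parse_misc(misc: str) -> dict[str, str]:
    if misc in ("_", ""):
        return {}
    out = {}
    for part in misc.split("|"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def _parse_conllu_sentence(lines: list[tuple[int, str]], index: int) -> Sentence:
    tokens: list[Token] = []
    for lineno, line in lines:
        cols = line.split("\t")
        if len(cols) < 8:
            raise CorpusError(f"line {lineno}: expected >=8 CoNLL-U columns, got {len(cols)}")
        tok_id = cols[0]
        if _ID_RANGE.match(tok_id):  # multiword-token range or empty node: skip
            continue
        try:
            int(tok_id)
        except ValueError as exc:
            raise CorpusError(f"line {lineno}: bad token id {tok_id!r}") from exc
        feats = cols[5]
        morph_count = 0 if feats in ("_", "") else len(feats.split("|"))
        try:
            head = int(cols[6]) if cols[6] != "_" else 0
        except ValueError as exc:
            raise CorpusError(f"line {lineno}: bad HEAD {cols[6]!r}") from exc
        misc = _parse_misc(cols[9]) if len(cols) > 9 else {}
        tokens.append(
            Token(
                surface=cols[1],
                lemma=cols[2] if cols[2] != "_" else cols[1],
                upos=cols[3],
                morph_count=morph_count,
                head=head,
                deprel=cols[7],
                is_filled_pause=misc.get("FilledPause") == "Yes",
                is_personal_pronoun=misc.get("Personal") == "Yes",
                topic_tag=misc.get("Topic"),
            )
        )
    if not tokens:
        raise CorpusError("empty sentence block")
    return Sentence(tokens=tuple(tokens), index=index)


def read_conllu(path: str | Path, participant_id: str | None = None) -> Transcript:
    """Parse one CoNLL-U document into a Transcript.

    Sentence boundaries are blank lines; comment lines (``#``) are ignored
    except ``# participant_id = ...`` which overrides the filename-derived id.
    """
    path = Path(path)
    pid = participant_id or path.stem
    sentences: list[Sentence] = []
    block: list[tuple[int, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("#"):
                m = re.match(r"#\s*participant_id\s*=\s*(\S+)", line)
                if m:
                    pid = m.group(1)
                continue
            if not line.strip():
                if block:
                    sentences.append(_parse_conllu_sentence(block, len(sentences)))
                    block = []
                continue
            block.append((lineno, line))
    if block:
        sentences.append(_parse_conllu_sentence(block, len(sentences)))
    if not sentences:
        raise CorpusError(f"empty document: {path}")
    return Transcript(participant_id=pid, sentences=tuple(sentences))


def write_conllu(transcript: Transcript, path: str | Path) -> None:
    """Serialise a Transcript to CoNLL-U (lossless w.r.t. ``read_conllu``)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# participant_id = {transcript.participant_id}\n")
        for sent in transcript.sentences:
            for i, tok in enumerate(sent.tokens, start=1):
                misc_parts = []
                if tok.is_filled_pause:
                    misc_parts.append("FilledPause=Yes")
                if tok.is_personal_pronoun:
                    misc_parts.append("Personal=Yes")
                if tok.topic_tag is not None:
                    misc_parts.append(f"Topic={tok.topic_tag}")
                misc = "|".join(misc_parts) or "_"
                feats = (
                    "|".join(f"F{j}=v" for j in range(tok.morph_count))
                    if tok.morph_count else "_"
                )
                fh.write(
                    "\t".join(
                        [str(i), tok.surface, tok.lemma, tok.upos, "_", feats,
                         str(tok.head), tok.deprel, "_", misc]
                    ) + "\n"
                )
            fh.write("\n")


_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+")

#: Default German filled-pause inventory for plain-text segmentation.
DEFAULT_FILLED_PAUSES = ("äh", "ähm", "hm", "mhm")


def read_plain_text(
    path: str | Path,
    participant_id: str | None = None,
    filled_pauses: Sequence[str] = DEFAULT_FILLED_PAUSES,
) -> Transcript:
    """Whitespace/sentence-punctuation segmentation of a raw transcript.

    Produces tokens with no dependency or POS annotation beyond the
    filled-pause flag; an annotator adapter must enrich the result before
    feature extraction.  Each sentence is parsed as a flat chain rooted at
    the first non-pause token so that the tree invariant holds.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8").strip()
    if not text:
        raise CorpusError(f"empty document: {path}")
    pauses = {p.lower() for p in filled_pauses}
    sentences = []
    for si, chunk in enumerate(s for s in _SENT_SPLIT.split(text) if s.strip()):
        words = [w.strip(".,;:!?\"'()") for w in chunk.split()]
        words = [w for w in words if w]
        toks: list[Token] = []
        root_seen = False
        for w in words:
            fp = w.lower() in pauses
            if fp:
                toks.append(Token(surface=w, lemma=w.lower(), upos="INTJ",
                                  head=0, deprel="discourse", is_filled_pause=True))
            else:
                head = 0 if not root_seen else next(
                    i for i, t in enumerate(toks, start=1) if not t.is_filled_pause
                )
                toks.append(Token(surface=w, lemma=w.lower(), upos="X",
                                  head=head, deprel="root" if not root_seen else "dep"))
                root_seen = True
        if toks and root_seen:
            sentences.append(Sentence(tokens=tuple(toks), index=len(sentences)))
    if not sentences:
        raise CorpusError(f"no sentences with words in {path}")
    return Transcript(participant_id=participant_id or path.stem,
                      sentences=tuple(sentences))


def read_corpus(path: str | Path, dialect: str = "conllu") -> list[Transcript]:
    """Read a directory (or single file) of transcripts.

    ``dialect`` is ``"conllu"`` (``*.conllu``) or ``"plain-text"`` (``*.txt``).
    """
    path = Path(path)
    if dialect == "conllu":
        reader, pattern = read_conllu, "*.conllu"
    elif dialect in ("plain-text", "plain_text", "text"):
        reader, pattern = read_plain_text, "*.txt"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    files = sorted(path.glob(pattern)) if path.is_dir() else [path]
    if not files:
        raise CorpusError(f"no {pattern} files under {path}")
    return [reader(f) for f in files]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_COVARIATE_COLS = ("group", "age", "sex", "tiv", "verbal_iq", "medication_index")


def records_to_frame(records: Sequence[ParticipantRecord]) -> pd.DataFrame:
    """Flatten participant records into one row per participant.

    Column order is fixed: id, covariates, FTD items, the 18 features, then
    ROI columns (prefixed ``roi_``) in sorted order.
    """
    ids = [r.participant_id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise CorpusError(f"duplicate participant ids: {dupes}")
    roi_names = sorted({name for r in records for name in r.brain})
    rows = []
    for r in records:
        row: dict[str, object] = {"participant_id": r.participant_id}
        for c in _COVARIATE_COLS:
            row[c] = getattr(r, c)
        for item in FTD_ITEMS:
            row[item] = r.ftd_items.get(item, MISSING)
        row.update(r.features.as_dict())
        for name in roi_names:
            row[f"roi_{name}"] = r.brain.get(name, MISSING)
        rows.append(row)
    return pd.DataFrame(rows)


def write_feature_table(records: Sequence[ParticipantRecord], path: str | Path) -> None:
    """Write the cohort to CSV; missing values serialise as empty cells."""
    records_to_frame(records).to_csv(path, index=False, na_rep="")


def read_feature_table(path: str | Path) -> list[ParticipantRecord]:
    """Inverse of :func:`write_feature_table`."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        fv = FeatureVector(**{n: float(row[n]) if pd.notna(row[n]) else MISSING
                              for n in FEATURE_NAMES if n in row})
        ftd = {item: (float(row[item]) if pd.notna(row[item]) else MISSING)
               for item in FTD_ITEMS if item in row}
        brain = {c[4:]: float(row[c]) for c in df.columns
                 if c.startswith("roi_") and pd.notna(row[c])}
        out.append(
            ParticipantRecord(
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                age=float(row["age"]) if pd.notna(row["age"]) else MISSING,
                sex=str(row["sex"]),
                tiv=float(row["tiv"]) if pd.notna(row["tiv"]) else MISSING,
                verbal_iq=float(row["verbal_iq"]) if pd.notna(row["verbal_iq"]) else MISSING,
                medication_index=(float(row["medication_index"])
                                  if pd.notna(row["medication_index"]) else MISSING),
                ftd_items=ftd,
                features=fv,
                brain=brain,
            )
        )
    return out
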