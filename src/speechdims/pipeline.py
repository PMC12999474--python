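"""End-to-end convenience layer: transcripts -> features -> factors -> associations.

Thin orchestration over the stage modules; every step is also callable on
its own.  The speech-factor stage standardises features, drops columns that
are constant or missing, and reports which features entered the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import associations as assoc
from . import factors
from .adapters import LexiconSentimentModel, MarkupGrammarChecker
from .cfa import CfaFit, CfaModel, fit_cfa
from .corpus import FEATURE_NAMES, FTD_ITEMS, ParticipantRecord, Transcript
from .features import (
    CorpusNorms,
    FeatureConfig,
    FeatureProviders,
    compute_corpus_norms,
    extract_features,
)
from . import lexicons


def default_providers(static_embeddings, contextual_embeddings) -> FeatureProviders:
    """Fixture-backed adapters around a pair of embedding providers."""
    return FeatureProviders(
        static_embeddings=static_embeddings,
        contextual_embeddings=contextual_embeddings,
        sentiment=LexiconSentimentModel(
            negative_lexicon=frozenset(lexicons.NEGATIVE_WORDS)),
        grammar=MarkupGrammarChecker(),
    )


def feature_table(
    transcripts: list[Transcript],
    providers: FeatureProviders,
    norms: CorpusNorms | None = None,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Extract all features for a corpus; index = participant_id.

    Syntactic-complexity norms default to the corpus being analysed.
    """
    norms = norms or compute_corpus_norms(transcripts)
    rows = {}
    for t in transcripts:
        fv, _ = extract_features(t, providers, norms, config)
        rows[t.participant_id] = fv.as_dict()
    return pd.DataFrame.from_dict(rows, orient="index").loc[
        :, list(FEATURE_NAMES)]


@dataclass
class SpeechFactorResult:
    """Output of the speech-factor stage."""

    screen: factors.CorrelationScreen
    kmo: dict
    bartlett: dict
    solution: factors.FactorSolution
    scores: pd.DataFrame
    feature_names: list[str]
    k_votes: dict | None = None


def speech_factor_stage(
    features: pd.DataFrame,
    k: int | str = 3,
    method: str = "uls",
    rotation: str = "promax",
    seed: int = 0,
) -> SpeechFactorResult:
    """Screen, diagnose and factor the feature table; return scores.

    ``k="auto"`` selects the factor number by the multi-criterion vote.
    Columns with any missing value are dropped listwise per participant
    first; fully missing or constant columns are dropped with the reduced
    feature list reported.
    """
    usable = [c for c in features.columns
              if features[c].notna().all() and features[c].std(ddof=1) > 0]
    X = features[usable].to_numpy(dtype=float)
    screen = factors.screen_features(X)
    kmo_res = factors.kmo(screen.R)
    bart = factors.bartlett_sphericity(screen.R, n=X.shape[0])
    votes = None
    if k == "auto":
        sel = factors.select_n_factors(X, seed=seed)
        k, votes = sel["k"], sel["votes"]
    solution = factors.fit_efa(X, int(k), method=method, rotation=rotation)
    scores = pd.DataFrame(
        factors.factor_scores(solution, X),
        index=features.index,
        columns=[f"speech_factor_{j + 1}" for j in range(int(k))],
    )
    return SpeechFactorResult(screen=screen, kmo=kmo_res, bartlett=bart,
                              solution=solution, scores=scores,
                              feature_names=usable, k_votes=votes)


def ftd_factor_stage(records: list[ParticipantRecord],
                     model: CfaModel | None = None) -> tuple[CfaFit, pd.DataFrame]:
    """CFA of the FTD items; participants with missing items are excluded."""
    model = model or CfaModel()
    complete = [r for r in records if r.has_complete_ftd]
    if len(complete) < 30:
        raise factors.FactorAnalysisError(
            f"only {len(complete)} participants with complete FTD items")
    X = np.array([[r.ftd_items[item] for item in model.items] for r in complete])
    fit = fit_cfa(X, model)
    scores = pd.DataFrame(fit.scores,
                          index=[r.participant_id for r in complete],
                          columns=list(model.factors))
    return fit, scores


def speech_ftd_correlations(
    speech_scores: pd.DataFrame,
    ftd_scores: pd.DataFrame,
    family_size: int | None = None,
) -> list[assoc.AssociationResult]:
    """Bonferroni-corrected bivariate correlations of the two score sets."""
    return assoc.correlate_with_correction(speech_scores, ftd_scores,
                                           family_size=family_size)
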