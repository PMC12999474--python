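"""Worked examples for each of the 18 speech features."""

import numpy as np
import pytest

from speechdims.adapters import ConstantSentimentModel, ZeroGrammarChecker
from speechdims.corpus import Sentence, Token, Transcript, is_missing
from speechdims.features import (
    CorpusNorms,
    FeatureError,
    MtldConfig,
    ReadabilityCoefficients,
    coherence_features,
    compute_corpus_norms,
    disfluency_features,
    extract_features,
    lexical_ratios,
    morphological_complexity,
    mtld,
    negative_sentiment,
    readability_index,
    syntactic_complexity,
    syntactic_metrics,
    word_graph_cohesion,
)
from conftest import (
    ConstantEmbedding,
    TableEmbedding,
    chain_sentence,
    make_token,
    simple_transcript,
)


class TestLexicalRatios:
    @pytest.mark.parametrize("words,expected", [
        (["a", "b", "c"], 1.0),
        (["a", "a", "b"], 2 / 3),
        (["A", "a", "b"], 2 / 3),       # case-folded types
    ])
    def test_ttr(self, words, expected):
        t = simple_transcript([chain_sentence(words)])
        assert lexical_ratios(t)["ttr"] == pytest.approx(expected)

    def test_pronoun_shares(self):
        toks = [make_token("geht", upos="VERB", head=0, deprel="root")]
        toks += [make_token(w, upos="NOUN", head=1, deprel="dep")
                 for w in "abcdefg"]
        toks.append(Token(surface="ich", lemma="ich", upos="PRON", head=1,
                          deprel="nsubj", is_personal_pronoun=True))
        toks.append(Token(surface="das", lemma="das", upos="PRON", head=1,
                          deprel="obj"))
        t = simple_transcript([Sentence(tokens=tuple(toks))])
        res = lexical_ratios(t)
        assert res["pronoun_ratio"] == pytest.approx(0.2)
        assert res["personal_pronoun_ratio"] == pytest.approx(0.5)

    def test_no_pronouns_gives_missing_not_zero(self):
        t = simple_transcript([chain_sentence(["a", "b"])])
        assert is_missing(lexical_ratios(t)["personal_pronoun_ratio"])

    def test_ttr_excludes_filled_pauses(self):
        t = simple_transcript([chain_sentence(["äh", "a", "b"], pauses=(0,))])
        assert lexical_ratios(t)["ttr"] == pytest.approx(1.0)


class TestMtld:
    @pytest.mark.parametrize("seq,expected", [
        (list("aaaa"), 2.0),            # factors close at every 2nd token
        (list("ababab"), 3.0),          # 2 full factors each direction
    ])
    def test_known_scores(self, seq, expected):
        assert mtld(seq) == pytest.approx(expected)

    def test_all_distinct_is_missing(self):
        assert is_missing(mtld(list("abcd")))

    def test_empty_sequence_is_error(self):
        with pytest.raises(FeatureError):
            mtld([])

    def test_threshold_must_be_in_unit_interval(self):
        with pytest.raises(FeatureError):
            MtldConfig(threshold=1.5)


class TestMorphAndSyntax:
    @pytest.mark.parametrize("counts,expected", [
        ([0, 0, 0], 0.0), ([2, 2, 2], 2.0), ([1, 2, 4], 7 / 3),
    ])
    def test_morphological_complexity(self, counts, expected):
        toks = [make_token(f"w{i}", head=min(i, 1), morph=c,
                           deprel="root" if i == 0 else "dep")
                for i, c in enumerate(counts)]
        t = simple_transcript([Sentence(tokens=tuple(toks))])
        assert morphological_complexity(t) == pytest.approx(expected)

    def test_subordination_zero_without_subordinate_heads(self):
        t = simple_transcript([chain_sentence(list("ab"), index=i)
                               for i in range(3)])
        assert syntactic_metrics(t)["subordination_ratio"] == 0.0

    def test_subordination_counts_advcl_heads(self):
        def sent(i):
            toks = (make_token("geht", upos="VERB", head=0, deprel="root"),
                    make_token("weil", upos="SCONJ", head=1, deprel="mark"),
                    make_token("regnet", upos="VERB", head=1, deprel="advcl"))
            return Sentence(tokens=toks, index=i)
        t = simple_transcript([sent(0), sent(1)])
        # 2 subordinate heads over 2 main + 2 subordinate clauses
        assert syntactic_metrics(t)["subordination_ratio"] == pytest.approx(0.5)

    def test_connective_rate_per_sentence(self):
        def sent(i):
            toks = (make_token("geht", upos="VERB", head=0, deprel="root"),
                    make_token("und", upos="CCONJ", head=1, deprel="cc"),
                    make_token("aber", upos="CCONJ", head=1, deprel="cc"))
            return Sentence(tokens=toks, index=i)
        t = simple_transcript([sent(0), sent(1)])
        assert syntactic_metrics(t)["connective_ratio"] == pytest.approx(2.0)

    def test_empty_connective_lexicon_is_error(self):
        t = simple_transcript([chain_sentence(["a"])])
        with pytest.raises(FeatureError):
            syntactic_metrics(t, connective_lexicon=frozenset())

    def test_subtyped_deprel_counts(self):
        toks = (make_token("x", upos="VERB", head=0, deprel="root"),
                make_token("y", upos="VERB", head=1, deprel="acl:relcl"))
        t = simple_transcript([Sentence(tokens=toks)])
        assert syntactic_metrics(t)["subordination_ratio"] == pytest.approx(0.5)


class TestReadability:
    def test_formula_arithmetic(self):
        # ASL 10, ASW 1.5 -> 180 - 10 - 87.75
        words = ["ba"] * 5 + ["baba"] * 5      # 1 and 2 syllables
        t = simple_transcript([chain_sentence(words)])
        assert readability_index(t) == pytest.approx(180 - 10 - 58.5 * 1.5)

    def test_minimal_one_word_sentence(self):
        t = simple_transcript([chain_sentence(["ba"])])
        assert readability_index(t) == pytest.approx(120.5)

    def test_longer_sentences_lower_score(self):
        short = simple_transcript([chain_sentence(["ba"] * 5)])
        long = simple_transcript([chain_sentence(["ba"] * 10)])
        assert readability_index(long) < readability_index(short)

    def test_custom_coefficients(self):
        t = simple_transcript([chain_sentence(["ba"])])
        c = ReadabilityCoefficients(c0=100.0, c1=2.0, c2=10.0)
        assert readability_index(t, c) == pytest.approx(100 - 2 - 10)


class TestSyntacticComplexity:
    def test_zero_at_corpus_means(self):
        norms = CorpusNorms(length_mean=2.0, length_sd=1.0,
                            depth_mean=1.0, depth_sd=0.5)
        t = simple_transcript([chain_sentence(["a", "b"])])
        assert syntactic_complexity(t, norms) == pytest.approx(0.0)

    def test_symmetric_two_transcript_corpus(self):
        t1 = simple_transcript([chain_sentence(list("ab"))], pid="a")
        t2 = simple_transcript([chain_sentence(list("abcd"))], pid="b")
        norms = compute_corpus_norms([t1, t2])
        s1 = syntactic_complexity(t1, norms)
        s2 = syntactic_complexity(t2, norms)
        assert s1 == pytest.approx(-s2) and s2 > 0

    def test_chain_depth_enters_z_score(self):
        # a 5-token chain has depth 4; norms make the z-score explicit
        norms = CorpusNorms(length_mean=5.0, length_sd=1.0,
                            depth_mean=2.0, depth_sd=2.0)
        t = simple_transcript([chain_sentence(list("abcde"))])
        assert syntactic_complexity(t, norms) == pytest.approx((0 + 1.0) / 2)

    def test_zero_sd_norms_rejected(self):
        with pytest.raises(FeatureError):
            CorpusNorms(length_mean=1, length_sd=0, depth_mean=1, depth_sd=1)


class TestCoherence:
    def test_identical_sentence_vectors_give_unit_coherence(self):
        prov = ConstantEmbedding([1.0, 2.0])
        t = simple_transcript([chain_sentence(list("ab"), index=0),
                               chain_sentence(list("cd"), index=1)])
        res = coherence_features(t, prov, prov)
        assert res["semantic_coherence_static"] == pytest.approx(1.0)
        assert res["sentence_coherence_contextual"] == pytest.approx(1.0)

    def test_orthogonal_content_words_zero_density(self):
        prov = TableEmbedding({"a": [1, 0], "b": [0, 1]})
        t = simple_transcript([chain_sentence(["a", "b"])])
        assert coherence_features(t, prov, prov)["semantic_density"] == \
            pytest.approx(0.0)

    def test_word_level_coherence_cosine_arithmetic(self):
        s2 = np.sqrt(2) / 2
        prov = TableEmbedding({"a": [1, 0], "b": [s2, s2], "c": [0, 1]})
        t = simple_transcript([chain_sentence(["a", "b", "c"])])
        res = coherence_features(t, prov, prov)
        assert res["word_level_coherence"] == pytest.approx(s2, abs=1e-9)

    def test_single_sentence_coherence_missing(self):
        prov = ConstantEmbedding([1.0])
        t = simple_transcript([chain_sentence(["a", "b"])])
        assert is_missing(
            coherence_features(t, prov, prov)["semantic_coherence_static"])

    def test_unknown_words_are_skipped(self):
        prov = TableEmbedding({"a": [1, 0], "c": [1, 0]})
        t = simple_transcript([chain_sentence(["a", "b", "c"])])
        res = coherence_features(t, prov, prov)
        assert res["word_level_coherence"] == pytest.approx(1.0)


class TestGraphCohesion:
    def test_single_edge_graph(self):
        t = simple_transcript([chain_sentence(["a", "b", "a"])])
        assert word_graph_cohesion(t) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_path_graph_closed_form(self, n):
        words = [f"w{i}" for i in range(n)]
        t = simple_transcript([chain_sentence(words)])
        assert word_graph_cohesion(t) == pytest.approx((n + 1) / 3)

    def test_largest_component_only(self):
        s1 = chain_sentence([f"a{i}" for i in range(5)], index=0)
        s2 = chain_sentence([f"b{i}" for i in range(3)], index=1)
        t = simple_transcript([s1, s2])
        assert word_graph_cohesion(t) == pytest.approx(6 / 3)  # path on 5 nodes

    def test_single_type_is_missing(self):
        t = simple_transcript([chain_sentence(["a", "a", "a"])])
        assert is_missing(word_graph_cohesion(t))


class TestDisfluency:
    def test_filled_pause_ratio_includes_pauses_in_denominator(self):
        t = simple_transcript([chain_sentence(["äh", "a", "b"], pauses=(0,))])
        res = disfluency_features(t, ZeroGrammarChecker())
        assert res["filled_pause_ratio"] == pytest.approx(1 / 3)

    def test_repetition_positions(self):
        t = simple_transcript([chain_sentence(["a", "a", "a"])])
        res = disfluency_features(t, ZeroGrammarChecker())
        assert res["repetition_ratio"] == pytest.approx(2 / 3)

    def test_repetition_across_pause(self):
        t = simple_transcript([chain_sentence(["a", "äh", "a"], pauses=(1,))])
        res = disfluency_features(t, ZeroGrammarChecker())
        assert res["repetition_ratio"] == pytest.approx(1 / 2)
        strict = disfluency_features(t, ZeroGrammarChecker(),
                                     repetition_skips_pauses=False)
        assert strict["repetition_ratio"] == 0.0

    def test_zero_checker_gives_zero_errors(self):
        t = simple_transcript([chain_sentence(["a", "b"])])
        res = disfluency_features(t, ZeroGrammarChecker())
        assert res["grammatical_error_ratio"] == 0.0


class TestSentiment:
    def test_constant_adapter_passthrough(self):
        t = simple_transcript([chain_sentence(["a"])])
        assert negative_sentiment(t, ConstantSentimentModel(0.5)) == 0.5

    def test_neutral_text_logistic_baseline(self, providers):
        t = simple_transcript([chain_sentence(["a", "b"])])
        expected = 1 / (1 + np.exp(2.0))
        assert negative_sentiment(t, providers.sentiment) == \
            pytest.approx(expected)

    def test_out_of_range_adapter_rejected(self):
        t = simple_transcript([chain_sentence(["a"])])
        with pytest.raises(FeatureError, match="1.3"):
            negative_sentiment(t, ConstantSentimentModel(1.3))


class TestExtractFeatures:
    def test_gold_transcript_yields_all_finite(self, lexicon_bundle, providers):
        from speechdims import synthetic
        from speechdims.features import compute_corpus_norms
        prof = synthetic.SpeakerProfile.from_latent(np.zeros(3))
        ts = [synthetic.generate_transcript(prof, lexicon_bundle["lexicon"],
                                            seed=s, participant_id=f"p{s}")
              for s in range(3)]
        norms = compute_corpus_norms(ts)
        fv, errors = extract_features(ts[0], providers, norms)
        assert errors == {}
        assert np.all(np.isfinite(fv.as_array()))

    def test_no_pronouns_leaves_exactly_one_missing(self, providers):
        prov = ConstantEmbedding([1.0, 0.0])
        from speechdims.features import FeatureProviders
        provs = FeatureProviders(prov, prov, ConstantSentimentModel(0.2),
                                 ZeroGrammarChecker())
        norms = CorpusNorms(2, 1, 1, 1)
        t = simple_transcript([chain_sentence(["a", "b"], index=0),
                               chain_sentence(["c", "d"], index=1)])
        fv, _ = extract_features(t, provs, norms)
        arr = fv.as_dict()
        missing = {k for k, v in arr.items() if isinstance(v, float)
                   and np.isnan(v)}
        assert "personal_pronoun_ratio" in missing
        assert "mtld" in missing          # all-distinct short text
        missing -= {"personal_pronoun_ratio", "mtld"}
        assert missing == set()

    def test_determinism(self, lexicon_bundle, providers):
        from speechdims import synthetic
        prof = synthetic.SpeakerProfile.from_latent(np.array([0.5, -0.5, 0.2]))
        t = synthetic.generate_transcript(prof, lexicon_bundle["lexicon"],
                                          seed=3)
        norms = CorpusNorms(10, 2, 3, 1)
        fv1, _ = extract_features(t, providers, norms)
        fv2, _ = extract_features(t, providers, norms)
        a1, a2 = fv1.as_array(), fv2.as_array()
        assert np.array_equal(a1, a2, equal_nan=True)
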