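# Methods

`speechdims` implements an analysis chain for picture-elicited spontaneous
speech in psychiatric research: NLP feature extraction from annotated
transcripts, latent-dimension modelling of those features, and association of
the resulting factor scores with clinician-rated formal thought disorder
(FTD) and ROI-level brain structure. This note documents the models, the
parameters that matter, the synthetic-data design, and the numerical choices.

## 1. Transcript model and feature definitions

Transcripts are token sequences with Universal Dependencies-style gold
annotation (UPOS, morphological feature counts, dependency heads and
relations). Filled pauses are ordinary tokens flagged in MISC
(`FilledPause=Yes`); they are never deleted at parse time, and each feature
documents whether its numerator/denominator includes them. Content words are
the open classes NOUN, PROPN, VERB, ADJ, ADV (excluding filled pauses).

The 18 features:

| feature | definition | pauses in denominator |
|---|---|---|
| ttr | distinct lowercased surface forms / tokens | no |
| mtld | bidirectional MTLD, threshold τ = 0.72, partial-factor correction | no |
| pronoun_ratio | PRON tokens / tokens | no |
| personal_pronoun_ratio | personal pronouns / pronouns (missing when no pronouns) | no |
| morphological_complexity | mean morphological attribute-value pairs per token | no |
| syntactic_complexity | mean of corpus-referenced z-scores of mean sentence length and mean max parse depth | no |
| subordination_ratio | subordinate-clause heads / (main + subordinate clauses); heads are tokens with deprel in {ccomp, xcomp, advcl, acl, csubj} incl. subtypes | no |
| readability | 180 − ASL − 58.5·ASW (German reading-ease form; higher = easier); syllables by a vowel-group heuristic (German diphthongs are contiguous vowel groups) | no |
| connective_ratio | SCONJ/CCONJ tokens plus discourse-marker lemmas, per sentence (may exceed 1) | no |
| semantic_coherence_static | mean cosine of consecutive sentence vectors, static provider | — |
| sentence_coherence_contextual | same, contextual provider | — |
| word_level_coherence | mean cosine of consecutive embeddable word pairs | no |
| semantic_density | mean pairwise cosine over all content-word token vectors | no |
| graph_cohesion | average shortest path length of the word-type adjacency graph, largest connected component | excluded from graph |
| filled_pause_ratio | pause tokens / all tokens | yes |
| repetition_ratio | consecutive identical non-pause surfaces / non-pause tokens; an intervening pause does not break the pair (switchable) | no |
| grammatical_error_ratio | checker errors / non-pause tokens | no |
| negative_sentiment | adapter probability in [0,1] | — |

Design choices where the construct is underdetermined:

- **MTLD** uses the canonical bidirectional definition (forward and reversed
  passes averaged) with the standard threshold 0.72; both are configurable.
- **Readability** uses the German reading-ease linear form with coefficients
  (180, 1, 58.5) in config. The direction convention (higher = easier ⇒
  negative loading on a complexity factor) is reported with the sign used.
- **Syntactic complexity** has no standard combination rule for length and
  parse depth; we use the mean of two z-scores against an explicit
  `CorpusNorms` object (by default the corpus being analysed), making the
  reference reproducible.
- **Word graph**: nodes are lowercased word types, edges join types adjacent
  within a sentence (pauses transparent), undirected and unweighted,
  self-loops from immediate repetition ignored, statistic taken on the
  largest component. Distances are computed with `scipy.sparse.csgraph`
  (unweighted Dijkstra ≡ BFS); tests verify equality with naive all-pairs
  BFS and the path-graph closed form (n+1)/3.
- **Semantic density** pairs content-word *tokens*, not types, so frequent
  repetition of semantically close words raises density — the narrow-focus
  construct it is meant to capture.
- Unknown-embedding words are skipped, never zero-filled, keeping cosines
  well-defined.
- Coherence is computed over the concatenated multi-picture transcript
  (one value per participant), matching how the factor stage consumes it.

Model-backed components (word vectors, sentence embeddings, sentiment,
grammar checking) sit behind small deterministic adapter contracts
(`EmbeddingProvider`, `SentimentModel`, `GrammarChecker`). The shipped
implementations are fixtures: a hash-keyed topic-geometry embedding, a
logistic negative-lexicon sentiment model p = σ(α + β·share) with α = −2,
β = 8, and a markup-driven grammar checker. Production deployments plug in
FastText/BERT/spaCy-backed providers through the same contracts.

## 2. Latent dimensions

**Screening.** Pearson correlations with flags at |r| > 0.80; VIFs from
per-feature regressions with a flag at VIF ≥ 5 and an infinite sentinel for
singular designs. KMO from anti-image partial correlations
(q<sub>ij</sub> = −S<sub>ij</sub>/√(S<sub>ii</sub>S<sub>jj</sub>), S = R⁻¹);
Bartlett's sphericity χ² = −(n−1−(2p+5)/6)·ln det R on p(p−1)/2 df. Both are
tested to 1e−8 against naive regression-based oracles.

**Factor number** by majority vote of the Kaiser criterion, Horn's parallel
analysis (50 seed-controlled normal simulations, 95th percentile) and
Velicer's minimum average partial; ties resolve to parallel analysis, and a
vote of zero factors is an error demanding an explicit k.

**Extraction** minimises the chosen discrepancy over uniquenesses ψ with
loadings profiled out via the eigendecomposition: ULS/minres (sum of squared
off-diagonal residuals), ML (the likelihood discrepancy on
Ψ^{−1/2}RΨ^{−1/2}), or iterated principal axis. Start values are squared
multiple correlations. Heywood cases are handled by clamping ψ at 1e−3 with
the offending loading rows rescaled for consistency, and flagged — never
silent.

**Rotation.** Varimax (Kaiser row normalisation) followed, for promax, by an
oblique least-squares transformation toward the |loading|^4 target, scaled so
Φ has unit diagonal. The implementation reproduces R's
`factanal(..., rotation="promax")` loadings and implied factor correlation on
a frozen fixture to ≈3 decimals. Solutions are reported as pattern matrices;
columns are ordered by explained variance (diag ΦΛᵀΛ) with the dominant
loading made positive. Rotation provably does not change the fitted
correlation matrix (U(UᵀU)⁻¹Uᵀ = I for an invertible k×k transformation),
and a test asserts this to 1e−6.

**Bootstrap.** Case resampling with a mandatory seed; every resample is
refit and aligned to the point estimate by optimal column assignment on
|Tucker congruence| with sign flips (`scipy.optimize.linear_sum_assignment`),
removing label switching before averaging and percentile CIs. Failed
resamples are dropped and counted; more than 10% dropped is an error. The
**average solution** applies the same alignment across extraction methods.

**Factor scores** are regression (Thurstone) scores Z R⁻¹(ΛΦ), standardised
per column; Bartlett scores are available. Singular R falls back to a ridge
of 1e−8 with a warning.

**FTD CFA.** A congeneric three-correlated-factor model (free loadings,
uniquenesses, factor correlations; factor variances 1) fit by ML discrepancy
minimisation on the item correlation matrix (L-BFGS-B; factor correlations
parametrised through tanh). Reported: χ² = (n−1)F, df = p(p+1)/2 − 2p −
k(k−1)/2 (51 for 12 items), CFI against the independence baseline, RMSEA,
and SRMR over the lower triangle. The item→factor map is an editable default
(SANS items → emptiness; SAPS derailment/tangentiality/circumstantiality/
pressure/distractibility → disorganization; incoherence/illogicality/
clanging → incoherence) because the published assignment derives from prior
validation work. Participants with missing items are excluded listwise.

## 3. Associations

- Factor-factor linkage: Pearson r per pair with Fisher-z 95% CIs,
  pairwise-complete rows, Bonferroni over a declared family (default m = 9
  for 3×3 factor pairs; configurable and reported).
- ROI GLMs: OLS of the standardised ROI measure on the standardised factor
  plus age, sex, TIV and diagnostic group (dummy-coded, healthy-control
  reference), complete cases only with counts reported; the factor's
  coefficient is the standardized β with its CI.
- Moderation: mean-centred factor × moderator product term added to the
  same design; the product term's estimate/CI/p is the result.
- An optional max-|t| permutation correction across a supplied ROI set
  (seeded, default 10,000 permutations) is provided as the desk-scale
  analogue of image-space family-wise error control; voxelwise inference is
  out of scope.
- Group descriptives: one-way ANOVA with η² = SS_between/SS_total and
  Bonferroni-adjusted pairwise t contrasts with direction labels;
  chi-square with Cramér's V (Yates-corrected for 2×2) for categoricals.

## 4. Synthetic study design

The generator emulates the target study: ~12 minutes of picture-elicited
narration per participant, a cohort of 178 healthy controls, 146 affective
and 48 psychotic patients, three speech factors correlated with three FTD
factors, and ROI measures with planted standardized effects. The language is
an abstract fixture language with German-like structural knobs; feature
extraction consumes only the gold annotation, so no parser or embedding
model is needed anywhere in the test path.

Transcript lengths target a mean of 1139 words (SD 370), truncated to
[250, 2400] so every draw lies inside the observed corpus range [200, 2496];
sentence length links to the syntactic factor within [6, 36] tokens.

Speaker parameters derive from the latent factors η = (A, B, C) through
monotone logistic/exponential links with slopes calibrated so a 1 SD latent
shift moves each primary feature by roughly half a cohort SD:

- **A (syntactic complexity):** subordination probability σ(−0.4+0.9A),
  connective rate e^{0.2+0.55A} per sentence, mean sentence length
  13·e^{0.22A}, dependency-chain attachment probability σ(0.2+0.6A), topic
  drift hazard σ(−0.8−0.5A) (falling with A, so sentence-to-sentence
  coherence rises), and a mechanically induced negative link to the
  readability and negative-sentiment features.
- **B (lexical diversity and fluency):** Zipf exponent 1.05−0.28B (smaller =
  flatter = more diverse), filled-pause rate σ(−2.2−0.8B), grammar-error
  rate σ(−3.2−0.6B), repetition rate σ(−3.8−0.15B), morphological-richness
  multiplier e^{0.18B}. Graph cohesion and MTLD respond through vocabulary
  diversity; repetitions also respond through chance adjacency of frequent
  words under a steep Zipf law.
- **C (narrow thematic focus):** pronoun-substitution probability
  σ(−1.1+0.9C) and topic concentration σ(1.0+1.4C), which acts twice: as
  within-sentence topic fidelity and as the attraction of a per-speaker
  "home topic" on drift, concentrating the global topic distribution and
  hence raising semantic density and word-level coherence.

The joint latent (3 speech + 3 FTD) is multivariate normal with
within-block correlations 0.3 (speech) and 0.4 (FTD) and a configurable
cross-block; the default cross block mirrors the negative
complexity-FTD / diversity-emptiness pattern. Group mean shifts are applied
on top. FTD items follow a graded-response scheme (0.9·latent + N(0, 0.6)
cut at thresholds). The default thresholds are floor-skewed, as clinical
ratings are in a cohort whose healthy majority scores 0. The
`planted_correlation_study` configuration zeroes group shifts (so the
marginal latent correlation equals the planted value exactly) and uses
symmetric thresholds, i.e. a dimensional-rating design whose categories span
the population range — with floor-skewed thresholds the ordinal measurement
would be so unreliable that the design would mostly measure the rating floor
rather than the planted linkage.

ROI outcomes are built on the standardized scale: y = γᵀ(covariates) + βᵀη +
ε with σ_ε² = 1 − explained variance, so the planted β is exactly the
adjusted standardized coefficient when η is independent of the covariates
(the calibration study); in the default cohort, group shifts make η and
diagnosis correlated, and β remains the group-adjusted coefficient.
Per-participant randomness is spawned from the master seed via a stable CRC32
hash of the participant id, so cohorts are reproducible under subsetting.

**What the generator does not emulate:** real lexical semantics (topic
geometry is a stylised orthogonal structure), recognition/transcription
errors, rater idiosyncrasies beyond item noise, non-Gaussian covariate
structure, and any spatial structure in the brain measures. Passing tests
demonstrate that the pipeline recovers structure *when the generating model
holds*; they say nothing about parser quality or embedding quality on real
German speech, which enter through the adapters.

## 5. Numerical choices and problem sizes

- Promax power m = 4; parallel analysis 50 simulations at the 95th
  percentile; bootstrap percentile CIs at 95%.
- ψ floor 1e−3; L-BFGS-B with numeric gradients (p ≤ ~30 makes this cheap).
- Degenerate inputs are errors, not warnings: identity KMO, non-PD
  correlation matrices, zero-variance columns/moderators, empty connective
  lexicons, cyclic dependency annotation.
- Test problem sizes mirror the design scale where the check is about the
  design (n = 500 recovery, B = 500 bootstrap, 200-1000 replicates for
  calibration, 50 seeded cohorts of n = 300 for end-to-end recovery); unit
  and property tests use the smallest size that exercises the property.
- EFA reconstruction residuals are asserted against the correlation
  sampling-noise floor (≈ n^{−1/2}) rather than a fixed small constant.

## 6. Known limitations

- The ML discrepancy is optimised over ψ with numeric gradients; for p much
  larger than ~40 an analytic-gradient implementation would be preferable.
- The CFA treats 0-5 ordinal items through Pearson correlations (a
  polychoric front-end can be substituted by passing a correlation matrix).
- Promax factor correlations are known to depend on the power parameter;
  m = 4 is the field default but is exposed in config.
- The plain-text reader only segments and flags filled pauses; all
  linguistic annotation must come from an annotator adapter.
- Bonferroni is the only multiplicity scheme implemented, matching the
  target analysis; FDR alternatives are out of scope.
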