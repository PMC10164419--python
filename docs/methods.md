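# Methods

`vaxsent` analyses public sentiment about COVID-19 vaccines from short
social-media texts and turns the result into a spatial recommendation of
vaccination centers. This note records the models and procedures it
implements, the parameters that matter, the design choices made where the
design was genuinely open, and what the synthetic study conditions do and
do not demonstrate.

## Text cleaning

Cleaning is staged in a fixed order: hashtag-symbol removal (the tag word
is kept, since vaccine hashtags such as `#PfizerBioNTech` are content),
URL removal (`http(s)://` plus the maximal non-whitespace run), @-mention
removal (on by default, flag-controlled), punctuation stripping
(intra-word apostrophes survive, so contractions remain one token), and
case-insensitive stop-word removal over a whitespace tokenization. Case
is preserved: downstream lexicon matching case-folds on its own, and
preserving case keeps the cleaned text human-auditable.

The packaged stop-word list is deliberately compact — function words only.
Temporal prepositions ("after", "before") and ordinals ("first",
"second") are *retained* as content words: in vaccine chatter, "fever
after first dose" loses its meaning without them.

## Lexicon polarity

`score_polarity` is a pattern-style lexicon scorer. Each word found in the
sentiment lexicon contributes its polarity in [−1, +1]; an intensity
modifier immediately before the word rescales it (e.g. "very" ×1.3,
"slightly" ×0.7); a negator within the two preceding tokens flips and
damps it by −0.5 (the classic pattern convention — "not good" is weakly
negative, not the mirror image of "good"); contributions are clipped to
[−1, 1] and averaged. A text with no lexicon word scores exactly 0.

The lexicon itself is authored and shipped with the package
(`data/sentiment_lexicon.csv`, ~100 entries centred on vaccine-discourse
vocabulary). Entry values are calibrated against the package's reference
sentences — "Fever after first dose PfizerBioNTech" → −0.5, "Vaccine
scheduling available online" → +0.7, "Second dose done" → 0 — which the
test suite pins exactly. The lexicon is replaceable by a
`word,polarity` CSV for other domains.

Seven-class bucketing maps |polarity| through two cutoffs, `weak = 0.3`
and `strong = 0.6` (config-overridable): neutral is the single point 0,
then weakly / mild / strongly on each wing. The point-neutral convention
follows the reference examples, where exactly 0 is Neutral and 0.7 is
already Strongly positive. The ternary collapse (sign of the wing) is
what labels training data and word-cloud subsets. The word-cloud artifact
is the term-frequency table (case-folded counts, alphabetical tie-break);
image rendering is presentation, not analysis, and is left to the caller.

## NBSVM

The core classifier is the interpolated Naive-Bayes/SVM construction for
text. From a binarized document-term matrix and binary labels it computes
log-count ratios

    r = log( (α + p) / ‖α + p‖₁ ) − log( (α + q) / ‖α + q‖₁ ),

with p, q the per-class term-count sums and α = 1 by default, and then
trains a linear squared-hinge margin classifier (liblinear, C = 1, fixed
random state) on the NB-scaled features x = f ∘ r. Binarization and α = 1
are the standard choices in this lineage. Weight interpolation toward the
mean magnitude (w̃ = (1 − β)·w̄ + β·w) is implemented but off by default
(β = 1): on short texts the uninterpolated model is already the stronger
variant, and the default keeps the model exactly "log-count ratios as SVM
features". Margins are mapped to [0, 1] through a logistic link so NBSVM
scores share a scale with probabilistic classifiers for fusion; the hard
label thresholds at 0.5. An empty document scores from the intercept
alone.

Baselines live behind one harness: an authored multinomial NB (Bayes'
rule with Laplace smoothing, computed in log space; a document of only
unseen words falls back to the class prior) and an authored KNN (n-D
Euclidean distance; distance ties break by training order, vote ties go
to the class with smaller summed distance), plus scikit-learn decision
tree, random forest and linear SVM wrapped to the same score/label
contract. Note the smoothed NB is *not* exactly invariant under
duplicating the corpus — pseudo-counts do not scale with the data — so
that invariance is only asserted in the vanishing-smoothing limit.

Metrics are the standard confusion-matrix quantities; a ratio with zero
denominator is reported as 0 together with an `undefined` flag naming the
metric, so a degenerate evaluation cannot masquerade as a true zero.

## Encoder and fusion

The transformer classifier is a compact encoder implemented directly in
numpy: CRC32-hashed token embeddings (512 buckets) plus learned positions,
two self-attention layers (hidden 32, 4 heads, GELU feed-forward,
post-layer-norm), a [CLS] token pooled as the sequence representation C,
and a softmax classification head P = softmax(C·Wᵀ + b). The built-in
configuration is `tiny-random`: encoder weights are a fixed, seeded random
draw, sized so everything runs on one CPU in seconds. Fine-tuning freezes
the encoder body and trains the head with Adam (β₁ = 0.9, β₂ = 0.999)
on cross-entropy, one mean-minibatch-loss trace entry per epoch; the head
problem is convex, so the loss trace descends on any learnable data.
Defaults: 5 epochs, batch 8, learning rate 0.05, seeded shuffling.

Fusion is a weighted sum of the encoder's and NBSVM's positive-class
scores with defaults w_bert = 0.87, w_nbsvm = 0.08. Because those weights
do not sum to 1, the fused score is divided by the weight sum by default
(raw mode available) so it stays in [0, 1] and thresholds at 0.5.

`grid_search_weights` scans (w_bert, w_nbsvm) exhaustively over
{0, step, …, 1}² minus the origin and keeps the pair with the best
validation accuracy. Accuracy ties break by the larger minimum decision
margin — among equally accurate weightings, prefer the most confident
separation. This refinement is what makes the search zero out a member
that is *anti-correlated* with the truth (rather than merely out-voting
it with a larger opposing weight), while leaving genuinely uninformative
ties to the final deterministic tie-break (larger w_bert, then larger
w_nbsvm). The search is deterministic and row-order invariant.

Following the two-model scheme, `train_polarity_pair` trains one fused
model for positive-vs-rest and one for negative-vs-rest, where "rest"
includes neutral texts so both binary tasks are defined on the whole
corpus (overridable). Each member gets its own stratification-free seeded
80/20 split, its own grid-searched weights, and validation metrics from
the shared metrics module.

## Geospatial analysis

Geocoding is an offline gazetteer lookup (trim, case-fold, collapse
whitespace); a miss is a value, not an error. Distances are great-circle
(haversine) on a sphere of radius 6371.0088 km.

The Average Nearest Neighbor statistic uses the Clark–Evans/GIS
convention: DO is the mean distance to the nearest other point,
DE = 0.5/√(n/A) is its expectation under complete spatial randomness,
ANN = DO/DE, z = (DO − DE)/SE with SE = 0.26136/√(n²/A), and the p-value
is two-sided normal. The study area A defaults to the bounding rectangle
(on the sphere for geographic input: A = R²·Δλ·(sin φ_max − sin φ_min))
and should be supplied explicitly whenever a meaningful frame is known —
the bounding rectangle of a clustered pattern understates A and so
understates the clustering signal. Confidence uses the conventional
printed joint table (p < 0.10/0.05/0.01 with |z| > 1.65/1.96/2.58 →
90/95/99%); the analytic critical values are exposed separately
(`z_critical`), and the 90% row's printed 1.65 is kept as-is rather than
"corrected" to 1.6449. When the p-row and z-row disagree the result
carries a flag and a logged warning instead of a silent choice. A pattern
is *called* clustered (ANN < 1) or dispersed (ANN > 1) only at ≥ 90%
confidence; otherwise random.

Buffering selects centers within a closed geodesic ball (default radius
10 km — the distance found most practical to encourage uptake), sorted by
distance then name. Recommendation ranks in-radius centers by the maximum
positive-share over their brands from a regional-sentiment table (missing
brands default to 0.5, i.e. no information), ties broken by distance then
name; each recommendation records where its score came from. The ranking
rule itself is this package's concretization of "people's beliefs about a
brand influence their choice of center" — it is deliberately simple and
auditable, not optimal.

## Synthetic study conditions

The corpus generator emulates the *structure* of vaccine-tweet data, not
its language: three pairwise-disjoint word lists (positive, negative,
neutral filler, drawn from dominant word-cloud vocabulary), 3–8 words per
tweet, 100 tweets per class by default, optional hashtag/URL decorations
(rate 0.3) to exercise cleaning, and a label-noise fraction that flips
labels. Noise 0 makes the corpus linearly separable by construction, so
perfect held-out accuracy on it validates the estimator machinery — it
says nothing about accuracy on real tweets, where classes overlap
lexically, negation is rampant and labels are themselves noisy.

The point-pattern generator covers the three regimes the ANN statistic
distinguishes: CSR (uniform in a box; defaults n = 500 in 100 × 100 km
for calibration runs), clustered (a Thomas-process analogue: 20 uniform
parents × 10 Gaussian offspring with σ = 1 km, clipped to the box — the
simplest mechanism guaranteeing ANN < 1), and a regular grid of cell
centers, whose ANN against the full box area is exactly 2 in closed form.
CSR calibration uses 200 replicates; the ~5% rate of |z| > 1.96 is
checked with a binomial tolerance. All generators are pure functions of
their spec, seed included, using `numpy.random.default_rng` only — no
global RNG state anywhere.

The gazetteer (25 cities) and center table (13 synthetic centers covering
all seven recognized brands) are deterministic program constants, so
geocoding and buffering tests run offline and reproduce bit-for-bit.

## Numerical and degenerate-input choices

- Polarity exactly 0 is neutral; bucket thresholds compare with
  `<`/`≥` so the cutpoints 0.3 and 0.6 belong to the stronger class.
- LinearSVC uses tol 1e-8 and a fixed `random_state`, making NBSVM
  training deterministic for a given seed.
- The encoder processes texts independently, so batch composition cannot
  change results; softmax is computed with max-subtraction.
- Grid-search margins are rounded to 12 decimals before tie comparison so
  floating-point noise cannot break exact ties.
- ANN on < 2 points, nonpositive areas, and degenerate (zero-width)
  bounding rectangles are errors, not NaNs.
- CSV parsing is lenient by default (malformed optional cells become
  absent fields with a logged warning); strict mode raises row errors
  with 1-based row numbers. Duplicate tweet ids warn (lenient) or error
  (strict).

## Known limitations

English only; the lexicon is small and domain-calibrated rather than
exhaustive; the encoder's pretrained-checkpoint path is a contract only —
the built-in configuration is the tiny seeded one; retweet/duplicate
handling before training is exposed as a flag (`drop_retweets`) with no
default opinion; ANN assumes a homogeneous process within a correctly
specified study area, and the geodesic variant treats the Earth as a
sphere.
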