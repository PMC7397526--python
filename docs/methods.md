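# Methods

## The problem being modeled

Learners of any language face a restriction problem with causatives: a verb
like *break* appears freely in the less-transparent (transitive) causative,
while *laugh* does not, yet children are never told which verbs are out, and
they still generalize novel verbs by meaning. The package implements three
interlocking quantitative accounts — distributional statistics (entrenchment
and preemption), rated verb semantics, and a discriminative learning model
that subsumes both — together with the evaluation layer that compares each
against graded acceptability judgments, verb by verb.

## Corpus bias statistics

Input is a per-verb count table over three construction categories:
less-transparent causative, more-transparent causative, and all
non-causative ("other") uses. For a focal verb and a rated structure we form
a 2×2 table — rows: focal verb vs the pooled remaining verbs; columns: rated
structure vs a comparison category — and compute the uncorrected Pearson
chi-square via the closed form N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)). The sign is
set by comparing the cross products ad vs bc: positive when the focal verb's
odds toward the rated structure exceed the pooled base rate, negative
otherwise. Design choices:

* **No continuity correction, no smoothing.** The statistic is used as a
  graded predictor, not a test; worked examples in this literature contain
  zero cells, and the cross-product sign rule needs no correction to stay
  defined.
* **Comparison category.** Preemption uses the competing causative
  structure; entrenchment uses non-causative uses only, so no token is
  counted by both predictors. This makes entrenchment a deliberately
  conservative, non-overlapping signal.
* **Base rate = the supplied verb set.** "All other verbs" means the other
  verbs in the table, an approximation to language-wide behaviour that
  matches how such predictors are computed from finite study lexica.
* **Standardization.** Each predictor column is Z-scored across verbs with
  the sample (n−1) SD. Any monotone rescaling of the raw chi-square would
  leave downstream correlation analyses unchanged.

A structural property worth keeping in mind: the chi-square magnitude scales
linearly with a verb's token count, so under a Zipfian lexicon the predictor
conflates the *direction and size* of a verb's bias with its *frequency*.
The sign tracks the bias direction essentially perfectly; the magnitude is a
frequency-weighted evidence measure, not a pure effect size.

## Semantic profiles

Raters place each verb on continuous analogue scales; we store positions on
0–100 (the choice is cosmetic — both downstream forms are invariant to
affine rescaling). Per-verb arithmetic means feed (a) Z scores for use as
regression predictors and (b) min-max scaling to [0, 1] across verbs per
scale for use as model input activations. Min-max is the minimal monotone
map onto the unit interval; it preserves rank order and spreads the lexicon
over the full activation range. Missing raters are tolerated; an empty
(verb, scale) cell is an error, never silently imputed.

## The discriminative learner

Architecture: input = 60 one-hot lexical units, 1 binary causative unit
(set when the utterance uses either causative structure), 4 continuous
semantic units in [0, 1], and a constant bias; output = 3 softmax units
(less-transparent, more-transparent, other). No hidden layer — the task is
deliberately conceptualized at a level where a single associative layer
suffices, which also keeps the model identical across languages.

Learning is online, one corpus-sampled utterance at a time:

    W ← W + η((t − y) ⊗ x − λ_step·W)

with t the one-hot attested form and y the softmax prediction, both the
error and decay terms evaluated on the pre-update weights. This is
stochastic gradient descent on the softmax cross-entropy (the Widrow-Hoff
family with continuous cues), so with λ = 0 the per-context output
activations converge to the empirical conditional form frequencies.
Parameters and defaults:

* **η = 0.01** (exposed). The qualitative behaviour — convergence to
  conditional frequencies, overgeneralization-then-retreat — is robust to η;
  smaller values reduce the stationary fluctuation of constant-step SGD at
  the cost of slower convergence. Setting η = 0 is allowed and freezes the
  weights (useful as a control).
* **Weight decay 0.5 per epoch** (exposed). Decay is specified as a
  per-epoch budget and applied per update as λ_step = decay /
  utterances_per_epoch, so one epoch exerts an O(decay) regularizing pull
  regardless of epoch length. Decay shrinks confidence: it pulls activations
  toward uniform, more strongly for weakly-evidenced verbs.
* **Initialization uniform on ±0.5** (exposed as `init_range`), matching
  the conventional "range" parameter of single-layer fitting routines.
* **Regimen**: epochs of 10,000 utterances sampled with replacement from
  the corpus counts (with-replacement sampling matters because some corpora
  are small); an ensemble of independently initialized and independently
  sampling runs stands in for a participant sample. Run r seeds its
  generator with `seed + r`; everything is bit-reproducible from the master
  seed.

Judgments: a forward pass with learning off and the causative unit clamped
to 1; the less- and more-transparent activations are the model's graded
acceptability judgments. Judgments are recorded before training (epoch 0)
and after every epoch, giving developmental trajectories.

Split-half validation draws one random half of the lexicon, restricts the
sampler to it, and judges the held-out half. Held-out lexical weights stay
at initialization (modulo decay), so held-out predictions are carried
entirely by the causative, semantic and bias weights — exactly the
generalization channel of interest. The same partition is shared by all
runs of an ensemble, so ensemble means are computed over a fixed held-out
set.

The inner training loop is JIT-compiled with numba; a fallback decorator
runs the identical code uncompiled if numba is unavailable. All sampling
happens in numpy before the compiled loop, so results do not depend on
which path executes.

## Evaluation

By-verb means are the unit of comparison throughout: activations are
averaged over runs first, ratings over participants first, then correlated
across verbs (Pearson). Three comparisons per epoch: LESS activations vs
LESS rating means, MORE vs MORE, and difference scores (MORE − LESS) vs
difference scores. Difference scores are the fairest test of a model that
makes relative predictions, and they cancel any per-verb shift common to
both forms. Constant model output (e.g. a zero-initialized model at epoch
0) makes r undefined; such epochs are flagged `degenerate` with r = NaN
rather than silently scored 0, which would corrupt trajectory plots.

Critical values invert the t test of a correlation:
r* = t*/√(t*² + df), df = n_verbs − 2. With 60 verbs, one-tailed: r* = 0.21
at p < .05 and 0.30 at p < .01.

The cross-language analysis correlates each language's event-merge rating
means with each language's adult difference scores in a full matrix,
flagging cells that exceed the critical r — positive off-diagonal structure
indicates a semantic constraint shared across languages.

## Synthetic data generator

What it emulates, per table:

* **Corpus counts.** Per-verb totals ∝ rank^(−s) with s = 1 (the canonical
  Zipf exponent for word frequencies), scaled to 10⁶ tokens; each token is
  causative with probability p_c = 0.1; causative tokens fall on the
  less-transparent structure with probability σ(β₀ + β_sem·m_v), β₀ = 0,
  β_sem = 6, where m_v ~ U(0,1) is the verb's event-merge latent. β_sem = 6
  spans allocation probabilities from 0.5 to ~0.998 across the lexicon —
  a strong but not deterministic semantics→structure link.
* **Ratings.** 20 raters per scale read the latent with additive Gaussian
  noise (sd 0.1 on the unit scale) and clip; subsidiary scales are the
  event-merge latent plus clipped noise (sd 0.1), inducing pairwise
  correlations above 0.7 — mirroring the strong collinearity of rated
  causative semantics dimensions.
* **Judgments.** 48 participants per age group rate each verb in both
  sentence types. Latent acceptability for the less-transparent form is
  γ_sem(m_v − ½) + γ_freq·b(v) + noise with γ_sem = 2, γ_freq = 1, noise sd
  0.5; both systematic terms flip sign for the more-transparent form, since
  b(v) — the verb's log-odds of LESS vs MORE relative to the lexicon base
  rate, with 0.5 added per cell to keep zero counts finite — reverses when
  the rated structure reverses. Latents are discretized into 1–5 by
  equal-width bins over the generative range. Age groups share the
  generator; developmental differences are not modeled.

What the generator does **not** emulate: real lexical frequency profiles of
any particular language, rater- or participant-level reliability
differences, presentation-order effects, age-group effect-size gradients,
and any dissociation between preemption and entrenchment beyond what the
allocation model induces. Passing tests on synthetic data therefore show
that the pipeline recovers the signals it assumes, at study scale and
realistic noise — not that those signals have the same strength in any real
corpus.

The designed overgeneralization corpus is a separate, hand-structured
scenario: 20 verbs in two semantic clusters (event merge ≈ 0.9 vs ≈ 0.1),
causative tokens allocated by a sharp logistic so each cluster strongly
prefers one structure, and one target verb with high-merge semantics whose
2,000 tokens (2% of the corpus) include only more-transparent causatives.
The target's frequency matters to the phenomenon itself: early in training
the semantic weights — driven by the frequent high-merge verbs — pull the
target's less-transparent activation up (overgeneralization); its own
attested tokens then supply the lexical counter-evidence that drives the
retreat. A target too rare to accumulate lexical evidence overgeneralizes
without retreating, which is the entrenchment point in miniature.

## Problem sizes and numerical choices

* The benchmark regimen is 8 runs × 20 epochs × 10,000 utterances per seed
  (full-lexicon plus split-half), 20 seeds. Fit curves plateau well before
  epoch 20 at these corpus shapes; the 48 × 50 regimen is available through
  `LearnerConfig` and changes the late-epoch correlations negligibly.
* The conditional-frequency fixed-point check uses a single-verb corpus
  with an 80/20 causative split, η = 0.01, no decay, and averages judgments
  over 5 runs × the last 10 of 40 epochs: constant-step SGD fluctuates
  around the fixed point, and the stationary *mean* of the judged
  activations is the empirical conditional frequency.
* Softmax is computed with max-subtraction; weights are checked finite
  after every epoch and divergence raises with run/epoch context.
* Degenerate inputs (constant vectors to Z-scoring or correlation,
  all-zero contingency tables, empty rating cells) raise typed errors;
  nothing is silently coerced to 0.
* Verb identity is a stable string key; integer indices are positional in
  the counts table and emitted alongside outputs.

## Known limitations

* The chi-square predictor's magnitude conflates bias with frequency (see
  above); rank-based or odds-ratio variants would decouple them but are not
  part of the modeled analysis.
* The learner sees only the study lexicon — no information about verbs
  outside the 60 — so its base rates are lexicon-relative, like the
  statistics.
* The per-epoch training protocol is an online reading of a regimen
  originally fit with a batch routine; the delta rule with per-epoch decay
  budget preserves the regularization role without claiming to replicate an
  unspecified optimizer.
* Ratings discretization uses equal-width bins; the two-step
  (grammatical/ungrammatical, then degree) elicitation procedure of real
  judgment tasks is not modeled, only its 1–5 output.
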