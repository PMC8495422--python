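# Methods

## The model

`lexprop` treats a lexical psycholinguistic property (LPP) as a latent scalar
attached to each word *as used in a particular corpus*. The estimator is
semi-supervised label propagation: a small set of words with extreme human
ratings anchors the two ends of the dimension, and affinity to each pole is
measured by how often a random walker on a semantic-similarity graph, who
repeatedly restarts at the pole's seeds, visits each word.

Formally, for a sub-corpus with transition matrix `P` (row-stochastic,
derived from the kNN cosine graph over that sub-corpus's embeddings) and a
seed distribution `s` (uniform over one pole), the landing distribution is
the unique fixed point of

    p = β · pP + (1 − β) · s,   0 < β < 1,

solved by iterating from `p = s` until the max-norm change drops below `tol`.
This is the stationary distribution of a random walk with restart; the
Monte-Carlo walker (`monte_carlo_propagate`) simulates the same process
explicitly, records every state traversed, and converges to the same
distribution — it is kept as an independent cross-check of the deterministic
solver, not as the production path.

With landing masses `c` (high pole) and `a` (low pole), a word scores
`c/(c+a)` in [0, 1]. Scores are averaged over a bootstrap in which each pole
is subsampled independently per round, removing the leverage of any single
seed. The corpus-level score is the unweighted mean of word scores over the
target words shared by all groups being compared.

### Key assumptions

- Distributional similarity in a sub-corpus tracks similarity in the LPP of
  interest well enough that graph proximity carries label information.
- The seed ratings (collected from native speakers) are valid anchors for the
  *extremes* of the dimension even when the corpus authors are L2 learners;
  everything between the extremes is inferred from usage, not from norms.
- Scores are comparable across sub-corpora because target words and seed sets
  are identical across groups; only the embeddings (usage) differ.

## Parameters

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `EmbeddingConfig.dim` | 300 | customary dimensionality for static corpus embeddings; tests and synthetic benchmarks use 30–100 for speed at small vocabularies |
| `EmbeddingConfig.window` | 5 | symmetric co-occurrence window (tokens) |
| `GraphConfig.n_neighbors` | 25 | kNN degree; established practice for lexical graphs of this kind |
| `GraphConfig.weight_kernel` | clipped cosine | `max(cos, 0)` keeps weights in [0, 1]; an affine `(cos+1)/2` variant is available |
| `WalkConfig.beta` | 0.9 | continue probability; expected excursion length 1/(1−β) = 10 steps |
| `WalkConfig.tol` | 1e-6 | fixed-point max-norm stopping rule |
| `WalkConfig.n_subsets` | 50 | bootstrap rounds (B) |
| `WalkConfig.subset_fraction` | 0.7 | per-pole subsample fraction per round |
| `SeedSelectionConfig.min_count` | 10 | seed candidates must occur ≥ 10 times in *every* sub-corpus |
| `SeedSelectionConfig.n_per_pole` | 20 | 20 + 20 seeds per dimension |
| `TopicModelConfig.n_topics / n_top_words` | 20 / 1000 | LDA topics and the size of the "representative of corpus content" filter |

Rating normalization divides by the scale maximum (6.3 on a 7-point scale →
0.90) rather than min-max scaling; this matches the convention of published
score tables this package's outputs are meant to sit beside and is strictly
increasing, so Spearman validity correlations are unaffected by the choice.

Target words for scoring are the words shared by all compared sub-corpora at
any frequency (`min_count=1`); the frequency-10 filter applies only to seed
*candidates*, where rating reliability and graph centrality matter most.

## Design choices where the design was open

- **Deterministic solver as production path.** The propagation literature
  narrates Monte-Carlo walks; the fixed point they estimate is available in
  closed form, so the deterministic iteration is the default (reproducible,
  faster, no sampling error). The walker remains available and is tested to
  agree within total variation 0.02 at 10⁵ walks.
- **Two trainers behind one contract.** The skip-gram trainer (seeded numpy
  SGD, optional hashed character n-grams for subword sharing) is for real
  corpora; the PPMI-SVD trainer is bit-reproducible and is what every unit
  test and synthetic benchmark uses. SVD component signs are fixed by a
  largest-entry-positive convention so runs are byte-identical.
- **Topic-word ranking.** LDA is fitted with scikit-learn's variational
  inference; words are ranked by Σ_t P(w|t)·P(t) with corpus-level topic
  weights. Collapsed Gibbs sampling would serve equally; the ranking, not the
  inference algorithm, is what the seed filter consumes.
- **Content-word filter.** Implemented as a configurable function-word
  stoplist rather than a POS tagger, keeping dependencies light; the stoplist
  is only ever applied to seed candidates and to the static baseline's
  `content_only` mode, never to scoring.
- **Symmetrisation.** The kNN relation is directed; the default graph takes
  the union of directed edges (cosine is symmetric, so weights agree).
  Isolated nodes — all candidate edges clipped to zero — are removed,
  reported in QC, and left unscored (missing, never 0).
- **Bayesian regression engine.** Conjugate normal–inverse-gamma closed form
  with a weak prior (coefficient sd 10³, InvGamma(10⁻³, 10⁻³)); a Gibbs
  sampler over the same posterior is the MCMC cross-check. Reported
  intervals are 95 % equal-tailed credible intervals from the Student-t
  marginal.
- **Distances** between groups are computed on the five-dimension
  corpus-score vectors (one 5-vector per group).
- **Ties** (equal cosine, equal rating) break lexicographically everywhere,
  making every pipeline stage deterministic given its seeds.

## The synthetic generator

`SyntheticSpec`/`generate_bundle` emulate exactly the statistical structure
the estimator relies on: each word gets a latent θ ~ U(0, 1); each document
draws a context z (uniform, shifted per group by a drift term and clipped);
tokens are drawn with probability ∝ zipf(w) · exp(−(θ_w − z)²/2τ²). Small τ
couples co-occurrence tightly to θ; τ → ∞ degenerates to pure Zipf sampling.
Norms are `clip(θ·(scale_max−1) + 1 + ε)`, ε ~ N(0, 0.3) on a 1–5 scale by
default — roughly the disagreement level of crowd-sourced rating studies.
Defaults (V = 2000, 2000 docs of 50 tokens, τ = 0.1, Zipf exponent 1.1,
group drift 0.05/level) were chosen so one group trains reference embeddings
in a few seconds while leaving ~2000 words above the seed-frequency filter.

What the generator does **not** emulate: English lexical statistics, syntax,
learner errors, task/prompt effects, polysemy, or rater-specific norm biases.
Passing the recovery benchmark therefore shows the estimator is correct and
well-conditioned *under its own assumptions*; it does not certify accuracy on
real learner corpora, where validity must be re-established against held-out
human ratings (the validity-correlation output exists for exactly that).

## Benchmarks the test suite computes

- **Ground-truth recovery**: at the benchmark spec (V = 2000, 2000 docs,
  doc length 50, τ = 0.1, n = 25 neighbours, B = 10) the Spearman correlation
  between estimated word scores and planted θ over non-seed words must reach
  0.7; observed runs are far above it, and a permuted-θ null stays below 0.1.
- **Pole-swap antisymmetry**: swapping seed poles maps every score s → 1 − s
  to 1e-9 (single full-seed round, deterministic solver).
- **Solver agreement**: 10⁵ Monte-Carlo walks match the fixed point within
  total-variation 0.02 on a 20-node graph.
- **Calibration**: nominal 95 % regression credible intervals cover a true
  slope in ≥ 90/100 replicates at n = 1000, σ = 0.1.
- **Static-vs-dynamic contract**: duplicating documents leaves the unweighted
  static baseline unchanged but moves both the frequency-weighted baseline
  and the dynamic score.

Problem sizes in the test suite (vocabularies of 100–2000, documents of
25–50 tokens, 30–100-dimensional test embeddings) were chosen as the smallest
at which the statistical structure of interest is clearly expressed.

## Numerical notes and degenerate inputs

- Transition rows are renormalised after division to hold row sums at 1
  within 1e-12.
- `polarity_score(0, 0)` (a word unreachable from both poles) returns the
  neutral 0.5 and flags the word as unsupported rather than failing.
- A PPMI matrix of rank < dim is zero-padded with a warning; words with an
  all-zero PPMI profile receive a deterministic tiny fallback vector so
  cosine stays defined.
- Non-convergence of the fixed-point iteration raises with the residual; it
  cannot occur for β < 1 on a stochastic matrix unless `max_iter` is set
  below ~log(tol)/log(β).
- Spearman on a constant vector and cosine on a zero vector raise rather
  than return NaN.

## Known limitations

- Scores are per word *type* per sub-corpus; occurrence-level (token)
  variation within one sub-corpus is averaged away by construction.
- Corpus-level scores are unweighted type means; a frequency-weighted
  aggregation would answer a different question (the baseline's weighted
  variant illustrates the contrast).
- Very small sub-corpora produce unstable embeddings, hence unstable graphs;
  the validity correlation and QC report are the guardrails, not internal
  heuristics.
- The SGNS trainer is seeded and reproducible, but its scores are not
  bit-stable across numpy versions; for exact reproducibility use the
  PPMI-SVD trainer (`trainer: reference` in the run config).
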