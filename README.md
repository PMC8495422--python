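# lexprop

Dynamic, corpus-specific estimation of **lexical psycholinguistic properties**
(LPPs) — concreteness, imageability, familiarity, age of acquisition (AoA) and
semantic size — for every word of a corpus, and comparison of those estimates
across corpus partitions such as CEFR proficiency levels of second-language
writing.

## Why

The conventional way to assess, say, the concreteness of a learner corpus is
*static*: look up each unique content word in a table of human rating norms
and average the ratings. That approach ignores word frequency, misses every
word the norms don't cover (function words above all), and assumes a word is
used with the same degree of concreteness by every group of writers.

`lexprop` instead estimates a score for **every** word from how that word is
*used in that corpus*. Learners at different proficiency levels who use the
same word in different contexts get different scores for it — a beginner's
*egg* (in "I do not like eggs") is not an advanced writer's *egg* (in "build a
nest egg").

## Method

For each sub-corpus (group) and each LPP dimension:

1. **Embeddings** — train word vectors on the sub-corpus alone (default 300
   dimensions), so the geometry reflects that group's usage. Two trainers are
   provided: a seeded skip-gram with negative sampling (optionally
   subword-aware), and a deterministic PPMI + truncated-SVD trainer.
2. **Lexical graph** — connect each word to its *n* = 25 nearest neighbours by
   cosine similarity; edge weights are the (clipped) cosines; row-normalising
   the weights gives a transition matrix *P*.
3. **Seed words** — from a norms table, pick the 20 highest- and 20
   lowest-rated candidate words among those that are frequent in every group
   (count ≥ 10), topic-representative (top LDA words), and content words.
4. **Propagation** — run a random walk with restart from each pole: the
   landing distribution is the fixed point of
   `p ← β·pP + (1−β)·s` (β = 0.9, `s` uniform over the pole's seeds). With
   landing masses *c* (high pole) and *a* (low pole), a word's score is

   **score(w) = c / (c + a)  ∈ [0, 1]**

   averaged over bootstrap rounds in which each pole is randomly subsampled
   (B = 50 rounds, 70 % of seeds), so no single seed dominates.
5. **Aggregation** — a sub-corpus's dimension score is the unweighted mean of
   its word scores over the target words shared by all groups being compared.

Cross-group statistics: Spearman validity correlations against human ratings,
Euclidean/Manhattan distances between the per-group five-dimension score
vectors, cross-dimension correlations with hierarchical clustering
(complete linkage on 1 − r), and Bayesian linear regression (conjugate
normal–inverse-gamma) of higher-level on lower-level word scores. The static
mean-of-norms baseline (plain and frequency-weighted) is included for
contrast.

## Worked example

No external corpus is needed: the built-in generator creates
proficiency-partitioned corpora in which every word carries a latent property
value θ ∈ [0, 1], co-occurrence is biased toward words of similar θ, and a
noisy norms table is derived from θ.

```python
import lexprop as lp

spec = lp.SyntheticSpec(vocab_size=500, n_groups=3, docs_per_group=500,
                        doc_length=40, tau=0.1, group_shift=0.12, rng_seed=7)
bundle = lp.generate_bundle(spec)
targets = lp.shared_words(bundle.collection, 1)          # 458 shared words
seeds = lp.make_seed_set(bundle, group=0, n_per_pole=15, min_count=8)

for sc in bundle.collection:
    emb = lp.reference_embeddings(sc, lp.EmbeddingConfig(dim=60, window=5))
    P = lp.to_transition_matrix(lp.build_knn_graph(emb, lp.GraphConfig(n_neighbors=20)))
    table = lp.score_dimension(P, seeds, lp.WalkConfig(n_subsets=10, rng_seed=0))
    print(sc.label, round(lp.corpus_score(table, targets), 3))
```

prints

```
G1 0.576
G2 0.459
G3 0.399
```

— the corpus-level scores drift monotonically across the three groups,
tracking the planted shift in usage contexts. Correlating the per-word scores
of group G1 with the planted θ over the 465 non-seed words gives Spearman
ρ = 0.976, i.e. the propagation scores recover the ground-truth property
ordering almost perfectly at this corpus size.

The worked example of the score formula itself: a word whose landing masses
are c = 0.64 (from the concrete seeds) and a = 0.16 (from the abstract seeds)
scores 0.64/(0.64+0.16) = **0.8**.

## Command line

```bash
lexprop simulate --out sim --n-groups 3           # synthetic bundle
lexprop corpus-stats sim/G1.txt sim/G2.txt
lexprop score --config run.yaml                   # full pipeline
lexprop compare --scores-dir out --norms CONC=sim/norms.tsv
lexprop embed sim/G1.txt --out vectors.txt
lexprop seeds sim/G1.txt --norms sim/norms.tsv
```

`lexprop score` writes per-(group, dimension) word-score TSVs, a
group × dimension corpus-score matrix, a QC report and a provenance JSON;
`lexprop compare` adds distances, correlations, a dendrogram (Newick + JSON)
and adjacent-level regression summaries. Exit codes: 0 ok, 2 validation
error, 3 stage failure.

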