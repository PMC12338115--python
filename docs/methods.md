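# Methods

## Problem setting

Given a corpus of biomedical publications annotated with normalized
concepts (compounds as MeSH-style IDs, diseases, genes), the task is to
rank compounds by their association with hepatotoxicity, producing a
score in [0, 1] per compound per method and a fused consensus score.
Validation uses an ordinal liver-injury severity ranking (classes 0–8,
8 = most severe) as ground truth for a "most severe class vs rest"
binary discrimination task.

## Literature mining

For compound *c*, let *k* be the number of documents mentioning both *c*
and the endpoint, *b* the number mentioning *c* elsewhere, *n_tox* and
*n_other* the endpoint and non-endpoint corpus sizes. Two statistics are
combined:

- **Odds ratio** as a ratio of mention proportions,
  OR = (k/n_tox)/(b/n_other). When k > 0 and b = 0 a Haldane-style 0.5
  is added to both numerator counts (totals unchanged, adjustment
  logged) to keep the ratio finite; k = 0 scores 0.
- **Hypergeometric upper tail** P(X ≥ k), inclusive, for X ~
  Hypergeom(N, n_tox, k+b). The tail is accumulated from
  log-gamma-based log-pmf terms with a log-sum-exp, never materializing
  probabilities: realistic compounds produce tails of order e^−5000,
  far below float underflow. The negative log is reported; the log base
  is a parameter defaulting to *e* (a base-10 reading is a constant
  rescaling, exposed in the CLI output as a second column).

The raw score OR · (−log p) is max-normalized across the scored
compounds; all ties at the maximum receive exactly 1. The endpoint
document set can be defined by surface forms matched case-insensitively
against annotation mention text ("hepatotoxicity", "hepatotoxic",
"liver toxicity", "hepatic toxicity") or by concept IDs; both routes
exist because curated corpora define the endpoint textually while the
synthetic generator plants a concept ID. Concepts in fewer than 5
publications are dropped before scoring (strict cut, configurable).

## Word embeddings

Sentences are lower-cased; multi-word entity mentions are replaced
longest-match-first by single concept-ID tokens; tokens with no
alphanumeric character and single-character tokens are removed;
sentences with fewer than two chemical/disease/gene entities are
dropped (a lone entity carries no relational signal). Stop-words are
*not* removed; that choice is left as a preprocessing knob.

The trainer is skip-gram with negative sampling written against numpy:
dynamic window (uniform 1..window per center), 5 negatives drawn from
the unigram distribution^0.75, linear learning-rate decay, vectorized
minibatch updates with scatter-add. Defaults are 10 epochs, minimum
count 5, learning rate 0.025, window 5, dimension 1000; the test suite
and examples run at dimension 32–64 where all qualitative behavior is
preserved. With a fixed seed and single worker, training is exactly
reproducible (multi-worker mode is deliberately not implemented).
Output vectors are L2-normalized; the association score is the cosine
between compound and toxicity tokens, kept unclamped (negative values
mean "unrelated", not "protective", and downstream fusion consumes them
as-is).

Two properties of SGNS matter for interpretation and test design:

- Input-vector cosine measures *shared context distributions*
  (second-order co-occurrence), not direct adjacency. A corpus where
  tokens merely sit next to each other but share no neighbors gives no
  cosine signal — the synthetic generator therefore gives
  endpoint-co-mention sentences a distinct toxicity-topic filler
  vocabulary, emulating the topical structure of real abstracts.
- On very small corpora all input vectors acquire a shared "common
  direction" from the negative-sampling drift, inflating pairwise
  cosines at small dimensions; rankings remain informative, which is
  why tests assert orderings and rank correlations rather than absolute
  cosines.

The vector-arithmetic report takes (toxicity-type, organ) token pairs,
forms difference vectors, and reports the cosine of each and of their
mean against the general-toxicity vector, plus 2-D PCA coordinates of
all involved vectors for plotting. In a space where each toxicity-type
vector is exactly organ + offset, the mean-difference cosine against
the offset is 1 by construction; in random high-dimensional spaces it
concentrates near 0.

## Language-model scoring

Two single-token generation probes:

- **Confidence**: the probability of answering "A" ("I know this
  compound") to a knowledge prompt — exp of the returned logprob, not
  renormalized over other tokens. Compounds below the default 0.9
  threshold are excluded from headline analyses.
- **Severity**: a multiple-choice prompt with 0–4 class definitions
  (severity-oriented), a context block of retrieved abstracts (or an
  explicit no-context statement, the ablation mode), and the compound
  name. The five digit-label logprobs are exponentiated and
  renormalized to a distribution; the pre-normalization mass is kept as
  a diagnostic since residual mass can sit on off-label tokens. The
  score is the expectation of f(k) = 0.25·k. A score exactly 0.5 is
  flagged indecisive.

Prompt templates are versioned text assets with one compound slot and
one context slot; identical inputs produce byte-identical bundles.
Providers implement a single `logprobs(prompt, candidates)` method; the
shipped mock provider answers from a knowledge table and is the
reference backend for tests and simulation. Adapters for hosted models
are out-of-tree plugins by design.

## Context retrieval

Candidates are documents mentioning both the compound and the endpoint.
Stage 1 encodes documents and three templated questions ("Does
[compound] cause liver damage?", "... induce hepatotoxicity?", "... have
hepatic effects?"); each document's cumulative relevance is the *sum*
of its cosines against the three query vectors (the cumulative reading
of combining duplicate-document scores), top-20 kept, ties broken by
ascending document ID so ranking is independent of input order. Stage 2
rescores candidates with a pluggable (query, document) pair scorer
against a specialized symptom query and keeps the top 5, truncated to
100 words. The bundled encoder is a hashed bag-of-words (CRC32 into 256
buckets, L2-normalized) — deterministic and stateless, so the whole
path is reproducible byte for byte; real sentence encoders and
cross-encoders slot in behind the same contracts.

## Fusion and validation

The combined score is Σ wᵢsᵢ / Σ wᵢ over present components with
weights 2 (literature mining), 1 (embeddings), 2 and 2 (model sizes);
missing components and their weights drop out, which is the only rule
consistent with fusing compounds that lack an embedding vector. The
result is invariant to weight rescaling and reduces to the plain mean
under equal weights.

AUC is the Mann–Whitney estimate via midranks (tied pairs count one
half); the 95% CI uses the DeLong structural-component variance with a
normal approximation, clipped to [0, 1]. The paired DeLong test forms
the variance of the AUC difference from the covariance of the two
classifiers' structural components; zero variance (identical
classifiers) reports p = 1 with a warning. Threshold rows (tp/tn/fp/fn,
PPV, NPV, sensitivity, specificity, balanced accuracy) are computed by
sweeping all distinct scores as thresholds (score ≥ t positive),
selecting the balanced-accuracy maximum with ties resolved toward the
lower threshold; the criterion is a parameter since no canonical choice
exists. Method comparison reports pairwise Pearson and Spearman
coefficients with p-values and top-k (default 100) membership overlap
as exact Venn counts.

## Synthetic data generator

The generator emulates the statistical shape of the real analysis
corpus, not its text:

- **Publication counts** per compound are log-normal (default log-mean
  3, log-sd 1), rounded up with floor 1 — the heavy right tail of real
  compound literatures (tens to hundreds of thousands of papers).
- **Planted signal**: each compound has a toxicity level 0–4
  (round-robin by default); a document hosting compound *c* carries the
  endpoint concept with probability base + slope·level(c), clamped to
  [0, 1] (defaults 0.02 and 0.15, chosen so level-4 compounds are
  clearly but not trivially separable at a few thousand documents).
  Documents are partitioned among compounds — one host compound per
  document — so this law holds exactly per compound; compound-compound
  co-mention is deliberately absent since no analysis here uses it.
- **Background**: compound-free documents carry the endpoint at rate
  0.01; a few background disease concepts add annotation noise.
- **Labels**: level maps onto the ordinal scale by {0,2,4,6,8}; with
  probability `label_noise` (default 0.05) a label flips to a uniformly
  random other class, giving an imperfect class-8-vs-rest task.
- **Sentences**: templated token lists, one per compound per document;
  endpoint co-mention sentences draw filler from a toxicity-topic
  vocabulary (see the embeddings section for why). Abstracts are the
  same sentences rendered with concept names, so generated corpora
  round-trip through the annotation I/O.
- **Mock knowledge**: confidence is a strictly monotone map of log
  publication count, log1p(n)/(log1p(n)+3), plus optional seeded
  Gaussian noise clipped to [0, 1]; the choice distribution is a
  discretized Laplace around the planted level with scale `dispersion`
  (0 = point mass, making the model score exactly 0.25·level).

Everything is driven by `numpy.random.default_rng` on the config seed
(sub-streams derived with fixed offsets, kept below 2^31), so all
outputs are byte-identical across runs.

What the generator does **not** emulate: natural language (so nothing
here validates NER or real prompt comprehension), correlated mention
structure between compounds, publication-date effects, or the biases of
real model knowledge. Passing tests demonstrate that the statistical
machinery recovers a planted signal under the stated noise model — not
performance on real literature.

## Numerical and design choices

- Log-space tail: clamped at log(1) from above to absorb rounding; the
  enumeration oracle agrees to 1e-9 relative for all populations ≤ 60.
- Worked-example tail: the natural-log evaluation reproduces the
  reference value (~5699) to 0.1%; a base-10 evaluation gives ~2473,
  which is why the base is exposed rather than hard-coded.
- Composite normalization follows raw = OR · (−log p), normalized =
  raw/max exactly as stated; published per-compound normalized tables
  are not reproducible from their own printed OR and p columns under
  any fixed base, so those absolute values are a non-goal.
- Problem sizes: unit tests run corpora of 10²–10³ documents; the
  end-to-end recovery check uses 10⁴ documents and 50 compounds with a
  noise-free provider, embeddings at dimension 32 — a scale chosen so
  the planted gradient is comfortably detectable while the whole suite
  stays in desk-scale runtime.
- The bootstrap oracle for the DeLong test uses stratified
  within-class resampling, 10⁵ replicates, and a normal approximation
  on the bootstrap variance; at 8 data points both approximations are
  rough, so the frozen toy instance is one where the comparison is
  meaningful (difference stable across bootstrap seeds).

## Known limitations

- Co-occurrence and embedding scores are undirected: hepatoprotective
  compounds co-mentioned with liver injury score high. Nothing in the
  package disambiguates direction; the language-model route is the only
  one that can.
- The mock provider cannot misknow: its errors are parameterized
  (noise, dispersion), not emergent, so provider-contract tests say
  nothing about real model behavior.
- The DeLong CI is asymptotic and degrades below ~10 per class.
- SGNS determinism holds only single-threaded; there is no parallel
  training path.
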