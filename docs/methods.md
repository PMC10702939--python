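# Methods

## Model and procedure

The package treats feature selection for binary text classification as
continuous optimization. Each candidate solution is a vector X ∈ [0, 1]^M
over the M vocabulary terms; coordinate j > 0.5 selects term j. A selected
mask S is scored by

    fitness(S) = w₁ · acc_KNN(S) + w₂ · (M − |S|) / M,

where acc_KNN is the accuracy of a k-nearest-neighbor classifier restricted
to the selected columns, measured on a validation set held out from the
training split. Because w₁ + w₂ = 1 and both terms lie in [0, 1], fitness
lies in [0, 1]; at fixed accuracy, removing features never decreases it.

The optimizer is a grey wolf algorithm with dimension-learning-based
hunting. Per iteration, with a(t) = 2(1 − t/MaxIter) and the deterministic
schedule r₁(t) = 2 − 2t/MaxIter replacing the usual uniform r₁ draw:

1. the population is ranked; the three best wolves become the leaders;
2. every wolf builds a leader-following candidate
   (mean of X_k − A·|C_k·X_k − X| over the three leaders, A = 2·a·r₁ − a,
   C_k = 2·r₂ with r₂ uniform or chaotic per variant);
3. every wolf builds a DLH candidate: with radius R = ‖X − X_GWO‖ and the
   neighbor set {X_j : ‖X_j − X‖ ≤ R} (never empty — the wolf itself is a
   member at distance 0), each dimension takes
   X_d + rand·(X_{n,d} − X_{r,d}) with a fresh neighbor n, population
   member r and multiplier per dimension;
4. the fitter candidate (ties favor the leader-following one) replaces the
   wolf only on strict improvement, making the best-so-far trace monotone.

Updates are synchronous: leaders and DLH neighborhoods are computed from
the population snapshot at the top of the iteration. Total fitness
evaluations are exactly N + 2·N·MaxIter.

### Chaotic variants

Three chaotic maps supply deterministic ergodic sequences:

- circle: z ← z + y₂ − (y₁/2π)·sin(2πz), y₁ = 0.5, y₂ = 0.2; the emitted
  unit value is the raw value reduced modulo 1 (the raw orbit drifts
  upward; the mod-1 reduction is the standard circle-map convention and
  keeps consumers in [0, 1]);
- logistic: z ← μz(1 − z), μ = 4 (fully chaotic regime; already in [0, 1]);
- iterative: z ← sin(yπ/z), y = 0.7; the raw orbit covers [−1, 1], the
  unit value is its absolute value. If |z| < 10⁻¹² the stream reseeds to z₁
  rather than divide by ~0 (exact arithmetic can reach 0, e.g. y = 0.7,
  z = 0.35).

All maps start from z₁ = 0.7 by default. The iterative map's y parameter
is only constrained to (0, 1) in the literature on this optimizer family;
0.7 was chosen to mirror the shared z₁ default and is configurable.

CNI-GWO1 consumes the orbit row-major during initialization
(X_ij = l_j + z·(u_j − l_j)); CNI-GWO2/3/4 consume one value per wolf per
iteration for the α/β/δ leader's C coefficient (C = 2z). Each run owns one
stream, so results are a pure function of (config, seed).

### Design choices where the design was open

- **Leader distance form.** Descriptions of this family sometimes typeset
  the hunting distance as |C − X_k − X|; the canonical multiplicative
  |C·X_k − X| is implemented (the encircling definition is multiplicative),
  with a `literal_distance` flag for the subtraction form.
- **Direction.** The engine maximizes; selection comparisons written for
  minimization are mirrored.
- **Boundary handling.** Candidates are clamped coordinate-wise to the
  bounds after every move, keeping the 0/1 decoding meaningful.
- **Feature term.** The reduction ratio (M − |S|)/M is the default: under
  maximization it is the direction that actually keeps subsets small. The
  literal ratio |S|/M is selectable for comparison.
- **Empty-mask guard.** If no coordinate clears the 0.5 threshold the
  single largest coordinate is selected (first index on exact ties), so
  the classifier always has at least one feature.
- **Fitness evaluation split.** Fitness is scored on a stratified 25 %
  hold-out from the training portion, not on the final test split;
  evaluating against the test set during the search leaks information and
  inflates test metrics. Passing the test split explicitly
  (`paper_protocol` in `detect`) reproduces that leaky arrangement when a
  like-for-like comparison is wanted.
- **KNN.** k = 5 by default (configurable). On binary data squared
  Euclidean distance equals Hamming distance, which is computed exactly via
  one matrix product. Even vote splits fall back to the nearest neighbor's
  label; equal distances are resolved toward the lowest training index, so
  predictions are deterministic. This tie policy is why the classifier is
  implemented here rather than delegated to a library implementation (which
  is used as an independent cross-check in the tests instead).
- **Friedman test.** Average ranks on ties, tie-corrected χ² statistic,
  df = k − 1, rejection when χ² exceeds the (1 − α) quantile. Larger rank =
  better value by default, matching the convention in which the winning
  algorithm carries the largest mean rank; a flag flips the direction.
  Degenerate all-tied inputs give χ² = 0 and no rejection.
- **0/0 metrics.** Precision, sensitivity, F and MCC define 0/0 as 0.
- **Quartiles** use linear interpolation (numpy default).

## Text pipeline

Preprocessing lowercases, strips URLs, @-handles, digits and punctuation,
tokenizes on whitespace, removes stopwords from a bundled classic English
list, and drops tokens shorter than 2 characters; every step is
configurable. Vocabulary = tokens in ≥ min_df documents (default 2),
sorted lexicographically; the matrix records binary presence. The 80/20
train/test split is stratified by default — safer under the ~81/19 class
imbalance these corpora show — and can be disabled.

## Synthetic data: what it emulates and what it does not

`SynthSpec` generates labels with a fixed positive fraction (default 0.831,
matching the imbalance of the motivating corpus), plants `n_informative`
columns present with probability p_pos (default 0.9) in the positive class
and p_neg (0.1) in the negative class, and fills the rest with
class-independent Bernoulli(q = 0.5) noise. It can render every row as a
pseudo-text over a generated vocabulary whose tokens survive the default
preprocessing, so the corpus → matrix path is exercised end to end and the
rebuilt matrix equals the planted one (restricted to observed columns).

This emulates binary presence features, class imbalance and a sparse
informative subset. It does **not** emulate correlated or redundant terms,
topic structure, document-length variation, label noise, or vocabulary
burstiness — passing tests show the optimizer reliably finds a planted
separating subset under independent noise, not that real social-media text
is classified at any particular accuracy.

## Problem sizes and numerical notes

The benchmark configuration used by the tests and the acceptance script is
400 documents × 80 terms with 10 informative columns, population 30, 100
iterations (6,030 fitness evaluations per run) and 5 seeded runs per
variant — large enough that all five variants reach ≥ 0.95 validation
accuracy with a sub-full mask in at least 4 of 5 seeds, small enough to
re-run routinely. Distances on binary data are computed in exact integer
arithmetic (via the Hamming identity); the only tolerances in play are the
10⁻¹² reseed guard of the iterative map and a 10⁻¹⁵ slack in the DLH
radius comparison to absorb floating-point norm rounding.

## Known limitations

- The comparison metaheuristics (ABC, HHO, SCA, …) and classical ML
  baselines are out of scope; the Friedman machinery accepts any results
  table, but only the five variants here are implemented.
- Wrapper selection with KNN re-fits on every evaluation; corpora beyond
  ~10⁴ documents × ~10⁴ terms will want subsampling or a cheaper inner
  classifier.
- No stemming/lemmatization; the tokenizer is whitespace/regex based and
  English-oriented.
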