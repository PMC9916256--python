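# Methods

## Problem setting

`ssoddi` predicts drug–drug / drug–target interactions in the
positive–unlabeled (PU) setting: a bipartite 0/1 matrix records *known*
interactions, and every remaining pair is unlabeled rather than a
confirmed negative. The predictor is a multilabel LSTM autoencoder
(MLSTM-AE) over fixed-length per-pair feature sequences, with its
hyperparameters tuned by sparrow search optimization (SSO). Two side
components complete the workflow: sentence preprocessing with drug
blinding for text-derived interaction data, and a lexicon-based severity
grader for interaction sentences.

## Text preprocessing

A sentence with `n` annotated drug mentions contains
`max(0, Σ_{i=1..n}(i−1)) = n(n−1)/2` candidate pairs. For each pair the
sentence is duplicated and blinded: the earlier focal mention becomes
`DrugA`, the later `DrugB`, all other mentions `DrugN`. Blinding forces a
classifier to learn relational cues ("DrugA might reduce the effect of
DrugB") instead of memorizing drug names; mapping the non-focal mentions
to `DrugN` likewise prevents name leakage. Whether a multi-pair sentence
should be shared or duplicated across its pairs is genuinely open; we
duplicate, which keeps each training instance a single (sentence, pair)
unit.

Tokens are embedded through a matrix `WEMB ∈ R^{ds×|V|}` (token *i* is
column *i*); sequences are post-padded with the PAD column (fixed at
zero) or truncated to length `T`, and out-of-vocabulary tokens map to a
reserved UNK column. Cleaning is lowercasing, punctuation stripping and
a small rule-based suffix lemmatizer (plural/-ing/-ed rules with a
3-character stem guard). A rule-based lemmatizer is crude compared with
a WordNet one — it exists so that lexicon matching and vocabulary
construction see normalized forms, and its rules are visible and
testable. Embeddings are read and written in the word2vec text format;
training embeddings on a literature-scale corpus is out of scope.

## The MLSTM-AE

Each sample is a sequence `x_i = (x_i1 … x_iT)`, `x_it ∈ R^d`, with a
binary label row `y_i ∈ {0,1}^C`. A single-layer LSTM encoder produces
hidden states `h_i^1 … h_i^T`; the final state `h_i^T` is the sequence
representation. Two heads share it:

* **Reconstruction.** A decoder LSTM with the same architecture shape,
  initialized with `h_i^T` and driven by zero inputs, emits `x̂_i`; the
  target is the *time-flipped* input `(x_iT, …, x_i1)`. Flipping makes
  the first decoding step reproduce the most recently encoded step, the
  easiest-first ordering for an autoencoder. The loss sums over time and
  features but averages over samples only:
  `L_rec = (1/N) Σ_i Σ_t ‖x_it − x̂_it‖²`.
* **Classification.** A fully connected head with per-label sigmoid
  gives scores `p_i ∈ [0,1]^C`. The target is the L1-normalized label
  row `p̂_i = y_i/‖y_i‖₁` and the loss is
  `L_cls = (1/N) Σ_i Σ_c (p_ic − p̂_ic)²`. Rows with `‖y_i‖₁ = 0` are
  excluded with a warning (the normalized target is undefined there);
  the average runs over the retained rows. We deliberately do *not*
  row-normalize the predictions inside the loss: normalization couples
  each label's gradient to the whole row sum and destabilizes training
  when most rows are one-hot, while plain MSE against `p̂` keeps the
  loss a strict function of the printed quantities.

The joint objective is `L = L_cls + γ·L_rec` with `γ ≥ 0` (default 1.0;
`γ` is one of the tuned hyperparameters). The whole model — forward,
backpropagation through time, Adam — is implemented in numpy; analytic
gradients are checked against central finite differences in the test
suite (atol 1e-6), and the vectorized losses against naive loop oracles
(1e-10). Training is full-precision, single-threaded, and bit-reproducible:
one `numpy` generator per run seed drives the train/validation split,
Glorot-uniform initialization (forget-gate bias +1), batch shuffling and
dropout, and the returned parameters are the checkpoint with the lowest
validation loss seen. A non-finite loss aborts with diagnostics rather
than continuing.

## Sparrow search optimization

SSO maintains `NP` positions in a bounded box and splits them by fitness
rank each iteration (ranks 1-based, best = 1):

* **Discoverers** (best `⌈PD·NP⌉`): with a per-sparrow warning draw
  `R2 ~ U(0,1)`, if `R2 < ST` the position contracts,
  `X ← X·exp(−i/(α·T_max))`, `α ~ U(0,1]`; otherwise it takes a random
  step `X ← X + O·G` with `O ~ N(0,1)` and `G` the all-ones row.
* **Joiners** (the rest): a sparrow ranked past the population midpoint
  jumps to `O·exp((X_w − X)/i²)` elementwise (`X_w` the worst position);
  the better half follows the best position `X_b + |X − X_b|·B`, `B` a
  row of ±1 draws.
* **Guarders** (`⌈SD·NP⌉` drawn uniformly each iteration): a non-best
  guarder moves toward the global best `X_best + β·|X − X_best|`; one
  already at the best fitness steps away from the worst,
  `X + K·(X − X_worst)/((f_i − f_w) + ε)`.

β and K are nominally "random integers in [−1,1]"; integer draws in
{−1, 0, 1} degenerate (a third of moves vanish, the rest are full-length
jumps), so the defaults are continuous — `β ~ N(0,1)` truncated to
[−1,1], `K ~ U[−1,1]` — with integer draws available behind config
flags. Positions are clipped to the box after every move; an elitist
archive keeps the best position ever evaluated, so the reported
best-fitness trace is monotonically non-increasing. NaN objectives are
treated as +∞ with a warning. Defaults `ST = 0.8`, `PD = SD = 0.2`,
`ε = 1e−12`.

For hyperparameter tuning the fitness is the classifier error rate in
percent on a validation split, `100 · (#misclassified / N)`, with a
sample misclassified when any thresholded label bit differs (exact-match
criterion; per-label Hamming error would be a looser alternative). The
search box covers log10 learning rate ([−2.5, −1.0]), hidden size
([8, 48]), batch size ([16, 96]) and γ ([0, 2]); integer dimensions are
decoded by rounding. Because exact-match error on a small validation
split is coarse, many candidates can tie at zero error and the tuner
then picks among them arbitrarily — a property of the prescribed
fitness, visible in the tuning traces.

## Severity grading

A polarity lexicon maps tokens to scores in [−1, 1]; a sentence's
polarity is the mean of its matched tokens' scores (0 with zero matches).
Scores below −1/3 grade as high severity / dangerous, above +1/3 as low
severity / advantageous, and the middle band as moderate / neutral. The
thresholds are symmetric thirds of the score range and configurable; the
convention that *negative* polarity means *dangerous* follows the
framing of harmful interactions as negatively phrased. The bundled
lexicon is a small hand-written synthetic demonstration table; a
converter from a full resource such as SentiWordNet is intentionally out
of scope.

## Synthetic data generator

The generator emulates small gold-standard interaction matrices
(enzyme/GPCR/ion-channel/nuclear-receptor scale) with *planted* low-rank
structure so that recovery is a meaningful test: latent factors
`U ∈ R^{n_drugs×r}`, `V ∈ R^{n_targets×r}` are standard normal, the pair
affinity is `⟨u_j, v_i⟩`, and exactly `⌈density·n_drugs·n_targets⌉`
top-affinity pairs become interactions (deterministic thresholding, not
Bernoulli, so positive counts are exact). Each pair's sequence carries
the drug latent row (projected to width `d` by a shared seeded random
map) in the first `T/2` steps and the target row in the last `T/2`,
plus i.i.d. `N(0, noise_sd²)` noise. Labels are `[interacts,
no-interaction]` (C = 2): the explicit complement bit keeps `‖y‖₁ ≥ 1`
on every row, which the classification loss requires; with `C ≥ 3`
additional type bits encode the sign of the leading latent coordinate
product on positives.

Defaults: 60 drugs × 40 targets, rank 3, density 0.05 (120
interactions), noise_sd 0.1, T = 4, d = 8, C = 2. These sizes make a
full SSO tune (NP = 10, T_max = 20, ≈250 model fits) plus five-seed CV a
matter of minutes on one CPU while leaving enough positives for 5-fold
CV with balanced negative sampling. What the generator does **not**
emulate: chemical-structure or sequence-derived features, hubness and
degree skew of real interaction networks, correlated noise, or
label-noise from missing annotations — so green tests demonstrate that
the pipeline recovers planted low-rank structure, not that it matches
published performance on the real gold standards.

For interaction matrices loaded from files the same featurization is
derived on the fly: truncated SVD factors of the 0/1 matrix (scaled by
√singular-values) stand in for the latent rows. Note these factors are
computed from the full matrix, including held-out entries — standard for
matrix-factorization-style baselines but a form of transductive leakage;
CV numbers on file data are accordingly optimistic.

## Evaluation protocol

AUC is the Mann–Whitney probability that a random positive outranks a
random negative (ties ½); AUPR is average precision, the step-wise sum
of precision × recall increments evaluated at distinct score thresholds
(tied scores enter together). Both are delegated to scikit-learn and
cross-checked against brute-force definitional oracles to 1e-12 in the
tests. CV runs 5 folds over the known positives, each fold paired with
an equal-size negative sample from the unlabeled pairs; one master seed
per repetition drives folds, negative sampling and weight
initialization, and metrics are reported as percentages to 2 decimals.
The top-k% labeling curve ranks all unlabeled pairs by score and counts,
within the top `⌈k/100·n⌉` (ties broken by stable order), those at or
above θ = 0.5; the counts are non-decreasing in k by construction.

## Pipeline and reproducibility

The `ssoddi` CLI mirrors the stage order (preprocess / simulate / tune /
train / evaluate / severity / run) over a YAML config. One master seed
is split into per-stage streams via `numpy.random.SeedSequence.spawn`;
every stage's randomness descends from its stream, so identical configs
produce byte-identical metric CSVs and reports. Checkpoints are NPZ with
a JSON sidecar (hyperparameters, seed, loss history).

## Known limitations

* The reference experiments hold out 20% of a balanced sample built
  from 120 positives, so held-out metrics carry sampling noise of
  several AUC points; the permuted-label null is centered at 50% with a
  standard deviation near 10 on 48 test pairs.
* Exact-match validation error is a coarse tuning fitness (see above);
  tuned hyperparameters are not guaranteed to beat the defaults.
* The LSTM is single-layer and CPU-bound by design; very long sequences
  (T ≫ 100) would make the python-loop BPTT the bottleneck.
* Severity grading is bag-of-words: negation ("does not increase
  toxicity") and scope are not modeled.
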