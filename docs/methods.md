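# Methods

This note records the models, estimators, numerical choices and known
limitations behind `suctionmorph`, in the order the pipeline runs them.

## Trait data model

Scores are real numbers in [0, 3] with `NaN` as the missing marker.
Although ordinal scores are conceptually integers, composite indices are
fractional and nothing in the scoring scheme forbids intermediate values,
so the storage type is float throughout. Characters carry a class tag
(`osteo_dental` vs `soft_tissue`) and an optional *binary* flag
restricting legal values to {0, 3} (the throat-grooves convention: the
trait is either absent or strongly present). Taxon-name matching treats
spaces and underscores as interchangeable and is case-insensitive, since
trait tables and tree tip labels routinely disagree in exactly these
ways; display names preserve the original spelling.

## SSI

`char_mean` (the SSI) is the mean score over the characters available
for a taxon; `char_sum` the sum; `adjusted_ssi` the mean over the
osteology/dentition subset only. The per-taxon score SD uses the sample
(n−1) denominator — the only convention under which the canonical
least-specialized pattern (nine 0s and one 1) yields the pair
(0.1, 0.316). Missing scores renormalize the mean over the observed
characters by default (`n_used` is always reported so consumers can
filter); a strict `error` policy is available. Ranking is by descending
`char_mean` with alphabetical tie-break. The conventional reading of
SSI > 1.00 as strong evidence of specialization is exposed as a
reporting flag (`specialization_threshold`), never hard-coded into any
test statistic.

## Phylogenetic machinery

Trees are rooted with branch lengths in time units; polytomies are
accepted (every formula below is defined on them). The BM covariance
`V[i,j]` is the root-to-MRCA path length. Wherever `V` must be inverted,
or a reciprocal branch length taken, an epsilon of `1e-8 ×` tree depth
guards against zero-length branches (published supertrees contain zero
cherries); the regularization is visible only past the 7th decimal in
cross-checks against an unregularized GLS implementation.

**Ancestral states.** ML reconstruction under BM solves the weighted
squared-change system: each internal state is the 1/branch-length
weighted average of its neighbours, tips fixed. For a Gaussian process
the joint mode equals the marginal means, so this is exactly the
marginal ML/GLS reconstruction and the root solves to the GLS
phylogenetic mean `â = (1ᵀV⁻¹Y)/(1ᵀV⁻¹1)`. The tip-to-internal solve
matrix is cached per tree, which makes the simulation nulls below cheap.

**Rate matrix.** `R̂ = (Y − 1âᵀ)ᵀ V⁻¹ (Y − 1âᵀ)/(n − 1)` on the GLS
residuals; for one trait on an equal-depth star tree this reduces to the
sample variance divided by the depth. A warning (not an error) fires
when n ≤ k, where the estimator is rank-deficient.

**Simulation.** Multivariate BM draws independent Gaussian increments
per edge with covariance `R × branch length`, giving tip values
MVN(root, kron(R, V)). Each replicate uses an independently spawned
stream of the caller's seed, so results are reproducible and independent
of replicate order. Simulated tip sets are returned as an
`(n_reps, n_tips, k)` array.

## Comparative statistics

**Kruskal–Wallis** uses mid-rank ties and the chi-square tail
(`scipy.stats.kruskal`); the tie-correction divisor
`1 − Σ(t³−t)/(N³−N)` is reported alongside. All-identical samples return
H = 0 with a warning. The chi-square tail is an approximation: on a
12-observation example the exact enumeration over all 924 relabelings
differs from it by about 0.06, which is the accuracy a user should
expect at such sizes.

**Blomberg's K** follows the phylogenetically-corrected form: both MSE0
(ordinary mean square) and MSE (`(y−â)ᵀV⁻¹(y−â)/(n−1)`) are centred on
the GLS mean `â`, and the observed MSE0/MSE ratio is divided by its BM
expectation `[tr(V) − n/(1ᵀV⁻¹1)]/(n−1)`. On a star tree the two ratios
coincide and K = 1 identically. The permutation test shuffles values
across tips and counts permutations with MSE at most the observed
(small MSE = strong signal); `p = (1 + #{≤})/(n_perm + 1)`, resolution
`1/(n_perm+1)`, default 1,000 permutations. Values are cross-checked to
7 decimals against an independent R implementation of the same statistic
on a fixed 6-taxon fixture.

**PGLS** is GLS with `sigma = V` (statsmodels); `tree=None` gives OLS.
Two-level feeding-mode predictors are coded Other = 0, Suction = 1, so a
positive slope means higher scores in suction feeders. Inference is by
t-tests with n − p degrees of freedom; coefficients, SEs, t and p match
an independent GLS implementation to 7+ decimals on the frozen fixture.
The regression direction is `score ~ mode`; the reverse is available by
swapping arguments.

## Classifier battery

The labeled taxa are split once (all battery rows share the split, the
fair comparison; `resplit_per_model` reproduces the alternative). Per
class the test count is `round-half-down(class size × fraction)`:
with 42/26 classes at 0.25 this gives 10 + 6 = 16 test taxa and
NIR = 0.625; round-half-up would give 11 + 7 and a different NIR, which
is why the rule is documented and configurable.

Logistic fits use an L2 penalty of 1e−8 (sklearn `C = 1e8`): the
strongest suction predictors separate the classes perfectly, where
unpenalized ML diverges; at this magnitude predictions are unaffected
and, for overlapping classes, weights match the unregularized MLE to
~1e−4 (checked against direct likelihood maximization). A constant
predictor degrades to an intercept-only majority-class model.

Evaluation reports the 2×2 confusion matrix (rows truth, order
[Other, Suction]), accuracy, precision/recall/F1 with Suction positive
(zero-denominator precision and F1 are reported as undefined, not 0),
the exact Clopper–Pearson 95% interval for accuracy
(`lower = Beta(0.025; x, n−x+1)` quantile, `upper = Beta(0.975; x+1,
n−x)`, with the conventional endpoints at x = 0 and x = n), and the
one-sided exact binomial tail `P(X ≥ correct | n, NIR)`. Because the
split is random, specific accuracies on any one dataset are
seed-dependent; the CI/p machinery is exact and seed-free.

## Morphospace and convergence

PCA z-scores each character (n−1 denominator), drops zero-variance
characters with a warning, and decomposes by SVD. Axis signs are fixed
by making each axis's largest-magnitude loading positive, so reports are
bit-reproducible across platforms. Ordinal skull characters are treated
as numeric before standardization — a deliberate simplification matching
the character-matrix PCA tradition rather than a geometric-morphometric
pipeline. Variance fractions are over the retained (nonzero) axes and
sum to 1.

`C1 = 1 − Dtip/Dmax` is computed over all supplied axes. `Dmax`
candidates are all state pairs along the two lineages from the MRCA, one
taken from each lineage, *including the tips* (Stayton's definition);
the stricter ancestors-only reading is available via `ancestors_only`.
A consequence of including the tips is that `Dmax ≥ Dtip` always, so
C1 ∈ [0, 1] by construction and its null mean is small but positive —
about 0.12 for 3 trait axes on a 32-tip tree, falling to ~0.01 by 20
axes as distances concentrate. With `ancestors_only` C1 can be negative;
negative values are reported, not clamped (a clamping flag exists).
If both lineages carry zero divergence (Dmax ≈ 0 at 1e−12 relative
tolerance) C1 is defined as 0 with a warning.

The group statistic is the mean C1 over all focal pairs (per-pair
values, Dtip and Dmax are always reported). Significance: tip data are
re-simulated `n_sim` times under multivariate BM with `R̂` estimated
from the observed scores and root at `â`; `p = (1 + #{sim ≥ obs})/
(n_sim + 1)`. The default uses the full estimated rate matrix;
`diagonal_rate` restricts to per-axis independent rates. Under a true BM
null the p-values are uniform (verified by a KS check at 500 replicates
with n_sim = 199 — sizes chosen to keep the routine test run fast while
leaving the p-value resolution at 1/200).

## Synthetic data generator

The generator defines the study conditions the tests run under:

- **Tree**: Yule pure-birth, default 68 tips, birth rate 1 (waiting
  times Exp(k·λ); pendant branches extended by one final waiting time so
  the tree is ultrametric).
- **Specialist clades**: 5 mutually non-nested internal nodes, each
  subtending at most 25% of tips, mirroring the independent origins of
  capture suction feeding; their tips are labeled Suction.
- **Characters**: each is a latent BM liability (rate 1) discretized at
  thresholds placed at the 0.4/0.65/0.85 quantiles of the stationary tip
  distribution, so baseline scores skew low as in the real matrix.
  Specialist tips get a liability shift δ (default 5 ≈ 2.6 tip SDs)
  scaled by per-character attenuation factors; the first character
  (blunt-rostrum analogue) is deliberately weak (0.2), reproducing the
  "weak predictor" phenomenon. The binary character scores 3 when its
  liability clears the top threshold.
- **Skull characters**: 25 liabilities with no shift — phylogenetically
  structured, non-convergent.

The threshold (liability) model was chosen over direct ordinal Markov
chains because it produces the strong phylogenetic signal observed in
real score matrices with a single interpretable rate parameter.

What the generator does *not* emulate: real matrices have correlated
characters (functional integration), non-Brownian evolution, observer
error, and missing data; tips here are exchangeable within the tree.
Passing tests therefore demonstrate correctness of the estimators and
recovery of planted effects under the stated model, not robustness to
every feature of empirical data.

A caution that is easy to miss: because labels are clades, characters
correlate with labels through shared ancestry even at δ = 0, so
non-phylogenetic tests (Kruskal–Wallis, the classifier) are *expected*
to fire above their nominal rate on δ = 0 data — that confounding is the
reason the PGLS stage exists. Nominal-level calibration checks therefore
permute labels across tips.

## Problem sizes used in routine runs

Test-suite and acceptance-script simulations use the study-scale
defaults (68 taxa, 1,000 simulations) where a single run suffices, and
reduced sizes for replicated Monte-Carlo checks (e.g., 200 BM replicates
on 64-tip trees for estimator recovery; 500 replicates at n_sim = 199
for the uniformity check; 399 simulations per seed for the multi-seed
convergence check). These sizes are the package's own accuracy/runtime
trade-off and are recorded in the individual tests.

## Known limitations

- BM only: no Ornstein–Uhlenbeck or lambda transformations of V, no
  multi-regime models; no multiple-testing correction in the
  correlation battery (none is applied upstream either).
- Convergence indices beyond C1 (C2–C4, Wheatsheaf) are out of scope.
- The reference phylogeny is always an external input; the package never
  bundles a published tree.
- No imputation models for missing scores beyond renormalization and
  optional mean-imputation in the PCA.
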