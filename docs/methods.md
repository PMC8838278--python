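# Methods

This note documents the models and procedures implemented in
`dermfusion`, the parameter defaults and why they were chosen, the design
decisions taken where the method family leaves choices open, and what the
synthetic benchmarks do and do not demonstrate.

## Contrast enhancement

The stretch operates per channel on the 0–255 scale. For an image `X`
with pixels `x_i` and a reference mean `m`:

- absolute mean deviation `MD = (1/n) Σ |x_i − m|`;
- sample skewness `SK = Σ (x_i − x̄)³ / ((n−1) σ³)` with `σ` the sample
  standard deviation (n−1 denominator), defined as 0 when `σ = 0`;
- transform `I₁ = |MD + X|`, `I_F = |I₁ − SK|`, clipped to `[0, 255]`.

`MD` and `SK` are scalar statistics broadcast over pixels; they have no
per-pixel definition. The reference mean is pooled over the whole dataset
by default (`AMDSkewnessEnhancer.fit`), so each image is stretched
against a common anchor; a per-image reference is available for
single-image use. RGB channels are treated independently. Clipping keeps
8-bit display compatibility; the absolute values already prevent
negatives. Degenerate inputs: a constant image with a matching reference
is a fixed point of the transform.

## Feature extraction

Real studies extract deep features from the global average-pool layer of
a fine-tuned CNN (1056-wide for NasNet-Large). Training such a backbone
is out of scope here; `ExternalBackbone` is the adapter contract (any
`images → (n, d)` callable, with width validation) through which such
features plug in. `ToyBackbone` is the deterministic stand-in used
throughout the tests: 3×3 box smoothing (valid convolution), ReLU, 2×2
average pooling, then per-patch mean / standard deviation / absolute mean
deviation on a 4×4 grid per channel — 144 features for RGB. It is
parameter-light and bitwise reproducible; it is *not* a claim about CNN
representations, only a carrier of image statistics sufficient to test
the downstream stages.

## HWOA: wrapper selection by whale optimization

Agents are positions in `[0,1]^D`, one coordinate per feature; a
coordinate ≥ 0.5 switches its feature on (an all-off candidate is
repaired to its single largest coordinate). Per iteration each agent
takes one of the standard whale moves — encircling the best solution,
spiraling around it (pitch `b = 1`), or exploring relative to a random
agent — with the shrink coefficient `α = 2 − 2t/maxIt`. The
exploitation/exploration switch `|V2| ≥ 1` is evaluated on the infinity
norm of the per-dimension coefficient vector `V2 = 2αr − α`; the norm is
a free choice in the vectorized formulation, and the infinity norm gives
balanced phases over the schedule.

Fitness of a candidate mask: `0.99 · err + 0.01 · |R|/D`, where `err` is
the validation error of an ELM (50 hidden nodes) and `|R|/D` the selected
fraction. The weights keep error dominant while breaking ties toward
smaller subsets, the standard wrapper-selection compromise. `err` is the
*average* over 4 fixed stratified 70/30 splits of the training data
(`n_eval_splits = 4`): a single 60-sample holdout has a binomial noise
floor of ~4.6 points, enough for a lucky mask to become an unbeatable
cached incumbent; averaging four splits roughly halves that noise and
measurably improves recovery of planted features. Fitness values are
cached by mask, so converged swarms cost little.

After the final iteration the best position is refined by the AMD cut:
features whose coordinate is at least the absolute mean deviation of the
coordinate vector are retained, with a top-k fallback (k = 5% of D, at
least 1) against empty selections. The cut thresholds scores against a
dispersion rather than a location statistic — an unusual rule that only
bites once the swarm has polarized coordinates toward 0/1; with the
default budget (20 agents × 100 iterations) it behaves as a mild
de-noising of the binarized best mask.

Defaults: `n_agents = 20`, `max_iterations = 100`, threshold 0.5,
`n_eval_splits = 4`. On the standard benchmark (below) this recovers 85%
of planted informative features while selecting a third of all columns,
in ~5 s per run. Shorter budgets leave coordinates unpolarized (the AMD
cut then retains most features); much longer budgets over-converge and
start dropping informative features whose individual contribution is
below the fitness noise floor.

## EMI: fuzzy entropy–mutual information filter

Each feature is min–max normalized to `[0,1]` and read as a membership
vector; its fuzzy entropy is `FE = −K Σ [m ln m + (1−m) ln(1−m)]`
(`K = 1`, nats; zero for crisp 0/1 memberships, maximal at 0.5).
Relevance is the mutual information between the (16-bin equal-width
discretized) feature and the class label, computed from the empirical
joint table; entropies satisfy `I = H(X) + H(Y) − H(X,Y)` exactly on the
table. The combined score `s_j = MI_j · FE_j / max_k FE_k` weights
relevance by relative fuzziness — it preserves the MI ranking among
features of comparable fuzziness while suppressing near-constant columns,
whose fuzzy entropy is defined as 0 (min–max normalization is degenerate
there, and the all-0.5 membership reading would absurdly maximize their
weight). Selection keeps features with `s_j ≥ mean(s)`. The filter is
fully deterministic. The mutual information is taken against the class
label, making the filter supervised; the feature–feature reading of the
same quantity is not implemented.

## Fusion by (multiset) canonical correlation analysis

For two sets the classical eigenproblem
`Z_xx⁻¹ Z_xy Z_yy⁻¹ Z_yx a_x = λ a_x` is solved on column-centered
sample covariances (n−1 denominator; the correlation objective is
invariant to this convention), with eigenvalues `λ = ρ²` the squared
canonical correlations and partner directions
`a_y ∝ Z_yy⁻¹ Z_yx a_x`. Projection columns are normalized to unit
projected variance. For three sets the sum-of-pairwise-correlations
(MAXVAR-style) generalized eigenproblem `C a = λ D a` is solved — `C` the
off-diagonal cross-covariance block matrix, `D` the block diagonal of
within-covariances — a standard multiset formulation chosen because the
three-set block equation with zero diagonal does not define a consistent
eigenproblem as written elsewhere.

The fused matrix concatenates the projected sets, sorts columns by
decreasing variance, and greedily prunes columns whose absolute Pearson
correlation with an already-kept column exceeds 0.95 (exact duplicates
always drop; the first, highest-variance column is never dropped).

Within-set blocks are ridge-regularized, `Z_kk + ε I` with
`ε = ridge · trace(Z_kk)/d_k`. The bare solver (`solve_mdcca`) defaults
to `ridge = 1e−6` — numerical rank protection only, so its canonical
correlations match a whitened-SVD computation to 1e−6. The pipeline-facing
estimator (`MultisetCCAFuser`) defaults to `ridge = 1.0` and keeps only
components whose eigenvalue exceeds the mean eigenvalue (Kaiser-style
cut). The distinction matters: with ~100 observations and sets tens of
columns wide, unregularized sample CCA saturates (every direction
correlates near 1, including directions that only align shared noise
columns), and keeping the full spectrum demonstrably destroys downstream
accuracy; the heavy ridge shrinks the problem toward a cross-covariance
(PLS-like) criterion whose spectrum decays, and the Kaiser cut keeps the
genuinely shared directions. Both knobs are plain parameters.

## Extreme learning machine

Hidden weights and biases are drawn once from `U[−1, 1]` (seeded);
the hidden response is `g(z) = exp(−z²)` applied to the affine
pre-activation `w_j·a + c_j` — the radial-basis squashing of the affine
form; a centre-based Gaussian `exp(−|c|·‖a − w‖²)` is available behind
the activation parameter. Targets are one-hot with {0,1} coding; output
weights solve `β = H‡ B` via `numpy.linalg.pinv` with relative cutoff
1e−12; prediction is the argmax column (ties to the lowest class index).

Inputs are standardized per column and shrunk by `1/√d` before the random
affine map. Without this, wide inputs drive `|z|` to tens and `exp(−z²)`
underflows, leaving a numerically dead hidden layer; the scaling keeps
pre-activations O(1) at any width and is recorded in the fitted model.

The default hidden width is `min(1000, n_train // 2)`. `L` must stay
below the training count: a square `H` interpolates the training set
exactly (the interpolation property is itself verified in the tests) and
generalizes at chance level.

Metrics: accuracy, macro precision (a class never predicted contributes
0), and `FDR = 100 − precision` — the convention of the dermoscopy
benchmark tables. Wall-clock time is recorded but never used as a
correctness criterion.

## Evaluation protocol

Stratified 50:50 train/test holdout by default; stratified 10-fold CV
behind a flag (published tables in this family report both without
distinguishing them; the holdout is the cheaper default and stratification
protects rare classes). Four experiments run on one shared split:
original features, HWOA subset, EMI subset, fused set. One master seed
fans out to per-stage seeds via `numpy.random.SeedSequence` spawn keys,
so a full run is bit-reproducible and each stage independently so.

## Synthetic benchmarks: what they show

`make_features` plants structure with retrievable ground truth:
informative columns are class-conditional Gaussians with unit noise whose
per-column class means are a seeded random permutation of equally spaced
levels spanning `class_separation` (in noise-σ units). Every informative
column therefore separates classes on its own (a per-column F-statistic
ranks all of them above noise), while the permutations differ across
columns, so the columns are jointly complementary and a selector must
keep essentially all of them — a shared one-dimensional signal would make
high recall meaningless. Redundant columns are random dense linear
combinations of the informative block plus `N(0, 0.01)` jitter; noise
columns are standard normal. Classes are balanced by default (an
imbalance knob exists); seven classes mirror the seven-lesion-class
setting.

The **standard selection benchmark** used by the tests and the acceptance
script is 200 samples × 60 features with 8 informative and 52 noise
columns at separation 3. Redundant columns are deliberately absent there:
a redundant set spans the informative signal by construction, so a
wrapper can swap informative for redundant columns with no fitness cost,
and informative-recall would be capped around 0.65 regardless of the
optimizer — measuring nothing about search quality. The 8+4+48 layout
(the `SyntheticSpec` default) is kept for tests of the generator itself
and of redundancy-related behaviour.

`make_images` renders a class-coded ellipse (colour offset, eccentricity,
internal texture) on smoothed-noise background; `contrast` scales every
class-dependent term, so `contrast = 0` is an exact null in which images
carry no class information — the end-to-end control. The images make no
attempt at dermoscopic realism.

Passing these benchmarks shows that the selectors recover planted,
individually-detectable signal among isotropic noise, and that fusion
preserves and concentrates complementary selected information at small
sample sizes. It does not show that the pipeline reaches any particular
accuracy on real dermoscopy data, which depends on the CNN backbone and
the datasets; those runs require the external-backbone path.

Problem sizes throughout (200×60 matrices, 140 images of 64×64, 20×100
optimizer budgets) are chosen so the full suite and the acceptance script
run in minutes on one CPU while keeping every statistical check away from
its noise floor.

## Known limitations

- The WOA branch condition on a vector coefficient has no canonical
  scalarization; results can differ between per-dimension and per-agent
  branching conventions.
- The AMD refinement is sensitive to how polarized the best position is;
  with very short budgets it approaches a no-op.
- Equal-width MI binning (16 bins) is a coarse estimator; no KSG/kernel
  estimators, and no redundancy-aware filters (mRMR and relatives) are
  provided.
- Multiset CCA beyond three sets, kernel and sparse CCA are out of scope.
- The ELM is not calibrated; decision scores are least-squares fits to
  one-hot targets, not probabilities.
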