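# Methods

This note documents the models and procedures implemented in aquamap, the
parameter choices that matter, what the synthetic-data generator does and
does not emulate, and the numerical decisions taken where the design was
genuinely open.

## Grid domain and feature preparation

The study area is a regular lattice of square cells (default 1 km),
indexed row-major from the north-west corner with half-open cell extents
and centres at ((r+0.5)·c, (c+0.5)·c) — stated explicitly so point-to-cell
assignment and resampling are bit-reproducible. Numerical layers are
resampled bilinearly at destination cell centres, categorical layers by
nearest source centre; destination centres in the half-cell border strip
outside the source-centre hull are clamped to the edge (constant
extrapolation), which makes resampling a grid onto itself an exact
identity.

Collinearity screening computes Pearson's r (numerical–numerical),
Cramér's V from the uncorrected chi-square of the joint contingency table
(categorical–categorical) and the correlation ratio η² (mixed) over
masked cells. Default thresholds are r ≤ 0.7, V ≤ 0.65, η² ≤ 0.7 —
bracketing the magnitudes at which practitioners typically drop a member
of a pair — and all are configurable. When a pair exceeds its threshold,
the member with the larger mean absolute association to all other layers
is dropped (tie: the later layer in stack order). This rule is
deterministic and keeps the maximal amount of independent information;
screening is idempotent by construction. Constant layers make a pair's
statistic undefined; such pairs are skipped with a warning rather than
failing the screen.

Categorical features are one-hot encoded with the reference category
kept: the models are pure presence/background discriminators with either
an L1 path (MaxEnt) or weight decay (MLP), so there is no identifiability
reason to drop a column, and keeping it makes permutation importances per
original layer straightforward.

## Presence-only estimation

With prevalence unidentifiable from presence-only data, both models
target the relative probability p* (presence-to-area density ratio),
reported on [0, 1] under an assumed prevalence of 0.5.

### MaxEnt

The presence density is parameterized as an exponential tilt of the
background density with basis classes linear, quadratic, product, hinge,
threshold, and categorical indicators. Numerical features are min-max
scaled to [0, 1] on background statistics before expansion (the standard
convention; hinge/threshold knots are then placed at k/(K+1), K = 5 per
class by default). Scaled values outside [−0.5, 1.5] indicate prediction
far outside the training support; they are clipped into [0, 1] with a
warning.

The objective — mean of α + βᵀh(z) over presence rows minus Σλⱼ|βⱼ|,
with α = −log of the background mean of exp(βᵀh) — is concave; the L1
term is handled exactly by splitting β into positive and negative parts
with box constraints and solving with L-BFGS-B. Regularization weights
are a single scale (default 1.0) times a per-class multiplier (hinge and
threshold doubled, as their many knots otherwise overfit), divided by
√m (m = number of presence rows) so the penalty vanishes at the classic
parametric rate as presence information grows. Zero-variance basis
columns are dropped with a warning. A perfectly separating feature with
no penalty drives its coefficient along a flat ridge of the objective;
coefficients are therefore boxed at ±30 and any coefficient beyond half
that bound is reported as a separability stop (converged = False) rather
than silently returned.

The raw Gibbs density q is mapped to p* = qc/(1+qc) with c calibrated by
root-finding so the background mean of p* equals the assumed prevalence
0.5; the raw density remains available for users preferring the
uncalibrated ratio. With β = 0 this yields p* ≡ 0.5 exactly.

### MLP

The perceptron is trained with scikit-learn's MLPClassifier (log loss,
Adam), inputs standardized to zero mean and unit variance on training
rows. Prediction runs the forward pass directly on the stored weights so
models round-trip losslessly through JSON. The hyperparameter grid
(eleven one-layer and eleven two-layer widths from 5 to 100; identity /
logistic / tanh / relu; constant / inverse-scaling / adaptive learning
rates; iteration caps 500/1000/2500) is searched by uniform random
sampling — reproducible and sufficient at the default 200 trials — with
stratified 5-fold cross-validation scored by mean validation log loss;
the first trial attaining the minimum wins, and among its fold models the
one with the lowest loss on the held-aside evaluation partition is
returned. The grid's `l1_ratio` entry is ambiguous for an MLP whose
library implementation exposes only an L2 weight-decay term; it is
implemented as a scaling of that term (alpha·(1−l1_ratio), so 1.0
disables decay) and documented as such.

Permutation importance shuffles each original feature (all one-hot
columns of a categorical jointly, with one permutation), averages the
log-loss increase over repeats and divides by the unpermuted loss; a
perfect fit (zero loss) returns unnormalized contributions with a
warning.

## Background sampling

Background cells are drawn from masked cells carrying no recorded
presence of any access type. The default sample size is ratio × presence
count (ratio 4), drawn without replacement; when the eligible pool is
smaller than the request the sampler falls back to replacement with a
warning, preserving the requested ratio — which the sensitivity analysis
shows is consequential — rather than silently shrinking the sample.

The weighted scheme distributes each type's expected total over cells
proportionally to population within each stratum (urban cells share the
urban total, rural the rural; a pooled variant is available behind a
flag) and samples with probability proportional to the inverse
expectation. Cells with zero expectation receive the largest finite
weight among populated cells, not infinity, so unpopulated cells are the
most likely pseudo-absences without becoming a degenerate point mass.
The 70/30 presence split is record-level (duplicate records in one cell
may land in both partitions, mirroring point-level registry splits); a
cell-level split is available for strict leakage control.

## Count scaling

sᵢ = Popᵢ/nᵢ is computed on cells with at least one recorded point,
where nᵢ counts recorded points of *all* types — co-located types share
the cell's population by design. The per-type, per-stratum s is the
unweighted mean of sᵢ over cells holding that type (a
population-weighted variant sits behind a flag). Expected totals are
y = share × stratum population / s; shares summing to less than 1 are
allowed (the residual is unmodelled population). Scaling distributes y
over cells proportionally to p\* within each stratum, conserving stratum
sums exactly and independently of the evaluation threshold.

Two identifying assumptions are surfaced in the summary report rather
than corrected: the register is treated as complete on the cells it
covers, and cells shared by several types attribute population to points
in proportion to point counts. The second makes the s estimator a
mixture wherever types with very different service loads co-locate —
with heterogeneous persons-per-point it is biased toward the co-located
types' mean, which is why the recovery experiment uses a uniform
persons-per-point world (where the estimator is consistent up to the
unserved-population share).

## Evaluation

TPR and FPR count scores *strictly* greater than θ (ties at θ are
non-presences); θ = 0.3 by default. Because background cells may contain
undetected presences, the best attainable FPR is typically above zero.
AUC is the rank probability that a presence outscores a background cell
(ties half) — invariant under monotone score transforms and insensitive
to the background ratio, which is exactly why the sweep reports the
TPR/FPR pair alongside it. The sweep fixes the presence split, re-draws
training background, re-trains, and evaluates on the fixed test
presences against a freshly drawn evaluation background per ratio
(reuse of the training background is available behind a flag).

## Synthetic worlds

The generator emulates the five inputs of a national water-point study
with known ground truth:

- **Feature layers** — spatially smoothed Gaussian fields (smoothing
  σ = 6 cells), standardized; categorical layers are quantile-thresholded
  fields with 3 codes.
- **Settlement and strata** — a clustered log-normal field; the top 20%
  of cells by settlement are urban.
- **True intensity and counts** — per type, intensity ∝ logistic of a
  stated linear/product combination of layers, modulated by the
  settlement field with a square-root exponent (communal sources serve
  many people, so source density grows sub-linearly with population) and
  by unit-mean lognormal overdispersion (σ = 1; real infrastructure
  siting is far from fully explained by mapped features). The mean
  intensity is 0.12 points per cell and type, the per-type density of a
  national registry at 1 km resolution. Counts are Poisson.
- **Population** — the served population implied by counts ×
  persons-per-point (defaults per type and stratum follow the magnitudes
  of national estimates: boreholes 75 urban / 300 rural, piped 40/50,
  springs 150/130) plus a 10% unserved component spread over the capped
  settlement field, so cells without points still carry people.
- **Shares** — persons served per type, normalized within each stratum
  (summing to 1 exactly).
- **Observation** — each occupied cell is detected independently with
  probability detection_rate × bias factor (distance decay from a survey
  centre; factor ≡ 1 at bias 0); a detected cell contributes one record
  per true point, as a register surveying a cell lists all of them.
  Default detection is 0.8 with no spatial bias.

What the generator does **not** emulate: real geography or projections,
registry schema beyond (type, cell), cross-type interactions in siting
(types are conditionally independent given features and settlement), or
survey nonresponse. Passing tests therefore show that the pipeline
recovers what the generative model encodes — calibrated relative
probabilities, conserved counts, sampling laws — not that any particular
national map is correct.

## Numerical choices and degenerate inputs

- Empty presence partitions are prevented by clamping the split to leave
  both sides non-empty; splits of fewer than two records are errors.
- A stratum with a positive expected total but zero population (or
  all-zero p\*) is an error naming the stratum.
- The group comparison inherits each household's cell prediction; a KS
  test of each group against a normal with the group's moments gates at
  p < 0.1 between the two-sample t-test and the Wilcoxon rank-sum test
  (normal approximation with tie correction — ties dominate because
  households share cells; exact mode below 20 per group). Empty or
  zero-range groups are flagged untestable instead of returning a
  p-value.
- The two-proportion z-test uses the pooled textbook statistic; both
  one- and two-sided p-values are reported. A pooled proportion of 0 or
  1 is an error.
- The finite-population sample-size formula with the reference inputs
  (χ² = 3.841, N = 50 000, P = 0.5, d = 0.05) evaluates to 381.18
  (ceiling 382); reference tables sometimes print 380 for these inputs,
  a rounding-convention difference that is documented here rather than
  reconciled.
- Master seed → stage seed derivation is counter-based and recorded in
  the run manifest, so any single stage can be reproduced from the
  manifest; identical config + seed reproduces every output byte for
  byte.

## Problem sizes

The test suite and reproduction script run on desk-scale worlds chosen to
make each property measurable: the default 60×60 grid (≈ 370–430 presence
cells per type) for the ratio sweep and full runs, an 80×80 grid for
persons-per-point recovery (comfortably over 200 qualifying cells per
stratum), a dense 100×100 single-type world for detection-law checks, and
ten seeded replicates for the model-class comparison.

## Known limitations

- Feature-stack I/O is CSV/JSON only; georeferenced raster formats are
  out of scope.
- No sampling-bias correction beyond the population-weighted background
  scheme (no target-group background or spatial thinning).
- The persons-per-point estimator is biased where types with very
  different service loads co-locate (see Count scaling above).
- Functionality/breakdown of access points is not modelled; counts are
  expected registered points, not working sources.
- Model classes are limited to MaxEnt and the MLP.
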