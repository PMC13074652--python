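# Methods

`pepperfw` estimates shoot and cumulative fruit fresh weight (FW) of
greenhouse sweet pepper from non-destructive morphological traits. It
implements four connected stages — a synthetic-data generator, allometric
baselines, group-wise data augmentation, and an evaluated/interpreted
ensemble — and this note records the models, the defaults, and the design
choices behind them.

## The data model

A record is one destructively sampled plant: grouping keys (year, season,
cultivar, interlighting treatment CT/RB/FR, days after transplanting DAT),
eight morphological traits (plant height and main/left/right stem segment
lengths in cm; basal/main/left/right stem diameters in mm), a pruning flag,
and two targets in grams: shoot FW (vegetative tissue) and fruit FW
(cumulative harvested ripe fruit). The crop is trained to two stems, so the
plant is represented by three longitudinal segments: a main (trunk) segment
up to the bifurcation and left/right segments above it.

Units are a package convention (cm / mm / g); the measurement protocol the
data emulates does not fix them, and RMSEs are reported in grams.

## Synthetic generator

No raw measurement table is publicly deposited, so the package generates
data matching the study's sampling design: 36 (year, season, cultivar,
treatment, DAT) cells totalling 303 plants, DAT 30–153, five growing
seasons. The generative structure encodes the relationships the analysis
stages are designed to detect:

* **Traits** follow logistic growth curves in DAT (asymptote, rate,
  midpoint per trait) with multiplicative lognormal noise (default CV 8%).
  Midpoints sit near DAT 60–72 with rates ≈ 0.03 d⁻¹, putting traits at
  ~90% of asymptote by DAT 150 — growth saturates late in the season.
  Plant height is derived, not independently drawn: main segment + the
  longer lateral + a 10 cm canopy offset (the crop grows mainly
  vertically), times its own multiplicative measurement noise at the
  trait CV — height is a separate ruler reading, not an arithmetic
  identity of the segment measurements.
* **Shoot FW** is a logistic sigmoid of *stick volume* (the summed segment
  lengths): L = 4000 g, k = 0.010 cm⁻¹, V₀ = 450 cm, times lognormal noise
  (CV 12%) and a −3% pruning effect. Shoot mass is therefore a function of
  structure, not of time directly. The link parameters place the observed
  volume range (≈ 100–400 cm) in the sigmoid's rising region — saturation
  is approached, not reached — so plant-to-plant structural variation at a
  given DAT still moves shoot FW (≈ 8.5 g per cm of summed length late in
  the season, above the target-noise floor). On the fully saturated
  plateau, structure would carry no information beyond developmental time
  and the organ-specific attribution pattern would vanish.
* **Fruit FW** is a cumulative logistic in DAT (maximum 3000 g, rate
  0.06 d⁻¹, midpoint DAT 115), zero before a fruiting onset at DAT 45,
  modulated weakly by standardized stick volume (weight 0.1) and by
  treatment multipliers within ±5% (CT 1.00, RB 1.03, FR 1.05), times
  lognormal noise (CV 12%). Fruit mass is therefore a function of
  developmental time first and structure second.

Because trait curves saturate (midpoints ≈ 60–72) well before the fruit
curve (midpoint 115), late-season DAT carries information about fruit FW
that the saturated traits no longer do. This separation is what lets the
ablation and attribution stages recover the organ-specific pattern
(structure → shoot, time → fruit) and is a generative assumption, not a
biological claim. Small management effects encode the same assumption for
the management group (least influential).

What the generator does **not** emulate: year/cultivar-specific growth
differences, weather covariates, per-fruit harvest events, heteroscedastic
measurement error, and multivariate trait coordination beyond the shared
logistic time course. Tests passing on this data show the pipeline's
mechanics and orderings are correct under the documented structure; they do
not certify performance on real greenhouse data.

## Allometric baselines

Three volume proxies per plant: stick V = Σ segment lengths (cm; a config
switch `stick_mode="height"` uses plant height instead), cylinder
V = Σ π r² L with each segment's own radius, truncated cone
V = Σ (πL/3)(r₁² + r₁r₂ + r₂²) with proximal-to-distal taper (main segment:
basal→main diameter; laterals: main→own diameter). Diameters are converted
mm→cm. The taper mapping is one consistent reading of the three-segment
representation; the measurement set does not uniquely determine it.

Two scaling laws are fitted by least squares: linear FW = αV + β, and the
logistic sigmoid FW = L / (1 + exp(−k(V − V₀))) with L the asymptotic FW,
k the rate, V₀ the inflection volume. Sigmoid fitting uses bounded
nonlinear least squares initialized at L₀ = 1.1·max FW, V₀ = median V,
k₀ = 4/range(V), with at most 10 000 function evaluations; on optimizer
failure or a non-positive/non-finite asymptote the fit falls back to the
linear form (`fallback_used` flag), per fit and per fold, so a baseline
always exists. Degenerate inputs (all V equal, fewer than 4 points) raise
rather than silently fall back. Allometric models are evaluated under the
same fold plan as the machine-learning models.

## Augmentation

Augmentation runs independently within each (season, treatment, DAT) group
(36 groups under the default design) and never alters an original row:

* **Gaussian path** (group size ≤ n_thr, default 10): resample rows with
  replacement and add zero-mean Gaussian noise with sd 0.05 × σ_f, σ_f the
  *within-group* feature sd (within-group, to preserve local statistical
  characteristics). Targets are perturbed like any continuous column
  (switchable).
* **VAE path** (size > n_thr): a variational autoencoder on the group's
  z-scored 10 continuous columns (8 traits + 2 targets): encoder and
  decoder with hidden layers 64/32 (mirrored), batch norm, LeakyReLU,
  dropout 0.1; latent dimension 8; loss = MSE + 0.1 × analytic Gaussian KL;
  Adam at 1e-3, batch 32, exactly 500 epochs. Synthetic rows decode
  standard-normal latent draws at inference settings and add the Gaussian
  observation noise of the decoder likelihood (per-feature residual sd
  estimated after training). Sampling the full p(x|z) is the default
  because the decoder mean alone under-disperses the synthetic marginals
  — the 8-dimensional latent space does not carry the residual variance —
  which both the KL quality control and downstream regression detect;
  mean-only sampling remains available (`sample_observation_noise=False`).
  Constant features use sd 1 in the z-score and decode back to their
  constant.

Categorical/discrete fields (keys, pruning, year, cultivar) are never
generated — they are reassigned from the source group. Generation is capped
at 10× the group size (default factor 10). De-standardized values are
clipped at 0 (no negative lengths or masses). A master seed fans out to
per-group seeds via a CRC32 hash of the group key, so results are
independent of group processing order.

**Quality control**: marginal KL divergence per continuous feature between
pooled original and synthetic values — 20 equal-width bins over the pooled
range, additive smoothing 1e-8, direction KL(original ‖ synthetic), natural
log — averaged over features. The working bound is mean KL ≤ 1 nat. A
threshold sweep over n_thr ∈ {3, 5, 7, 10} re-runs the augmentation per
candidate and picks the KL-minimizing threshold (ties to the larger value).
The histogram estimator is biased at small n and finite bins; the
20-bin/e-8 choices are conventions, and numeric parity with any particular
published KL value is not attempted.

## Learners and ensemble

Inputs follow a fixed taxonomy: basic (plant height, basal diameter),
structural (main/left/right diameters and lengths), temporal (DAT),
management (treatment one-hot over {CT, RB, FR}, pruning 0/1). Targets are
modeled independently.

Base learners: LightGBM (leaf-wise boosting; 200 trees, lr 0.05, 31
leaves), XGBoost (depth-wise; 200 trees, lr 0.05, depth 6), random forest
(200 trees), and a feed-forward network with hidden layers 32/8 (batch
norm, ReLU, dropout 0.1), Adam at 1e-3 on MSE, at most 500 epochs with
early stopping after 80 non-improving validation epochs and best-weight
restore, batch size 64, features and target z-scored by training
statistics. After training, batch-norm running statistics are re-estimated
with one clean pass (they lag the restored weights otherwise). The dropout
rate of 0.1 — the same rate the VAE uses — keeps the small network able to
fit a noiseless linear signal to within a few percent of the target sd,
which heavier dropout on an 8-unit layer prevents. Tree hyperparameters
are fixed package defaults; there is no tuning loop. Tree models take
features unscaled.

The neural networks are small numpy implementations (manual
backpropagation, Adam); at these problem sizes (hundreds to thousands of
rows, ≤ 14 inputs) they train in seconds and keep the package's behavior
fully deterministic given a seed.

**Ensemble**: greedy selection with replacement on the out-of-fold
prediction matrix — 100 rounds, each adding the base model that minimizes
the RMSE of the running average (ties to the declared order lgbm, xgb, rf,
ffnn), weights = selection frequencies at the best round. This yields
w ≥ 0, Σw = 1, and OOF RMSE ≤ the best single base by construction.
Weights are fitted per target and per repeat on that repeat's OOF matrix
(OOF predictions are exactly the validation-fold predictions). An
exhaustive simplex grid search is kept as an independent cross-check in the
tests.

## Cross-validation

Repeated K-fold (default 5 × 3) over original records only, stratified by
(season, treatment): within each repeat, records are shuffled within
strata, concatenated, and dealt round-robin to folds, so fold sizes differ
by at most one (303 → 60/61). The plan serializes to JSON and is identical
on replay.

Leakage rules, asserted on every fold at run time: test folds contain zero
synthetic rows, and synthetic training rows are regenerated inside each
training fold from that fold's training originals only — a strictly
stronger guarantee than excluding synthetic rows linked to test groups.
Augmentation never changes the fold plan. The FFNN's early-stopping
validation set is a seeded 20% of the training-fold originals, excluded
from its own training rows. Metrics are R² (1 − SSE/SST) and RMSE on the
OOF vectors, reported per repeat and summarized as mean ± sd across
repeats.

## Interpretation

**Ablation**: remove one feature group, re-run the full cross-validated
ensemble pipeline (augmentation included) under the identical fold plan,
report ΔR² = R²_full − R²_reduced per target. ΔR² may be negative.

**Shapley attribution**: permutation-sampling estimator for the fitted
ensemble. Per observation, features switch from a background row's values
to the observation's along random orderings; marginal prediction changes
are credited to the switched feature and averaged over draws (default 200
orderings, each paired with one uniformly drawn background row; background
= 100 seeded training rows). The per-observation baseline is the mean
model output over the sampled background draws, which makes efficiency
(baseline + Σ attributions = prediction) exact by construction; an
exhaustive all-orderings mode provides exact interventional Shapley values
for ≤ 8 features and anchors the estimator tests. Attribution is
interventional (independent background), at the one-hot level, with
treatment columns summed back to a single factor for reporting.

## Problem sizes and numerical choices

The package's own test and reproduction runs use the full 303-record
design; the expensive qualitative checks (augmented-vs-original ordering,
ablation orderings) use K = 5 with 1 repeat and a 3-seed majority, which is
where the orderings stabilize at this design size. VAE log-variances are
clipped to ±15 before exponentiation; batch norm uses ε = 1e-5 and
momentum 0.9 on running statistics; greedy-ensemble and fold-plan ties are
broken deterministically as documented above.

## Known limitations

Marginal KL control does not validate multivariate structure of the
synthetic rows; joint relationships may still be distorted. The augmented-
vs-original performance ordering is a small effect at this design size and
noise level — individual base learners (boosted trees, FFNN) benefit more
consistently than the forest-dominated ensemble. The generator omits
year/cultivar heterogeneity, so group keys beyond (season, treatment, DAT)
carry no signal. All conclusions from synthetic runs are statements about
the pipeline under the documented generative assumptions, not about real
sweet-pepper data.
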