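# Methods

This note documents the models, estimators and numerical choices behind
`bwmkl`, what the synthetic cohorts do and do not emulate, and the
limitations a user should know before trusting a number.

## Problem setting

Birth weight (BW, grams) is regressed on 17 first-trimester maternal–fetal
features partitioned into four modalities: maternal anthropometrics (MH,
MW, MBMI, SEX), fetal ultrasound biometry (CRL, BPD, HC, FL, AC), Doppler
velocimetry (R/L/MIN/MAX/MEAN-UAPI) and maternal ultrasound (PT, PL,
PT/PL). Cohorts are complete-case by contract: the loader rejects missing
or non-numeric cells rather than imputing, because every downstream score
(mutual information, impurity, dual coefficients) would silently change
under imputation. The one binary feature (fetal sex) is encoded 0/1.

## Standardization

All features are z-scored with the **sample** standard deviation (n−1
denominator). Parameters are always fitted on training rows only and
applied unchanged to validation/test rows; constant columns get scale 1 so
they map to zero instead of dividing by zero. Inputs are standardized
before both the selectors and the kernels — the linear-model scores are
only comparable across features on a common scale, and Gram-matrix
conditioning benefits as well. Targets are additionally standardized
inside the kernel machinery (see below) but all reported errors are in
grams.

## Ensemble feature selection

Six scores per feature, each min–max rescaled to [0, 1], then averaged
with equal weight; the top-Q features by average are selected, ties broken
by original column order so selection is deterministic.

* **NMI** — mutual information between feature and target after
  discretizing continuous variables into 10 equal-frequency bins
  (variables with ≤10 distinct values keep their own levels), normalized
  by the arithmetic mean of the marginal entropies. Quantile binning was
  chosen because the features span three orders of magnitude in scale;
  the bin count is a configurable argument.
* **F-statistic** — the univariate regression F, F = r²/(1−r²)·(n−2) per
  feature. A perfectly correlated feature would make this infinite; it is
  capped at 1e15 with a warning.
* **LASSO** — absolute coefficients of an L1-penalized linear fit at the
  penalty selected by 5-fold cross-validation over a 50-point logarithmic
  grid (seeded). Irrelevant features can score exactly zero.
* **LR** — absolute weights of the joint ordinary-least-squares fit;
  rank-deficient designs fall back to the minimum-norm solution with a
  warning (duplicated columns split their weight).
* **MDI-RF / MDI-ET** — mean decrease in squared-error impurity across
  500 random-forest / extra-trees regressors with a pinned seed and
  otherwise library-default tree parameters.

A selector that returns a constant score vector is rescaled to all zeros,
not all ones: an algorithm with no preference should contribute no
preference. Q can be fixed (the package's experiments use Q = 8) or tuned
over a grid by inner 5-fold cross-validation of the downstream regressor's
MAE, smallest Q winning ties (parsimony).

The min–max/average algebra is equivariant under feature permutation; the
tree-based scores are additionally seed-dependent, so their equivariance
is statistical rather than exact.

## Multiple-kernel ε-SVR

Each modality's feature block feeds one kernel — linear x·x′, polynomial
(γ x·x′ + c₀)^d, or RBF exp(−γ‖x−x′‖²) — and the combined Gram matrix is
K_η = Σ η_m K_m with η on the unit simplex. Normalizing η to sum to one
removes the scale redundancy between the weights and the box constraint C.
One kernel per modality is searched (not a sum of several per modality).

The dual problem

    max −½ βᵀKβ − ε‖β‖₁ + yᵀβ   s.t.  Σβ = 0, |β_i| ≤ C

is solved by a sequential-minimal-optimization loop specialized for
precomputed kernels: working pairs are chosen by maximal KKT violation
with a second-order (curvature-normalized) gain estimate, and the
one-dimensional pair subproblem — piecewise quadratic because of the L1
kinks at β = 0 — is maximized exactly segment by segment. Because SMO
alone crawls on (near) low-rank Gram matrices such as linear kernels, the
solver alternates SMO sweeps with an equality-constrained Newton step on
the current free support vectors (signs and bounds held fixed along the
step), which closes the convergence tail in a few linear solves. The KKT
gap tolerance defaults to 1e−6; inner model-selection fits use 1e−3 and
the winning configuration is refit at full precision. The bias b averages
the KKT residuals y_i − (Kβ)_i − ε·sign(β_i) over free support vectors,
falling back to the median residual over all support vectors, and — when
every target sits inside the tube and β = 0 — to the midpoint of the
feasible interval for a constant predictor.

Gram matrices assembled from valid kernels receive a one-shot diagonal
jitter of 1e−10·trace/n; user-supplied matrices are additionally checked
and rejected if their minimum eigenvalue is below −1e−6·trace/n. Targets
are standardized inside the fit for conditioning, so ε is expressed as a
fraction of the training-target SD; predictions are mapped back to grams.

Grid search is exhaustive over (per-modality kernel and parameters) × η ×
C × ε, scored by seeded inner 5-fold CV MAE on training data only, and
the winner is refit on all training rows. Ties prefer simpler kernels
(linear < polynomial < RBF), then smaller C. Defaults: C ∈ {0.1, 1, 10,
100}; ε ∈ {0.01, 0.1, 0.2}·sd(y); RBF γ ∈ {0.01, 0.1, 1/d_m, 1};
polynomial degree ∈ {2, 3}, coef0 ∈ {0, 1}; η on a step-0.25 simplex grid
(35 candidates for four modalities). The full default product is large,
so two graduated presets exist: `compact` (linear + auto-γ RBF, η step
0.5, C ∈ {1, 10}) and the CLI's `fast` (linear + auto-γ RBF, uniform η,
C = 10, ε = 0.1·sd), which the package's own experiments and the
acceptance script use so a full protocol run stays in the minutes range
on one CPU. With a single modality and η = (1) the model reduces exactly
to a plain ε-SVR — a useful identity check, verified in the tests.

## Validation protocol

`make_split` draws a seeded random cv/hold-out partition (default 500/78
from 578) and balanced folds (sizes differ by ≤1). Per fold: features are
(optionally) selected on the training rows, the grid search runs on the
training rows, and the fold's validation rows are scored once. Feature
selection defaults to **per-fold** to avoid selection leakage; the
published-style variant that selects once on the full CV set is available
behind `global_selection=True` and warns, because fold errors then share
selection information. Hyperparameter search is nested inside each fold
for the same reason.

The final hold-out model refits on all CV rows: the multiple-kernel model
at its most frequently winning fold configuration (ties broken by best
inner CV MAE, the feature set taken from the best such fold), the
baselines by re-running their grid search. An audit log records the
sample ids every stage consumed and raises if any hold-out row reaches a
training stage; the hold-out is read exactly once, at the final
evaluation.

Errors: MAE = (1/S)Σ|y−ŷ| in grams and MAPE = (100/S)Σ|y−ŷ|/y in percent
(targets must be positive), reported per fold, as mean ± sd across folds
(1 decimal in grams, 2 in percent), and once for the hold-out.

Baselines are deliberately thin wrappers over scikit-learn — random
forest, RBF-kernel SVR, MLP — tuned by `GridSearchCV` over compact
versions of the usual search spaces (estimator count/depth/criterion for
RF; C and γ for SVR; activation/solver/penalty/width for the MLP). They
are comparison plumbing; the package's contribution is the selection
ensemble and the multiple-kernel regressor.

## Synthetic cohorts

The generator draws features from a multivariate Gaussian whose marginals
match the study population (e.g. maternal height 155.60 ± 5.96 cm, BW
2868.95 ± 333.68 g) and whose correlation matrix contains the published
pairwise values — weight–BMI 0.9, PT/PL–PT −0.7, and 0.75 for every pair
of uterine-artery indices (the midpoint of the observed 0.6–0.9 range).
All other cross-correlations default to zero rather than guessing values
that were never printed. The assembled matrix is repaired to the nearest
positive-definite correlation matrix by eigenvalue clipping at 1e−6 and
diagonal rescaling; the Frobenius distance moved is logged. Fetal sex is
thresholded to 0/1 at the median of its latent Gaussian.

The outcome is a sparse linear link on the observed features on the
standardized scale: BW = 2868.95 + Σ c_j z_j + N(0, σ). The default
informative set is the eight features the selection analysis of the
emulated study surfaced (MH, MW, PL, MBMI, BPD, CRL, L-UAPI, FL), with
equal slopes scaled so the link explains half the target variance and the
total SD matches 333.68 g. Rows with non-positive BW are redrawn (at the
default intercept this is a ~10⁻¹⁷ tail event). `make_recovery_spec`
builds cohorts for recovery experiments: n informative features drawn
round-robin across the four modalities, slope 150 g/SD and noise 150 g by
default (a strong but not noiseless link, R² ≈ 0.9 at 8 features), and
zero cross-correlations so recovery is attributable to the link rather
than to correlated proxies.

What the generator does **not** emulate: nonlinear physiology of fetal
growth, the unpublished off-diagonal correlation structure, measurement
error models, or site effects. Passing recovery and fusion tests on these
cohorts therefore shows the pipeline is correct and sensitive under its
own assumptions — not that the same error levels will hold on clinical
data, whose headline numbers came from a private cohort and are not
reproducible here.

## Experiment sizes

The packaged experiments favor many seeded replicates over large single
runs: selection recovery uses 50 replicates of n = 300; the fusion-benefit
comparison uses 20 replicates of n = 150 with a fast grid; the protocol
demonstration uses one 578-subject cohort (500 CV / 78 hold-out); solver
verification uses 50 instances of n ≤ 30 against an independent dense QP
solution; generator fidelity uses n = 5000.

## Known limitations

* The SMO + Newton solver targets dense precomputed kernels up to a few
  thousand samples; no shrinking, caching or sparse paths.
* The exhaustive default grid grows multiplicatively with modalities; use
  the graduated presets or a custom `SearchGrid` for larger problems.
* MDI importances inherit the known bias toward high-cardinality
  features; with 10-bin NMI and four other selector families the ensemble
  dampens but does not remove it.
* `tune_q` evaluates a single downstream configuration per Q for speed; a
  full nested search per Q is possible through the `regressor_config`
  hook but costly.
* The correlation map reports 0 (with a warning) for constant columns,
  where the Pearson coefficient is undefined.
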