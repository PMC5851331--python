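# Methods

`dsnis` implements a complete brain-network classification chain for
two-group resting-state fMRI studies: Pearson connectome construction,
non-negative elastic-net selection of discriminative edges, kernel
discriminant classification with a nearest-neighbour rule, leave-one-out
evaluation, and group-level network topology summaries.  This note records
the model, the choices that were genuinely open, and what the synthetic
experiments do and do not demonstrate.

## Connectome construction

A subject is a `T x m` matrix of regional time-series (1-based AAL indexing;
the shipped lookup table covers the 90-region AAL parcellation).  The
functional network is the `m x m` matrix of pairwise sample Pearson
correlations with the diagonal fixed at 0; self-connectivity is never a
feature.  Thresholding at `tau` zeroes edges with `|r| < tau` and keeps sign
and magnitude of the survivors.  Thresholding uses the *magnitude*: strong
negative correlations are retained, since weak and negative connectivity can
carry discriminative signal.  No Fisher z-transform is applied by default
(an opt-in flag exists on `build_design`).  The feature vector is the
row-major upper triangle, `M = m(m-1)/2` edges; for m=90 that is 4005
features per subject.

## Non-negative elastic-net edge selection

Labels are encoded patient=+1, control=-1 (a zero-mean target suits the
intercept-free linear model `y = Xa + e`), and edge significances solve

    min_a ||y - X a||^2 + g1 ||a||_1 + g2 ||a||_2^2,   a >= 0.

The squared l2 penalty is used: it is the only reading under which the
augmented-data reduction to a pure non-negative lasso
(`X* = (1+g2)^{-1/2}[X; sqrt(g2) I]`, `y* = [y; 0]`,
`alpha = g1 (1+g2)^{-1/2}`, `a = (1+g2)^{-1/2} a*`) is an exact identity;
the identity is verified numerically in the test suite.  The positivity
constraint is implemented as `a >= 0`: a strict inequality has no minimiser
on a closed feasible set, and exact zeros are precisely the removed edges.

Solver: cyclic coordinate descent with non-negative soft-threshold updates,
alternating full sweeps with sweeps over the active set.  The coordinate
updates on the original quadratic coincide exactly with coordinate descent
on the augmented problem (the extra identity rows only add `g2` to each
column's squared norm), so the augmented matrices are never materialised.
Convergence: largest coefficient change in a full sweep below `tol = 1e-6`
(cap 10 000 sweeps); the objective is monotone non-increasing per sweep and
the KKT conditions are audited by `kkt_violation`.  The suite certifies
global optimality against two independent oracles: exhaustive support-set
enumeration on small instances, and Lawson–Hanson NNLS on the
completed-square form on larger ones.  A projected-gradient reference
solver provides a third route.

Defaults `g1 = 0.1`, `g2 = 10.0`.  The ridge weight is deliberately of the
same order as the design's column norms (`diag(X'X)` is roughly 6–12 for
cohorts of tens of subjects with correlations in [-1, 1]).  With a much
smaller `g2` the estimator degenerates toward non-negative least squares
plus l1, which keeps only a minimal predictive subset of a correlated edge
group — the elastic-net grouping bound
`|a_i - a_j| <= ||y|| sqrt(2(1 - rho)) / g2` is vacuous — defeating the
uniform-ranking purpose of the method.  A ridge-dominant setting activates
the grouping effect that motivates the elastic net here in the first place:
correlated discriminative edges enter together and the full ranking is
interpretable as a biomarker table.  Features are used raw (no per-edge
standardisation) by default, with an opt-in z-scoring flag.

DSNIS selection: sparsity `s` is the fraction of edges removed; the top
`round((1-s) M)` edges by weight are retained, never including exact zeros,
with ties broken by ascending edge index.  If the positive support is
smaller than the target the whole support is kept and the achieved sparsity
recorded.  Baselines for comparison: two-sample t-statistic ranking,
non-negative lasso (`g2 = 0`) and non-negative ridge (`g1 = 0`).

## Kernel discriminant analysis

On the retained edges, the discriminant direction
`w = sum_i alpha_i phi(z_i)` maximises the kernelised Rayleigh quotient
`(alpha' K W K alpha) / (alpha' K K alpha)` with `W` the block
class-indicator projection (`W_ij = 1/n_c` within a class).  The quotient
is solved in the subspace of K-eigencomponents above `1e-10 * lambda_max`,
which reduces it to a symmetric eigenproblem and handles singular `K K`
(duplicate subjects, rank-deficient kernels) without regularisation.  The
retained discriminant count is `c - 1` (one, for two classes), normalised
so `alpha' K K alpha = 1`; the attained quotients lie in `[0, 1]` because
`W` is idempotent.

Two deliberate choices:

- *Kernel*: default RBF with the median-pairwise-distance bandwidth
  heuristic (`gamma = 1/(2 sigma^2)`), since the motivation for a kernel
  method is non-linear separability; linear and polynomial are selectable.
- *Centering*: the quotient is solved literally, without kernel centering,
  by default.  When `K` has full rank this objective is degenerate — the
  maximal eigenvalue 1 has multiplicity `c` and its eigenspace contains the
  useless constant-projection direction.  The implementation resolves the
  degeneracy as a deterministic tie-break: within the maximal eigenspace it
  retains directions orthogonal to the constant projection, which attain
  the same maximal quotient.  An optional `center=True` flag instead
  double-centres `K` and uses the centred between-class projector (the
  classical kernel Fisher discriminant).  On zero-mean full-rank data with
  a linear kernel the literal form coincides with the classical Fisher
  discriminant, which the suite verifies (projection correlation >= 0.999).

Decision rule: 1-nearest-neighbour among training projections, distance
ties broken by the smallest training index.

## Evaluation

Leave-one-out cross-validation holds out each subject once.  Default
selection scope is `per_fold`: the elastic net and the discriminant are
re-fitted on every training fold and the held-out subject is restricted to
the fold's selected edges, avoiding selection leakage.  `global` scope
(selection once on the full cohort) is provided as the plausible historical
protocol and is always recorded in outputs.  Metrics: accuracy,
sensitivity, specificity, PPV, NPV as percentages to two decimals; any
zero-denominator statistic is reported as an explicit null.  A
threshold x sparsity sweep reuses each fold's fitted selection across
sparsity levels (the sparsity cut is a post-processing of the weights), so
the grid costs little more than one LOOCV per threshold.

Known evaluation caveat: under a true null (no group difference), LOOCV
with matched group sizes is pessimistically biased — removing the held-out
subject makes its own class the training minority, so accuracy tends to
fall below 50% (we observe roughly 25–45% across seeds on 20+20 null
cohorts).  A fixed-seed null run inside the binomial chance band is
therefore a weak calibration check, not evidence of unbiasedness.

## Synthetic cohorts

The generator emulates the structure of the original study's undeposited
cohort: two groups of regional time-series, default 24 patients and 21
controls, m=90 regions and T=170 timepoints (180 volumes minus the 10
discarded at preprocessing).  Each subject's rows are i.i.d. draws from a
zero-mean multivariate normal whose correlation is an equicorrelation
background (`rho = 0.2`, a typical mean functional-connectivity level) with
a planted set of signal edges raised by the effect size `delta` in patients
only (clipped to +-0.99); eigenvalue clipping at `1e-6` restores positive
definiteness where needed.  Inter-subject heterogeneity is additive
Gaussian noise (sd `subject_noise_sd`, default 0.1 — the order of the
across-subject standard deviation of single-edge functional connectivity
in real resting-state cohorts) on the off-diagonals, re-projected to PD per
subject.  A single master seed spawns per-subject streams, so cohorts are
bit-identical under the same spec.

What this does *not* model: BOLD hemodynamics and autocorrelation, scanner
drift, motion artifacts, spatially structured (network-organised)
covariance, or site effects.  Passing synthetic-recovery tests shows the
chain detects planted covariance differences of realistic size under
Gaussian assumptions; it does not certify performance on clinical data.

The deterministic experiment suite uses m=30 (435 edges) cohorts — 30+30
subjects at T=400 for edge recovery, 20+20 at T=300 for the separable and
null end-to-end runs — sizes at which the full per-fold LOOCV chain runs in
seconds while leaving the selection problem strongly underdetermined
(n << M), which is the regime the method targets.

## Topology metrics

None of the five group-level metrics comes with a formula in the source
literature summarised here; the standard forms were fixed as design
choices, all on absolute weights: node strength (row sum), node diversity
(population variance of a node's m-1 weights), geometric weighted
clustering (Onnela form, weights normalised by the network maximum, nodes
of degree < 2 scoring 0), and two generalised-Jaccard overlap scores across
a group's binarised / weighted edge sets.  Each implementation is checked
against brute-force enumeration and (for clustering) against networkx's
weighted clustering coefficient.  Published group-level values for these
metrics are not reproduction targets: they depend on the undeposited
cohort, and the published clustering means (> 1) are not attainable by any
standard normalised variant, so the exact original formula is unrecoverable.

## Limitations

- The headline clinical accuracies are properties of an undeposited
  45-subject dataset; this package reproduces the *method* and its
  evaluation arithmetic, and demonstrates recovery on synthetic cohorts.
- `g1`, `g2`, `tau` and `s` interact; the defaults are sensible for the
  synthetic regime and the documented rationale above, not tuned to any
  clinical dataset.
- The uncentered discriminant quotient requires the tie-break described
  above whenever the Gram matrix is full-rank; users wanting the textbook
  kernel Fisher discriminant should pass `center=True`.
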