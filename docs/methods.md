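# Methods

## Model and assumptions

`lsgrn` infers a directed, weighted gene regulatory network from a single
genes × observations expression matrix whose columns are treated as one
ordered series (time points, or chips in file order). The dynamics of
each target gene *j* inside a module Cᵢ are modelled linearly,

    dx_j/dt = Σ_k a_jk x_k(t) + Σ_l b_jl y_l(t),

with x_k the module's own genes and y_l external candidate regulators.
The derivative is discretized as the first-order difference
d_j(t_m) = x_j(t_m) − x_j(t_{m−1}) with the regressors evaluated at the
right endpoint t_m, giving T−1 rows per target. The model is linear,
time-invariant and additive; no Hill/sigmoid kinetics, no intercept term,
and no explicit degradation beyond what the self-coefficient a_jj
absorbs. Self-regulation is estimated (the target's own column stays in
the design) but self-edges are never reported, matching gold-standard
conventions.

## Pipeline stages and conventions

**Preprocessing.** Missing cells are filled by linear interpolation
within each gene row (nearest-value fill at the ends); interpolation
never alters observed values. Normalization is a per-gene z-score with
sample (n−1) standard deviation; constant rows map to zero with a
warning. Normalization is applied per gene, not per chip.

**Which matrix feeds which stage.** The MI stage consumes the normalized
matrix; Gaussian MI is invariant under per-gene affine maps, so this is
purely cosmetic/numerical. The regression stage consumes the interpolated
*un-normalized* matrix: the difference model is stated in expression
units and has no intercept, so mean-centering would make the model
mis-specified (the centering constants would need an intercept column the
model does not contain). This split is deliberate and is exercised by the
affine-invariance test of the MI module.

**Mutual information.** The Gaussian covariance-determinant form in nats,
computed in closed form from the 2×2 joint covariance (sample, n−1).
Negative round-off is clamped to zero. A singular joint covariance
(constant gene, perfectly collinear pair) yields a +∞ sentinel rather
than an error so thresholding still works; sentinels count as above any
cutoff. The diagonal of the MI matrix is stored as 0 and never consumed.

**Decomposition.** Edges require MI strictly greater than λ. Module
detection is greedy (CNM-style) modularity maximization on the undirected
thresholded graph — the standard algorithm family for sparse biological
networks; it is deterministic for a given graph, and module indices are
fixed by sorting on each module's smallest gene index. Isolated genes are
reassigned to the module containing their single strongest MI partner
(double max over modules and members), ties to the lowest module index,
against the frozen post-clustering modules so the result is independent
of processing order. A gene with no valid score falls back to the largest
module with a warning. An edgeless graph is an error (no module exists).

λ is an MI value in nats and therefore data-scale dependent; published
values tuned on benchmark compendia (e.g. 1.2, the `RunConfig` default)
do not transfer to other data. `select_lambda(mi, mean_degree)` picks the
cutoff from the empirical off-diagonal MI distribution so the thresholded
graph has a requested mean degree; the simulation-based tests use it with
mean degree 2–4, the regime in which the graph is sparse but connected
enough to cluster.

**Candidate regulators.** For module Cᵢ and every other module C_m, all
cross pairs are ranked by MI descending (ties by lexicographic gene IDs)
and the top ceil(fraction · count) pairs kept; the candidate set is the
deduplicated union of external endpoints in rank order. Default fraction
0.05; the fraction-1.0 limit admits every external gene and is the
setting used for noiseless identifiability checks, where every true
regulator must be available to the design.

**Solver.** The 2-norm condition number of the design chooses the branch:
above `cond_threshold` (default 1e6 — squaring in the normal equations
doubles the exponent, so 1e6 keeps that branch within double-precision
safety) the least-squares problem is solved by QR with column pivoting
(LAPACK gelsy, relative rank tolerance 1e-10, minimum-norm on rank
deficiency); otherwise the normal equations HᵀH·P = HᵀD are formed and
solved by LU with partial pivoting, falling back to QR with a warning if
they turn out singular. Both branches agree to ~1e-8 on well-conditioned
systems (tested). An optional ridge term (default 0) regularizes the
normal equations but is unused by default.

**Thresholding.** An edge (k → j) is reported when |β| > θ, strict, sign
blind — coefficients are signed regulation weights, so a magnitude cut is
the only reading consistent with sweeping θ ≥ 0. Edge sets are nested
along a θ grid, which makes TPR and FPR automatically monotone
non-increasing in θ.

**Orchestration.** Modules are inferred on an in-process worker pool
(threads; the numerical kernels release the GIL). Fragments are keyed by
module index and merged in key order, so the assembled network is
identical for any worker count and any completion order; this is asserted
byte-for-byte in tests. Duplicate directed pairs (possible through
candidate sets) keep the larger-magnitude coefficient, ties to the lower
module index — an associative rule. A module that fails on a worker is
retried once on the master. `assign_modules` balances statically:
largest module first to the least-loaded worker.

**Evaluation.** Confusion counts over every ordered non-self pair of the
gold universe (negatives implicit). TPR = TP/(TP+FN), FPR = FP/(FP+TN),
PPV = TP/(TP+FP), ACC = (TP+TN)/total; 0/0 ratios are reported as 0 with
a `degenerate` flag so tables never hold missing cells. ROC points come
from the θ sweep with (0,0) and (1,1) appended.

## Synthetic data generator

`generate_truth` plants a sparse coefficient matrix: genes split evenly
into modules, round(density · n(n−1)) off-diagonal weights placed with an
intra- versus inter-module slot bias of `modularity_bias` : 1 (stratified
so the total count is exact), magnitudes uniform on `weight_range` whose
lower bound (default 0.2) is a dead zone guaranteeing that a separating
θ exists, signs random. The diagonal carries negative self-decay
(uniform on `decay_range`, default 0.1–0.5), the standard first-order
degradation term, which also keeps unregulated genes dynamically active.

`simulate_expression` generates the series from the implicit-in-regressor
recurrence x(t) − x(t−1) = A·x(t), i.e. x(t) = (I−A)⁻¹·x(t−1), from a
random positive x₀ — exactly the difference model the inference stage
fits, so at zero observation noise the planted coefficients solve every
per-target system to machine precision (float residual ~1e-15 of the
signal scale; the tests assert 1e-10). Observation noise is additive
Gaussian. Divergent trajectories are rescaled by powers of two (exact in
floats, so the recurrence remains exactly satisfied); a non-finite step
raises with a hint to reduce weights.

**What the generator does not emulate.** Real compendia contain
heterogeneous conditions, perturbations and replicates rather than one
autonomous trajectory; kinetics are nonlinear and noise is not purely
observational. Passing recovery tests therefore demonstrate correctness
of the estimator under its own model, not performance on biological data.

## Identifiability limits of single-series data

A consequence of generating one autonomous linear trajectory deserves
emphasis, because it bounds what end-to-end recovery tests can show. The
snapshot matrix of x(t) = B·x(t−1) (B = (I−A)⁻¹) numerically spans only
the modes of B whose magnitude stays within the floating-point dynamic
range over T steps and whose frequencies are resolvable in T samples —
roughly O(√T) modes. At n = 30 genes and T = 60 the full-design
regression is therefore numerically rank-deficient for generic sparse A,
and the minimum-norm solution differs from the planted coefficients; no
solver can do better, since both fit the data to machine precision. A
second, independent obstruction is that Gaussian MI measures linear
correlation: the informative (well-excited) dynamical regimes are
oscillatory, and an oscillating regulator–target pair in phase quadrature
has sample correlation near zero, so the MI stages rank true couplings
*low* precisely when the dynamics would be identifiable. The acceptance
script reports the 30-gene noiseless recovery numbers as computed; the
suite asserts full recovery (median TPR 1, FPR 0, coefficient error
< 1e-6 over seeds) at 8 genes with candidate fraction 1.0, inside the
identifiable regime, and exact per-module recovery for 5-gene planted
modules.

For the same reason the θ-sweep stability band on the 202-gene noisy
instance is wide: every design column count ceil'd by the candidate rule
gives at least M−1 external regressors per module, so the number of
fitted coefficient slots is bounded below by about n(2√n − 2) ≈ 5,300 at
n = 202 — all of which are counted as predictions at θ = 0 under
all-ordered-pairs scoring — whereas accuracy stability over the sweep
would require the shed predictions to be well under 5% of the ~40,600
pair space. The sweep's monotonicity properties (TPR and FPR
non-increasing in θ) hold exactly and are asserted.

## Problem sizes and numerical choices

Simulation-based tests use 5–30 genes (T = 25–60) for unit and recovery
checks, 202 genes (T = 150, observation noise sd 0.3) for the θ sweep,
and 50 random graphs of 30–200 genes for partition properties; these
sizes keep the full suite and the acceptance script within seconds while
covering the regimes discussed above. Key tolerances: MI closed-form
agreement 1e-12; MI oracle agreement 1e-10; solver branch agreement 1e-8;
QR rank tolerance 1e-10; z-score mean/sd check 1e-10. Tie-breaks are
documented where they occur (lexicographic gene IDs for candidate ranks,
lowest module index for reinsertion and assembly, lowest worker index for
assignment). Degenerate inputs — constant genes, edgeless graphs,
singular designs, empty predictions — are handled by sentinels, warnings
or named errors rather than silent misbehaviour.

## Known limitations

- Observations are treated as one ordered series; steady-state-heavy
  compendia violate the difference model's premise.
- No sparsity-promoting regression (LASSO/elastic net); dense coefficient
  vectors are thresholded instead.
- Module detection is greedy modularity maximization; resolution limits
  of modularity apply to very large, weakly modular graphs.
- The MPI-style master/worker design is modelled by an in-process pool;
  a distributed transport can be slotted in behind `assign_modules` /
  `assemble` without changing results, but none ships here.
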