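# Methods

## Model

`gerforest` trains binary-tree ensembles whose internal nodes carry
oblique splits h(x; w, τ) = [⟨w, x⟩ < τ] (strict inequality routes
left). Node construction is the usual three-stage randomized search —
candidate directions, per-candidate threshold, cross-candidate
selection — and the semi-supervised method modifies **only the third
stage**. The premise: with few labels, per-candidate threshold search
(Stage 2) degrades gracefully, but cross-candidate *selection*
(Stage 3) is driven by a high-variance gain estimate and dominates the
accuracy loss. The package's bottleneck experiment measures exactly
this decomposition.

### Label propagation

All l labeled and u unlabeled training points are joined in a kNN graph:
each point selects its t nearest Euclidean neighbors and an edge is kept
if *either* endpoint selects the other (union symmetrization, which
keeps the graph connected more often than the mutual rule). Edge
weights are Gaussian, W_ij = exp(−‖x_i−x_j‖²/σ²); coincident points get
weight 1. The propagation objective is

    L(F) = ½ ‖F − Y‖²_F + (λ/2) Σ_{i<j} W_ij ‖f_i/√D_ii − f_j/√D_jj‖²

over score matrices F ∈ R^{(l+u)×K}, with Y the one-hot label matrix
(zero rows for unlabeled points). Counting each unordered pair once
makes the stationarity condition come out as the closed form

    F* = ((1+λ) I − λ S)^{−1} Y,   S = D^{−1/2} W D^{−1/2},

which is the solution the package computes; the test suite verifies
first-order optimality of F* under the analytic gradient and agreement
with the fixed-point iteration F ← (λ/(1+λ)) S F + (1/(1+λ)) Y. The
system matrix is symmetric positive definite for every λ > 0 because
spec(S) ⊆ [−1, 1], so the solution is unique.

Pseudo-labels ŷ_u are row-argmaxes of F* over the unlabeled rows, ties
resolved to the lowest class index. Propagation runs **once**, globally,
before any tree is grown; every tree and node reuses the same ŷ_u.
Per-node re-propagation would cost a linear solve per node with no
change in the fixed point's definition, so it is not supported.

### Graph-embedded gain

For a node population S (labeled member indices + unlabeled member
indices), class proportions count labeled members by label and
unlabeled members by pseudo-label. The Stage-3 score of a candidate
(w, τ) is the Gini gain

    G(S) − (|S_left| G(S_left) + |S_right| G(S_right)) / |S|

with *all* members routed through the split and sizes counting all
members. An empty node has impurity 0 by convention, making the
formula total; a one-sided split scores exactly 0. With u = 0 this is
algebraically identical to the supervised Gini gain, and the graph
variant then builds a forest node-for-node identical to the standard
one under the same seed (asserted structurally in the tests).

Child nodes are named left/right throughout the code; "labeled" and
"unlabeled" refer only to supervision status. This avoids the classic
confusion between the two uses of l/u subscripts in this setting.

### Variants

All variants share one grower and one prediction path; they differ only
in which labels score which stage:

| variant            | Stage 2 members      | Stage 3 members          |
|--------------------|----------------------|--------------------------|
| control / standard | labeled              | labeled                  |
| graph              | labeled              | all, unlabeled by ŷ_u    |
| perfect_stage3     | labeled              | all, unlabeled by truth  |
| perfect_splitting  | all, by truth        | all, unlabeled by truth  |
| optimal            | all, by truth        | all, unlabeled by truth  |

Oracle variants require the withheld true labels that
`split_labeled_subset` retains; they never touch propagation (asserted
by instrumentation in the tests). Stopping rules and leaf models are
identical across variants, so measured differences isolate split
supervision. Stage 3 of the graph variant is Gini by definition; the
supervised criterion (Stages 2 and 3 of the other variants) is Gini by
default with entropy available — the bottleneck harness uses entropy.

## Parameters

- `t = 10` graph neighbors; `σ` = median of retained neighbor distances
  (median heuristic) unless given; `λ = 99`, equivalent to the
  canonical α = λ/(1+λ) = 0.99 of normalized-Laplacian propagation.
- `n_candidates = 50` per node, mixing axis-aligned one-hot directions
  (probability 0.5) with sparse oblique directions (2 nonzeros uniform
  in [−1, 1]). Typical oblique-forest practice; the method is not
  sensitive to the exact mix at desk scale.
- `max_depth = 20`, `min_labeled_split = 4` (a node with fewer labeled
  members, or single-class labeled members, becomes a leaf). Stopping
  always counts *true-labeled* members so that variant comparisons hold
  tree shape roughly fixed.
- Leaves store Laplace-smoothed (+1 per class) distributions of their
  labeled members; a leaf with no labeled member inherits the nearest
  ancestor's distribution. Pseudo-labels are excluded from leaves by
  default (`leaves_use_pseudo` enables the ablation): the
  semi-supervised modification is confined to split selection.
- `n_trees = 100` by default; the experiment harness uses 25 to keep
  paired 20-seed runs at desk scale.
- Bootstrap of the labeled block is on by default; the unlabeled block
  is shared in full by all trees. Both choices are configurable.
- Linear systems are solved densely up to 4000 points and by conjugate
  gradients (tolerance 1e−10) beyond.

## Determinism

Every run is a pure function of its config and seed. A master seed
yields per-tree seeds; each tree derives a bootstrap stream and
per-node streams keyed by (tree seed, depth, path-in-tree). Keying
node randomness by position rather than visit order means raising
`max_depth` refines leaves without perturbing candidates elsewhere,
which makes the depth-monotonicity property (training accuracy
non-decreasing in depth, bootstrap off) exact rather than statistical.
Ties are broken deterministically everywhere: first candidate in
generation order, smallest threshold, lowest class index.

## Synthetic data

The generators provide the manifold structure the method assumes,
without downloads:

- `make_clusters` — two isotropic Gaussians, centers 20·noise apart by
  default (`center_distance` overrides), optionally embedded in higher
  dimension by a random orthonormal map. The default separation makes
  the task 1-NN-separable; harder settings come from the override.
- `make_moons` — interleaving half-circles (radius 1, jitter
  `noise_scale`): the canonical fixture where linear structure fails
  (~85% for a linear model at zero label scarcity) while graph
  propagation with one label per class exceeds 95%.
- `make_vessel_image` — bright Bézier-centerline tubes with Gaussian
  cross-sections (full width 2–5 px) on a noisy background, with mask;
  emulates a retinal-vessel patch-classification input with
  controllable SNR.

What these fixtures do **not** emulate: correlated feature noise, class
imbalance, label noise, intensity inhomogeneity or acquisition
artifacts of real fundus/neuronal images. Passing tests demonstrate the
mechanism — pseudo-labels repairing split selection on manifold data —
not clinical-grade segmentation accuracy.

### Experiment conditions

The bottleneck harness fixes its class separation at 2× the noise
standard deviation (Bayes accuracy ≈ 84%). The experiment needs an
operating point where accuracy is limited by estimation error rather
than class geometry — on well-separated clusters every variant
saturates at 100% and the stage-wise decomposition is vacuous. This
emulates the hard machine-learning benchmarks on which the bottleneck
is observable (benchmark accuracies in the 50–70% range). With
|S1| = 20, |S2| = 2000, 25 trees and 20 paired seeds, perfecting
Stage 3 yields a gap of roughly +2 accuracy points over the control
while additionally perfecting Stage 2 adds roughly a quarter of that or
less. Gap estimates are noisy functionals: across independent
replications of the whole 20-seed experiment the Stage-3 gap stays
positive, while the small Stage-2 gap fluctuates around zero and can
occasionally reach a third of the Stage-3 gap.

The two-moons comparison (2 labels per class, 25 trees, 20 paired
seeds) orders the variants standard < graph < optimal in mean accuracy,
with the standard→graph gap (~7 points) an order of magnitude larger
than the graph→optimal gap: scarce labels cap threshold quality for
both semi-supervised and oracle split selection.

## Numerical choices and degenerate inputs

- Candidate thresholds are midpoints between consecutive *distinct*
  sorted projections; a candidate whose projections coincide, or whose
  Stage-2 member set is single-class, is invalid. A node with no valid
  candidate becomes a leaf.
- Isolated graph nodes (possible when Gaussian weights underflow) get
  D^{−1/2} := 0; their scores shrink to Y/(1+λ) and nothing crashes.
- Duplicate points are legal everywhere (zero distance → weight 1).
- Gain comparisons use plain floating-point `>` with first-wins ties;
  the brute-force recount oracle in the tests agrees to 1e−12 over
  thousands of random node/split pairs.
- Model files are JSON with sorted keys; floats round-trip exactly, so
  save→load→save is byte-stable and repeated runs are bit-identical.

## Limitations

- Propagation is transductive: new points are classified by the forest,
  never by the graph. This is by design (prediction must stay exactly
  standard) but means pseudo-label quality is fixed at training time.
- The Gabor bank reads the 4×7×3 layout as scales × orientations ×
  channels with default wavelengths {2, 4, 8, 16} px and evenly spaced
  orientations, takes the response modulus, and forces kernels to zero
  mean. Published vessel-segmentation filter banks differ in exact
  parameterization; this one is a faithful generic bank, not a
  reimplementation of any specific one.
- Gabor features are 2-D only; 3-D inputs get per-slice patches
  (15×15×7 cubes) but no 3-D wavelets.
- `accuracy_curve` and the harnesses evaluate plain accuracy, matching
  the package's comparison protocol; no AUC/F1.
- No regression forests, no incremental training, no per-node
  re-propagation.
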