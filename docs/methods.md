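# Methods

## Model

A network of `N` nodes is a signed real matrix `W`; `w_ij` is the
connection from node *j* into node *i* and may be excitatory (positive)
or inhibitory (negative). An input state `v⁰ ∈ {−1, 0, +1}^N` is
propagated once, `v = W v⁰`. Energies are evaluated on absolute values
because net energy consumption is positive; signs only enter the
propagation:

- wiring cost `E_w(i) = Σ_j |w_ij|` — energy to build/maintain
  connections;
- activity cost `E_a(i) = (1/B) Σ_b Σ_j |v_i w_ij v_j|` — a
  Hopfield-style signal-transfer cost, averaged over a batch of B input
  vectors so its scale is batch-size independent;
- objective `⟨E_a(i)/E_w(i)⟩` — the unweighted arithmetic mean over
  nodes with `E_w(i) > 0`. Minimizing the ratio rewards strengthening
  the connections of highly activated nodes and weakening those of
  quiet ones; it is the energy-efficiency reading of cost reduction
  (consumption per unit of maintained wiring).

**Partner-state ambiguity.** The displayed activity cost uses one
symbol for both node states. We default to the literal reading in which
both `v_i` and `v_j` are post-propagation (`activity_form='post_post'`;
`E_a` is then homogeneous of degree 3 in `W` and the objective of
degree 2). The alternative with `v_j` pre-propagation is available as
`'post_pre'` (degrees 2 and 1). No intent is guessed; both forms share
the same analytic gradient machinery and tests.

## Input signals

Signals model a homogeneous external environment. Per vector, a
sparseness `p ~ U(0, p_max)` with `p_max = 0.5`; each entry is nonzero
with probability `p`, the sign uniform (`sign_scheme='split'`). "Each
sign independently with probability p" is the `'independent'` option.
A pool of 10⁴ vectors is generated once per run and partitioned into
10 batches per epoch by permutation (without replacement within an
epoch). The probe batch used for the trace, the activity floor and
`E_a⁰` is the first 1 000 pool vectors, fixed for the whole run so
epochs are comparable.

## Refinement protocol

Initialization: i.i.d. `N(0, 0.5²)` entries. Per epoch:

1. `W → W/⟨W⟩` with `⟨W⟩ = mean(|W|)` — the absolute mean is used
   because a signed mean near zero would make the division explode;
   the inverse restore uses the same constant after the batch loop.
2. 10 Adam updates (lr 0.01; β₁=0.9, β₂=0.999, ε=1e−8, the optimizer's
   canonical defaults), each on one batch, using
   the closed-form gradient of the objective (chain rule through
   `v = W v⁰` and the absolute values; subgradient 0 at 0, which keeps
   exact-zero weights stationary). Because `W` is asymmetric, each
   batch update is also applied to `Wᵀ`: the gradient of the objective
   evaluated on the transpose is computed at the updated matrix and
   applied through a second, independent Adam state
   (`transpose_mode='sequential'`; `'averaged'` applies the symmetric
   mean of the two gradients with one state, `'off'` disables it).
3. Restore the scale; clip entries to
   `w_u = mean(|w|) + n_sigma · std(|w|)` (population std, recomputed
   from the current matrix every epoch); then, if the probe-batch
   node-averaged `E_a` fell below `α E_a⁰`, rescale every weight by
   `E_a^L/E_a`. Cubic homogeneity makes this overshoot the floor;
   the rescale is applied literally anyway since overshoot still
   prevents the zero state. Clipping precedes the floor check because
   clipping can only lower `E_a`.

`E_a⁰` is measured on the initial random matrix against the probe
batch, before any training step. A run is deterministic given its
master seed, from which independent streams for signals,
initialization and batch shuffling are derived. Exact-zero activity
raises a collapse error (rescaling cannot recover it); non-finite
gradients or weights raise a numerical error naming the epoch.

Per-epoch diagnostics (applied `w_u`, post-clip max |w|, floor-rescale
factor, probe `E_a`) are recorded in the results object; the constraint
tests assert on them directly. Note the epoch-end matrix can exceed the
applied `w_u` by exactly the floor-rescale factor when both constraints
fire in the same epoch — the constraints are sequential, not jointly
projected.

## Network statistics

- **Stability RMSE**: per network, flatten |w|, sort descending,
  divide by mean |w|; average the RMSE over all unordered pairs.
  Absolute values are used for ordering and normalization, consistent
  with every other strength notion in the package; the statistic is
  invariant to weight permutations and per-network rescaling.
- **Strength distribution**: strengths `s_i = Σ_j |w_ij|` sorted
  descending; 100 points at the order nearest `((n+1)/101)·N`,
  normalized by the maximum, paired with cumulative probability
  `(n+1)/101`. Inputs shorter than 100 use every value.
- **Cluster curves**: for each ratio `r` on a 0.01 grid, keep the top
  `⌊r·n_c⌋` off-diagonal connections by |w| (ties broken by (row,
  column) index, deterministically); the cluster size of a node is its
  number of distinct partners in either direction; the curve reports
  the maximum, normalized by the full-network (r = 1) value so curves
  from different networks are comparable. Self-connections are excluded
  throughout. Binary topological networks are weighted by
  `w(i,j) = d(i)·d(j)` (degree product) before selection.

## Synthetic connectomes

`synth_connectome` emulates only the one feature the comparisons need:
a controllable heavy tail in node strength. Propensities are lognormal
with sigma = `hubness`; edge weights proportional to propensity
products with mild lognormal noise, kept at the requested density.
It reproduces neither spatial embedding, modularity, bilateral
symmetry nor the measurement noise of real connectomes — tests passing
on it show the analysis pipeline is correct, not that the model matches
any particular species' brain.

## Problem sizes and defaults

The reference protocol is N=200 nodes, 200 epochs × 10 batches, 10⁴
signals, lr 0.01, `n_sigma=5`, `α=10⁻³`. (The activity-floor parameter
is exposed freely; 10⁻³ is the package default.) The full protocol runs
in about a minute on one CPU, so the trace-shape and cluster-curve
checks use it directly. Cross-condition comparisons (stability,
pooled strength ranges) use five replicates at N=50, 50 epochs, where
the qualitative orderings are already decisive. At that reduced scale
the transient before the trace reaches the activity floor lasts about
38 epochs (its length is set by the learning rate and α, not by N), so
trace-flatness is only meaningful at the full epoch count.

## Known limitations

- Fully connected weights: no per-node connection-count caps, so very
  large sparse connectomes are only comparable statistically.
- Single layer, single propagation step; no spiking dynamics, Dale's
  law, learning-rate schedules or early stopping.
- Homogeneous random input only; no structured or environment-driven
  stimuli.
- The homeostatic rescale is global, not per node; the floor is checked
  on the node-averaged activity cost.
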