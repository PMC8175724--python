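# enform

Energy-constrained formation of brain-like networks: a generative
connectome model driven by minimization of the activity-to-wiring cost
ratio.

## The scientific problem

Brain networks — from neuron-level synaptic wiring diagrams to
region-level human connectomes — share characteristic structure: a
heavy-tailed node-strength distribution with prominent hubs, and large
clusters that survive even when only the strongest connections are
kept. A long-standing hypothesis is that these features arise from the
brain's tight energy budget: building and maintaining connections costs
energy (wiring cost), and so does signal transfer (activity cost).

`enform` implements a simulator for this hypothesis. A signed, generally
asymmetric weight matrix `W` (entry `w_ij` is the connection from node
*j* into node *i*) is refined by gradient descent on a normalized energy
function, under two boundedness constraints, and the resulting networks
are compared statistically with random-graph baselines and — if you
supply the files — with real connectome matrices.

## The model

For an activation state `v⁰` with ternary entries in {−1, 0, +1}
(excitatory / silent / inhibitory), one propagation step is
`v_i = Σ_j w_ij v⁰_j`. Per node *i*:

- wiring cost: `E_w(i) = Σ_j |w_ij|`
- activity cost (Hopfield-like, batch-averaged):
  `E_a(i) = ⟨ Σ_j |v_i w_ij v_j| ⟩`
- objective: the node-averaged normalized energy `⟨ E_a(i) / E_w(i) ⟩`,
  minimized with Adam (lr 0.01) over 200 epochs × 10 batches of 1 000
  signals drawn from a pool of 10⁴ random ternary vectors (each vector's
  nonzero fraction `p ~ U(0, 0.5)`).

Unconstrained, the objective admits two unphysical escapes: `E_w → ∞`
(weight divergence) and `E_a → 0` (a dead network). Two constraints
close them off after every epoch:

- **weight limit** — entries with `|w| > w_u` are clipped to
  `w_u = ⟨|w|⟩ + n·σ(|w|)`, recomputed from the current matrix;
- **homeostatic activity floor** — when the node-averaged activity cost
  drops below `E_a^L = α E_a⁰`, all weights are rescaled by
  `E_a^L / E_a`, mirroring homeostatic synaptic scaling.

With a finite limit the objective stabilizes; without it the trace
decreases without bound. The stabilized networks develop hubs (wide
strength distributions) and keep large clusters at small connection
ratios — the signatures seen in real connectomes.

## Worked example

```python
from enform import EnergyNetworkModel

model = EnergyNetworkModel(n_nodes=50, n_epochs=50, n_sigma=5, alpha=1e-3, seed=1)
res = model.fit()
print(res.summary())
```

```
Energy-constrained network formation — refinement results
==========================================================
nodes                 50
epochs x batches      50 x 10
signal pool           10000 (p_max=0.5)
weight limit n_sigma  5
activity floor alpha  0.001
seed                  1
----------------------------------------------------------
objective <E_a/E_w>   first epoch 1.50418
                      last epoch  0.0210382
initial E_a^0         38.7163
node strength         min 0.009593  max 4.43  CV 0.826
```

The objective fell ~70-fold and then levelled off on the activity floor
(the 10-epoch bin means are 0.719, 0.161, 0.057, 0.026, 0.022). The
node-strength coefficient of variation of 0.83 is far above the ~0.1 of
the initial random matrix: training has concentrated strength onto hub
nodes. `res.strength_distribution().value_range` (min/max of the
normalized strength quantiles) is 0.0022 for the trained network versus
0.60 for its random initialization — the wide, heavy-tailed range
characteristic of connectomes.

```python
res.cluster_curve().to_frame()       # max cluster size vs connection ratio
res.plot_trace(bin_size=10)          # energy convergence (log scale)
res.save("runs/demo")                # CSV matrices + trace + JSON manifest
```

The same pipeline is scriptable from the shell:

```bash
enform simulate --n 50 --epochs 50 --n-sigma 5 --alpha 1e-3 --seed 1 --out runs/demo
enform simulate --n 50 --epochs 50 --n-sigma none --seed 1 --out runs/nolimit
enform stability runs/demo runs/nolimit
enform strength-dist runs/demo --out dist.csv
enform clusters my_connectome.csv --degree-product   # binary topological nets
```

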