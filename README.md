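# fracbrain

Fractional-order network model of protein-driven neurodegeneration.

`fracbrain` simulates the joint spread of amyloid-beta and tau protein on
brain-connectome graphs, together with astrocyte dynamics and a per-region
neuronal-damage score. Each graph node carries a six-variable state — healthy
and toxic amyloid-beta (u, ũ), healthy and toxic tau (v, ṽ), astrocytes (w)
and damage (q ∈ [0, 1]) — evolving under heterodimer conversion kinetics,
logistic growth, an amyloid-to-tau coupling, and graph-Laplacian diffusion of
the four protein species. Time derivatives are Caputo fractional derivatives
of order α ∈ (0, 1]; decreasing α introduces a power-law memory that delays
toxic propagation, and α = 1 recovers the classical ODE system.

## The model

At each node (dropping node indices; L is the graph Laplacian of the species):

```
D^α u  = u (a0 − a1 u) − a2 u ũ                      − ρ_u  (L u)
D^α ũ  = −ã1 ũ + a2 u ũ − μ ũ (w − ũ)                − ρ_ũ  (L ũ)
D^α v  = v (b0 − b1 v) − b2 v ṽ − b3 ũ v ṽ           − ρ_v  (L v)
D^α ṽ  = −b̃1 ṽ + b2 v ṽ + b3 ũ v ṽ                   − ρ_ṽ  (L ṽ)
D^α w  = w (c0 − w / c1)
D^α q  = (1 − q) (k1 ũ + k2 ṽ + k3 ũ ṽ + k4 q)
```

The astrocyte term μ ũ (w − ũ) clears toxic amyloid when astrocytes outnumber
it and amplifies it otherwise (the "dual role"). The Laplacian is
L = ρ (D − A) with fiber-weighted adjacency A_ij = n_ij / l_ij², so rows sum
to zero and pure diffusion conserves each species' total.

## Quick start (Python)

```python
>>> from fracbrain import ModelParameters, positive_equilibrium, classify_stability
>>> p = ModelParameters()          # default parameter set
>>> e = positive_equilibrium(p)    # coexistence point of the local model
>>> e.state
array([0.59609375, 0.15390625, 0.33010961, 0.14020613, 0.1       ])
>>> classify_stability(e.state, p, alpha=0.8).stable   # Matignon condition
True
```

Network run on a synthetic connectome:

```python
from fracbrain import (GeneratorSpec, generate_connectome, ModelParameters,
                       NetworkParameters, simulate_network, summarize)

conn = generate_connectome(GeneratorSpec(n_nodes=60, seed=3))
net = NetworkParameters(base=ModelParameters())
traj = simulate_network(conn, net, alpha=0.9, t_end=100.0)  # dt auto-selected
per_region = summarize(traj, conn, "region")   # average ũ, ṽ, q time series
```

## Quick start (CLI)

```console
$ fracbrain generate-connectome --n 60 --seed 3 nodes.csv edges.csv
wrote N=60 nodes, E=82 edges; mean fibers 87.96, mean length 32.506 mm
$ fracbrain simulate-network --connectome nodes.csv,edges.csv --alpha 0.9 \
    --t-end 100 --out run90
converged: False; terminal toxic-tau ranking: ['brain stem', 'limbic',
'temporal', 'frontal', 'basal ganglia', 'parietal', 'occipital']
```

Other subcommands: `simulate-local`, `equilibria` (JSON report of all
nonnegative equilibria with stability verdicts across α), `sensitivity`
(Pearson correlations of sampled parameters against model outputs). Every run
writes a JSON manifest with the resolved configuration, package version, and
SHA-256 checksums of the input files. A YAML `--config` file fills in
defaults; explicitly passed flags win.

## Connectome format

Two CSV tables. Nodes: `id, x, y, z, brain_id, region` (0-based contiguous
ids; 7 region labels; 49 recognized brain IDs). Edges: `source, target,
n_fibers, length_mm` (undirected, no self-loops or duplicates). Optional
boolean node columns `seed_abeta` / `seed_tau` mark the toxic seeding sites;
the default seeds are small fractions of the healthy baseline (0.38% for
toxic amyloid, 0.25% for toxic tau).

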