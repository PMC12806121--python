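# Methods

Model equations, numerical schemes, conventions and design choices behind
`fracbrain`. Everything here is implemented in `src/fracbrain/` and exercised
by the test suite.

## 1. Local (temporal) model

Five concentrations per compartment — healthy/toxic amyloid-beta (u, ũ),
healthy/toxic tau (v, ṽ), astrocytes (w) — plus a damage fraction q:

```
D^α u  = u (a0 − a1 u) − a2 u ũ
D^α ũ  = −ã1 ũ + a2 u ũ − μ ũ (w − ũ)
D^α v  = v (b0 − b1 v) − b2 v ṽ − b3 ũ v ṽ
D^α ṽ  = −b̃1 ṽ + b2 v ṽ + b3 ũ v ṽ
D^α w  = w (c0 − w / c1)
D^α q  = (1 − q) (k1 ũ + k2 ṽ + k3 ũ ṽ + k4 q)
```

D^α is the Caputo derivative of order α ∈ (0, 1]. Healthy species grow
logistically and are converted by their toxic counterparts (heterodimer
kinetics); toxic species clear at first order; b3 ũ v ṽ couples the amyloid
and tau pathologies; μ ũ (w − ũ) is the astrocyte dual role (clearance when
w > ũ, amplification when w < ũ). Damage is monotone — the rate is
nonnegative for q ∈ [0, 1] and q = 1 is absorbing.

**Sign convention.** The toxic clearance terms enter with a minus sign
(−ã1 ũ, −b̃1 ṽ): clearance removes toxic protein. This is also the convention
under which the default parameter set yields the reference coexistence
equilibrium E* below (verified by hand before coding).

### Default parameters

| symbol | field | value | | symbol | field | value |
|---|---|---|---|---|---|---|
| a0 | `a0` | 1.035 | | c0 | `c0` | 1.0 |
| a1 | `a1` | 1.38 | | c1 | `c1` | 0.1 |
| a2 | `a2` | 1.38 | | μ | `mu` | 0.1 |
| ã1 | `a1_tilde` | 0.828 | | k1 | `k1` | 0.0001 |
| b0 | `b0` | 0.69 | | k2 | `k2` | 0.01 |
| b1 | `b1` | 1.38 | | k3 | `k3` | 0.1 |
| b2 | `b2` | 1.035 | | k4 | `k4` | 0.001 |
| b̃1 | `b1_tilde` | 0.552 | | ρ_u | `rho_u` | 1.38 |
| b3 | `b3` | 4.14 | | ρ_ũ | `rho_u_tilde` | 0.138 |
| α | `alpha` | 1.0 | | ρ_v | `rho_v` | 1.38 |
| | | | | ρ_ṽ | `rho_v_tilde` | 0.014 |

The four diffusivities are mapped to the species in listing order
(u, ũ, v, ṽ). All parameters are validated (nonnegativity, α ∈ (0, 1],
positive carrying capacities) and serializable to/from YAML or JSON.

## 2. Equilibria and stability

`find_equilibria` enumerates the closed-form branch cascade — w ∈ {0, c0 c1};
u-branches from u (a0 − a1 u) = a2 u ũ including the interior 2×2 linear pair;
tau branches analogously, including the coupled interior root — then polishes
every candidate with `scipy.optimize.root` and keeps solutions with residual
below 1e-10, deduplicated at 1e-8. The strictly positive coexistence point is

```
E* = (0.59609375, 0.15390625, 0.33010961, 0.14020613, 0.1)
```

with the default parameters. On the coexistence branch the toxic-amyloid level
has the closed form (used as the oracle for the dual-role study)

```
ũ* = (a2 a0 / a1 − ã1 − μ c0 c1) / (a2² / a1 − μ).
```

Stability uses the analytic 5×5 Jacobian. For α = 1 the criterion is
Re λ_i < 0; for α < 1 the Matignon-type condition |arg λ_i| > απ/2. The
verdict records the margin (min_i |arg λ_i| − απ/2, or −max Re λ_i) and flags
near-boundary spectra (|margin| < 1e-9) as marginal. A point with
b2 b0 / b1 > b̃1 supports self-sustained toxic tau ("primary tauopathy");
the default set is secondary (0.5175 < 0.552).

## 3. Solvers

* **α = 1:** classical RK4, fixed step (default dt = 0.01). Blow-ups raise
  `SolverBlowUpError` carrying the last finite time.
* **α < 1:** Adams–Bashforth–Moulton predictor-corrector (PECE) with full
  history, O(M²) work for M steps. Predictor weights
  c_k = ((k+1)^α − k^α) dt^α / (α Γ(α)); corrector weights
  d_k = ((k+2)^{α+1} + k^{α+1} − 2(k+1)^{α+1}) dt^α / Γ(α+2) with the j = 0
  corrector weight (n^{α+1} − (n−α)(n+1)^α) dt^α / Γ(α+2). Passing α = 1
  dispatches to RK4.
* **Oracle:** `mittag_leffler(alpha, z)` evaluates the series
  Σ z^k / Γ(αk + 1) in log-Gamma form for |z| ≤ 10; validated against
  E_1(z) = e^z and E_{1/2}(−x) = e^{x²} erfc(x). The predictor-corrector on
  D^α y = −y matches it within 1e-3 at dt = 1e-3 for α ∈ {0.5, 0.8, 0.9}.

**Step-size rule.** The explicit PECE scheme has a bounded linear stability
region: on D^α y = −λ y it was measured stable through |λ| dt^α ≈ 1.5 and
divergent at ≈ 2. Network runs with α < 1 therefore default to
`suggest_fractional_dt`: dt = (0.75 / (λ_max + 1))^{1/α}, capped at 0.05,
where λ_max is the largest Laplacian eigenvalue over the diffusing species
(0.75 gives a 2× safety factor; the +1 absorbs the O(1) reaction rates). The
step count is rounded to a multiple of 100 so thinned storage stays on a
uniform grid.

## 4. Network model

Nodes are gray-matter regions; edges carry fiber count n_ij and mean length
l_ij. Adjacency A_ij = n_ij / l_ij²; per-species Laplacian L^s = ρ_s (D − A).
Rows sum to zero, so reaction-free dynamics conserve per-species totals (to
1e-10 in the tests) and any spatially homogeneous equilibrium of the local
model is a fixed point of the network field. Astrocytes and damage do not
diffuse. The flat state layout is variable-blocked:
[u_1..u_N | ũ_1..ũ_N | v | ṽ | w | q].

**Seeding.** Default initial condition: healthy baseline
(u, v, w) = (0.75, 0.5, 0.1) — the disease-free levels a0/a1, b0/b1 and the
astrocyte carrying capacity c0 c1 — with toxic amyloid seeded at 0.38% of the
local healthy amyloid on the amyloid seed set and toxic tau at 0.25% of
healthy tau on the tau seed set (*relative* mode; an *absolute* mode treats
the fractions as raw concentrations). Synthetic graphs assign amyloid seeds
to temporal/frontal IDs (inferiortemporal, fusiform, temporalpole,
medialorbitofrontal, frontalpole) and tau seeds to entorhinal and brain-stem
nodes.

**Heterogeneity.** `NetworkParameters.overrides` patches local (reaction)
parameters per node; diffusivities stay global. `mixed_tauopathy_overrides`
expands brain-ID-level (b2, b3) assignments to node overrides; the default
primary-capable pair used in tests is (1.6, 4.14), chosen so that
b2 b0 / b1 = 0.8 > b̃1 = 0.552 while keeping the default coupling strength.

**Summaries.** `summarize` averages ũ, ṽ and q over regions or brain IDs and
ranks groups by terminal average toxic tau.

## 5. Synthetic connectome generator

Real reference connectomes are not bundled (text-only constraint), so
`generate_connectome(GeneratorSpec(...))` produces graded substitutes:

* nodes apportioned over 7 regions (largest-remainder), brain IDs assigned
  round-robin from a 49-ID catalogue, 3-D coordinates as Gaussian blobs
  around per-region centers (SD 14 mm);
* edges drawn with distance-decay probabilities rescaled to a target density
  (default 0.0316), then augmented with a minimum-spanning-tree pass so the
  graph is always connected;
* fiber counts from a clipped lognormal (μ = 2.392, σ = 1.6, clip
  [1, 4966.5], target mean ≈ 39.33) and lengths from a clipped gamma
  (shape 6, scale 5 mm, clip [10.270, 83.003], mean ≈ 30.089); summary
  statistics land within 15% of these targets for n ≥ 200.

Everything is reproducible from the `GeneratorSpec` seed, including byte-identical CSV
output. `fixture_graphs()` provides hand-specified oracle graphs, notably a
12-node two-territory fixture (dense blocks joined by one weak bridge) used
for the dual-role and mixed-tauopathy studies.

## 6. Sensitivity analysis

`run_sensitivity` samples the 16 local parameters independently and uniformly
within ±10% of nominal (configurable; deviation 0 reproduces the nominal
vector), integrates each sample with RK4 from
(0.75, 0.0075, 0.5, 0.005, 0.1, 0) to t_eval = 200, and reports the Pearson
correlation between each parameter and each of the six outputs. Integration
is vectorized across samples; diverging samples are excluded and counted.
Acceptance checks sign only (corr(a0, q) > 0 across seeds); exact correlation
magnitudes depend on the sampling seed and are not stable reference values.

## 7. Problem sizes and runtimes

The test suite (~4 min single-core) uses: the 12-node fixture for network
dynamics, dual role and mixed tauopathy; a 200-node synthetic connectome
(seed 7) for the memory-effect ordering (t_half of average ṽ and q strictly
increasing as α drops 1 → 0.9 → 0.8); n = 1000 sensitivity samples per seed;
and t ≈ 5·10⁴ horizons for the fractional damage limit (the α < 1 approach to
q = 1 has a power-law tail). `scripts/acceptance.py` runs in ~30 s.
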