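# Methods

## Model

The state of a network of `N` regions is a pair of concentration vectors
`(U, V)`. Each region runs the same local two-species kinetics `f, g`
(Gierer-Meinhardt, Mimura-Murray or Gray-Scott), and regions exchange mass
through a coupling operator built from the weighted directed adjacency
matrix `W` (`W[i, j]` = weight of the edge i → j):

    dU/dt = f(U, V) + D_u · L(t) U
    dV/dt = g(U, V) + D_v · L(t) V

In the default **output diffusion** mode,
`(L U)_i = Σ_j W[j, i] U_j − U_i Σ_j W[i, j]`: region i receives along its
afferents and loses along its efferents, so mass flows in the direction of
axonal projection. Input diffusion swaps the roles, and both variants exist
on the transposed adjacency (`out_transpose` ≡ input diffusion of the
original graph, and vice versa — the four modes form two pairs, kept as
four named options for configuration clarity). Every mode yields columns of
`L` summing to zero by construction, so pure diffusion conserves
`Σ_i U_i(t)` exactly up to solver roundoff; this is the invariant the
conservation tests pin down. Self-loops are dropped when building `L`
(diffusion to self is a no-op). An optional row normalization gives every
node unit total out-rate, which changes time scales but not conservation.

The Wilson-Cowan model is the non-diffusive baseline: the network term
enters the excitatory sigmoid input as `P + η (L E)` instead of as mass
transport, with the offset-subtracted logistic response of the classic 1972
formulation so that the resting state `(E, I) = (0, 0)` is exact.

### Weight semantics

Tract-tracing connection strengths are ordinal categories (0 = absent …
4 = very strong; verbal categories map onto this scale with fractional
interpolants such as 1.5 for "weak to moderate"). Analyses use the
exponential transform

    w(x) = 10^(−(16/49)(x−4)²),

strictly increasing on [0, 4] with w(4) = 1 — so the strongest category is
the weight unit and a "moderate" connection (x = 2) carries ≈ 0.049.

### Demyelination modelling

A `ModulationSchedule` multiplies the weights of a selected edge set by
`m(step)`. The coupling is split as `L(t) = L_rest + m(t) L_lesion`, where
`L_lesion` is the conserving operator of the targeted edges alone; the sum
is therefore conserving at every instant, and only the targeted edges feel
the modulation. Kinds:

- `step`: 1 before an onset iteration, a constant factor after (e.g. 0.3
  for a 70 % weight reduction, 0.1 for 90 %);
- `damped_cosine`: `max(floor, 1 − A e^(−λ·step)(1 − cos(2π·step/T))/2)`,
  an oscillating reduction whose excursions decay at rate λ — a stylized
  relapsing-remitting disease course. The exact analytic form of the
  published modulation curve is not stated anywhere, so this
  parameterization was chosen as the simplest damped cosine that respects
  the two documented anchors (amplitude 10, lower clamp 0.1: amplitudes
  that large saturate at the floor, giving the characteristic clipped
  troughs);
- `table`: explicit per-step multipliers, last value held.

Multipliers are required to be positive; a floor ≤ 0 is a configuration
error.

### Distance relays

Region centroids live in a stereotaxic coordinate system, so straight-line
(Euclidean) distances between regions are available even though real fiber
tracts curve. A connection A → B of weight `e1` can be expanded into a
relay chain A → E_1 → … → E_k → B with rate `D·e1` into the first relay and
`Θ·D·e1` out of each relay, implementing

    dA/dt = −D e1 A,   dE/dt = D e1 A − Θ D e1 E,   dB/dt = Θ D e1 E

for k = 1 and its obvious generalization for longer chains. More relays
mean later half-mass arrival at B — a discrete stand-in for conduction
delay. The relay count per edge is derived from the distance/weight
transform `F1·d + F2/w + S` (defaults F1 = F2 = 0.01, S = 1), rounded to
the nearest nonnegative integer; the leverage Θ defaults to 1. Whether this
transform should instead scale Θ is genuinely open — the source material
describes the effect only qualitatively (a damping of oscillations) — so
both hooks are exposed and the rounded-relay-count mapping is the default
as the simplest monotone choice.

### Noise

Two options, both applied after the deterministic update of a step:

- additive: `U += σ √dt ξ` per node;
- coupled Ornstein-Uhlenbeck: a scalar `δ(t)` follows the Euler-Maruyama
  recursion `δ += θ(μ − δ)dt + σ√dt ξ` and kicks the state by
  `dt · δ · (L U)` — noise that respects the network structure (and, since
  `L` is conserving, the total mass). Default is activator-only, switchable
  to both species.

One seeded `numpy` generator per run makes every stochastic path bitwise
reproducible; the seed is recorded in the trajectory metadata and in run
manifests.

## Solvers and numerical choices

- `euler` and `rk4`: fixed-step; the paper-scale presets are dt = 2 with
  5000–10000 iterations for GM and dt = 0.1 with 400 steps for MM.
- `dopri_adaptive`: scipy's step-controlled Dormand-Prince (RK45) with the
  schedule evaluated at `floor(t/dt)` so modulated runs agree with the
  fixed-step solvers on the dt grid. Stochastic runs require a fixed-step
  method.
- `implicit_euler`: backward Euler with a damped Newton iteration and a
  finite-difference Jacobian — intended for stiff small systems; its cost
  grows cubically with `2N`, so use it for probe runs, not large sweeps.
- The GM activator term divides by V. V ≤ 0 raises a domain error rather
  than being silently clamped; setting `SolverConfig.v_floor` opts into an
  explicit clamp (used in long oscillatory runs where RK4 stage values can
  transiently undershoot).
- Blow-up (non-finite state) aborts with the failing step index; explicit-
  solver failures carry a hint to try the implicit method.

## Stability analysis

The reduced uncoupled GM system (κ = 0, σ_v = 0, rates fixed at 0.01, free
parameters a = σ_u, b = μ_u) has the positive fixed point `u* = (0.01+a)/b`,
`v* = u*²`. Its Jacobian determinant is `0.01·b > 0` for every admissible
(a, b), so classification reduces to the trace sign: the fixed point is
stable iff `0.02/u* − b − 0.01 < 0`, and the boundary is a Hopf curve. The
implementation classifies by the numerically computed eigenvalues (largest
real part; |Re| < 1e−10 is reported "marginal") and finds the boundary
`b*(a)` by a coarse logarithmic scan plus Brent refinement rather than the
closed form, so the same machinery would survive a change of the reduced
system. For a ≥ 0.01 the trace is negative for every b and no boundary
exists (reported as NaN). Orientation of the regions: for fixed b the small-a
side of the curve is oscillatory; equivalently, for fixed a < 0.01 the
large-b side is oscillatory. Tests cross-check the classification against
long simulations (decay vs. sustained oscillation of |u − u*|) on a probe
grid.

## Synthetic data

`mechanosensory_fixture(seed)` builds a 40-node bilateral network: the 20
published region abbreviations × {L, R}, the mechanosensory chain (DRGs →
ipsilateral cuneate nucleus → contralateral VL/VPL thalamus → ipsilateral-
to-thalamus S1), a gracile/precerebellar/cerebellar loop, and seeded random
cortico-cortical and thalamo-cortical background edges with density
matching a plausibly sparse subconnectome (~100 edges). DRG nodes are pure
sources (no afferents), contralateral edges are flagged, every edge carries
an ordinal category in {1..4} whose transform is its weight, and centroids
are synthetic coordinates with the hemisphere encoded in the sign of x.

What it emulates: the pathway topology, bilateral symmetry, ordinal weight
semantics and source-only sensory ganglia of the real mechanosensory
subconnectome. What it does not: the actual tract-tracing weight matrix,
region-specific connection probabilities, and real stereotaxic geometry.
Passing tests on the fixture therefore demonstrate the machinery (lesion
effects propagate downstream, clustering finds coherent groups), not the
published region-level numbers, which depend on the downloadable empirical
weights.

Surrogate generators (Erdős–Rényi, Watts–Strogatz, Barabási–Albert via
networkx; Klemm–Eguiluz growth with inverse-degree deactivation and
directed degree-preserving double-edge swaps implemented here) produce
null models with matched node/edge budgets; rewiring preserves both degree
sequences exactly.

## Analysis conventions

- Cross-correlation: zero-lag Pearson on post-transient series; the default
  transient is the first 10 % of samples (oscillations settle within about
  100 iterations in the reference runs). Constant series correlate 0 with
  a warning; the diagonal stays 1.
- Kuramoto order parameter: phases from the Hilbert analytic signal of
  mean-subtracted series, 5 % trimmed at each window edge where the
  transform rings; constant series are excluded with a warning.
- Co-activation: node active above its own mean + 0.5 SD (configurable);
  pair score = |both active| / |either active|.
- Clustering inputs must be nonnegative: correlations are mapped through
  (1 + c)/2. Spectral clustering = normalized-Laplacian embedding +
  seeded k-means, k from the eigengap heuristic unless given. MCL follows
  the published parameter semantics exactly (zero threshold 1e−7, equality
  threshold 1e−7 for termination, loop gain setting the diagonal when
  positive, inflation 2.0); clusters are the attractor-row supports, merged
  when they overlap.
- Clustering comparison: average best-match Jaccard, symmetric, 1 iff the
  partitions are identical.
- Sweep grids are inclusive at both endpoints — required to reproduce the
  published combination counts (16, 256, 540, 375) — and enumerate in
  lexicographic order with a tested index ↔ parameter-tuple bijection. Of
  the two printed descriptions of the 375-combination MM sweep, the
  consistent reading (A, B, C over 14–18 step 1, D over 0.2–0.6 step 0.2)
  is adopted; the 540-combination grid uses the other printed ranges. A
  failed combination is excluded with a warning, not fatal.

## Parameter defaults

- GM diffusion defaults `D_u = 0.001, D_v = 0.002`: an order of magnitude
  below the reaction rates (~0.01), chosen so that network coupling on
  unit-scale weights perturbs the local limit cycle without quenching it
  (at `D_u ≈ 0.005` the coupling stabilizes the 5-node test network —
  diffusive stabilization is real, but it would make every oscillatory
  preset useless on dense graphs).
- The Turing-lattice demonstration uses `r_u = r_v = 1, μ_u = 1,
  μ_v = 1.2, σ_u = 0.02, κ = 0.25, D_u = 0.02, D_v = 1`: linear analysis
  puts the unstable band at squared wavenumbers ≈ 1.3–47, well inside the
  spectrum of a 32 × 32 torus Laplacian, and the saturation κ bounds the
  pattern amplitude. A 32 × 32 lattice keeps the demonstration to tens of
  seconds; the pattern is stationary by t ≈ 300.
- MM defaults follow the classic coexistence set (A = 35, B = 16, C = 9,
  D = 0.4) with sweep-scale diffusion `dP = 0.1, dQ = 0.01` and initial
  values `P0 = 6, Q0 = 12`.
- The Wilson-Cowan preset `wc_limit_cycle` ships the published parameter
  list (a_E = 1.2 … P = 0.25). Under the classic sigmoid adopted here that
  point relaxes to a steady state — its maximal excitatory loop gain
  `c_EE a_E/4 = 1.5` sits at the Hopf margin — so the preset is tested for
  boundedness, and a separate `wc_oscillatory` preset (textbook
  strong-coupling values, c_EE = 16, c_EI = 12, c_IE = 15, c_II = 3)
  carries the limit-cycle property test. The exact sigmoid variant of the
  original toolchain is not recoverable from the available material.

## Known limitations

- Dense `L`: fine for connectome-scale networks (tens to hundreds of
  nodes) and 32 × 32 lattices; thousands of nodes would want a sparse
  coupling path.
- No delay differential equations: distance enters only through relay
  chains, which add first-order lags, not pure delays.
- The implicit solver's finite-difference Jacobian is O((2N)³) per step.
- Phase extraction degenerates on non-oscillatory signals; the Kuramoto
  statistic is only meaningful in oscillatory regimes.
- Spectral/FFT analyses of trajectories are out of scope.
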