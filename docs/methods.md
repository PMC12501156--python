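# Methods

## Model formalism

All models are continuous-time Markov processes on finite sets of molecular
states, represented as directed graphs (`RateGraph`) whose edge labels are
transition rates affine in a single scalar input, the TF concentration
`x ≥ 0` (units nM): `rate_eff = rate + x_coeff · x`.  TF-binding edges carry
the concentration term in `x_coeff`; Pol-binding edges absorb the Pol
concentration into their rate constant.  Graphs must be strongly connected
(unique stationary distribution) and carry per-state transcription weights
`q_i`; multi-input labels and time-dependent inputs are out of scope.

Fold changes are ratios of steady-state rates, `F(x) = r*(x)/r*(0)`;
linear mRNA decay cancels in the ratio and is therefore not carried as a
parameter.

## Steady-state solvers

* **Path products** (`steady_state_equilibrium`): valid only under the
  Kolmogorov cycle condition, which is verified first on a cycle basis of
  the undirected support (relative tolerance 1e-9; a cycle whose forward
  and backward products are both zero at the given `x` — e.g. binding
  cycles at `x = 0` — counts as balanced).  Weights `μ_i` are products of
  forward/backward rate ratios along a BFS tree from the reference state.

* **Matrix-Tree sums** (`steady_state_spanning_tree`): `ρ_i` is the sum
  over spanning trees rooted at `i` (edges oriented toward the root) of
  the product of edge rates.  Trees are enumerated exhaustively for ≤ 12
  vertices (beyond that the solver falls back to the nullspace method with
  a warning); the rooted-tree index is cached per graph topology, so
  parameter or concentration sweeps re-use the enumeration.  Products are
  accumulated in log space and combined with log-sum-exp, which keeps
  probability ratios of hundreds of decades representable in doubles; an
  optional arbitrary-precision backend (`precision=` significant digits,
  100 by convention) evaluates the same sums in mpmath for ill-conditioned
  cases.  `steady_state_sweep` vectorizes the computation over a
  concentration grid.

* **Oracles** (`steady_state_oracle`, tests only): the `nullspace` route
  computes the kernel of the generator by GTH (Grassmann–Taksar–Heyman)
  state reduction — mathematically Gaussian elimination on the singular
  Laplacian, but subtraction-free, hence componentwise relatively accurate
  even for stationary probabilities 20+ decades below 1 (an SVD kernel has
  only normwise accuracy and is useless for such components).  The `ode`
  route integrates the time-rescaled master equation (`L/s`, `s` the
  fastest exit rate; the steady state is scale-invariant) from the uniform
  distribution with LSODA, switching to exact matrix-exponential
  propagator steps for horizons beyond 1e6 where adaptive steppers stall
  on near-degenerate spectral gaps; convergence is declared at residual
  `max|dP/dt| < 1e-10` on the rescaled system.  Because double-precision
  time integration has an absolute error floor (~1e-11 here), an
  arbitrary-precision variant (`precision=`) builds the rescaled generator
  with exactly zero column sums in mpmath and squares its one-unit
  propagator up to `t ~ 1e36`, with the residual threshold tied to the
  working precision.  The cross-solver acceptance check (1e-7 per
  component, components above 1e-12) uses this variant for the ODE leg;
  the double path cannot resolve 1e-12-sized components to seven digits
  in principle.

Degenerate cases: all-`ρ` underflow raises with a pointer to the
high-precision backend; a graph that loses strong connectivity (e.g.
`aT = 0` in the cycle model) is rejected at construction.

## Model layers

**Recruitment (4 states).**  The nonequilibrium parameterization is the
eight rates `(aT, aT_p, bT, bT_Tp, ap, ap_T, bp, bp_Tp)` plus `q3, q4`;
the equilibrium reduction is `KT = aT/bT`, `Kp = ap/bp`,
`ω = (aT_p/bT_Tp)/(aT/bT)`, `ε = q4/q3`.  The closed form and the
direction-sign expression `Kpω(ε−1) + εω − 1` are implemented directly and
cross-checked against the graph route.  For the coherence property suites,
a *coherent* nonequilibrium model is one where the cooperativity analogue,
`ε`, and the TF-induced changes in Pol binding (`ap_T/ap`) and retention
(`bp/bp_Tp`) all lie on the same side of 1 — this excludes both published
flavors of incoherence (opposite on/off-rate modulation, and opposite
recruitment-vs-activity effects).

**Cycle (6 states).**  TF binding/unbinding rates are state-independent
(one `aT`, one `bT` on all three cycle states); activation (`k2`) and
completion (`k3`) are irreversible; the TF multiplies rate `i` by `ε_i`
while bound.  The flux proportionality constant is 1 (only fold changes
matter).  Mode classification: coherent positive iff every non-unit effect
accelerates flux (`ε1, ε2, ε3 ≥ 1`, `ε1r ≤ 1`, at least one strict),
mirrored for negative, mixed = incoherent, none = neutral.

**Multisite.**  The mean-occupancy formula is the binomial average over
independent equal sites, `a = N·KTx/(1+KTx)` — the general weighted sum
over configurations with exponent *i* on `(KTx)` for configurations with
`i` sites bound — verified against brute-force enumeration of all `2^N`
configurations.  The saturable modulation law is applied to `k2` and `k3`
only by default.  In the explicit multisite graph, the bound-state
multiplier on rate `i` with `k` sites occupied is `k·ε_i` for `k ≥ 1` and
exactly 1 at `k = 0` (zero occupancy must leave basal rates untouched);
binding stoichiometry is `(N−k)·aT·x` up, `(k+1)·bT` down.  `N = 1`
reduces bit-for-bit to the single-site cycle graph.

## Response classification

`classify_monotonicity` works on successive differences of `log F`:
differences with magnitude ≤ `rtol` (default 1e-6) count as zero; all-zero
= flat, single-signed = increasing/decreasing, otherwise nonmonotonic,
with the peak location recorded for a single rise-then-fall pattern.
Classification is therefore invariant to positive rescaling of `F`.
Regime maps classify one axis slice at a time (fold change normalized to
that slice's basal input); the swept axis needs ≥ 8 points, the classified
axis ≥ 3 (site-number grids run 1..6).  Axis ranges for the reference maps
(`bT ∈ [1e-3, 1e2] /s`, `x ∈ [0.1, 1e3] nM`, `KT ∈ [1e-3, 1e2] /nM`) are
chosen to contain all three regimes for the reference parameter sets and
are caller-overridable; grid densities default to 25 per swept axis and 50
points per curve.  Parameter sampling is log-uniform, with default ranges
bracketing the reference values by roughly two orders of magnitude
(binding 1e-4–1 /nM/s, unbinding 1e-3–1e2 /s, cycle rates 1e-3–10 /s,
modulation factors 1e-2–1e2).

## Synthetic MPRA generator

The generator emulates a lentiviral reporter assay over synthetic
regulatory sequences: 1–6 identical TF sites × 6 affinity levels × 3
orientations × 3 spacings (4/10/20 bp) × 3 random-background sequences,
plus 417 random-DNA-only controls.  True activity of a design is the log
fold change of the occupancy-averaged cycle model at its `(N, KT)` (the
reference mechanism: `k1 = 0.05`, `k1r = 1`, `k2: 0.2 → 20`, `k3: 0.05 →
5e-4`, `s2 = 1`, `s3 = 0.1`, `h = 1`, evaluated at `x = 2 nM`);
orientation and spacing carry no true effect (the analysis averages over
them as nuisance), and controls are true-zero.  Observed activity adds a
per-sequence background offset (sd `σ_bg`) and per-measurement residual
(sd `σ_e`); all randomness flows from one seed.  Default noise sets
`σ_bg = σ_e` to 10% of the mechanism's activity dynamic range (≈ 0.24 log
units).  Normalization subtracts the mean *raw* control activity, so it is
idempotent and the control mean maps to exactly 0.

What the generator does **not** emulate: barcode/count-level sampling noise,
sequencing error, sequence-specific background effects correlated with the
design, PWM-derived affinities, or replicate-level DNA/RNA correlation
structure.  A green recovery test therefore establishes that the
statistical pipeline recovers trend classes under Gaussian sequence and
measurement noise of realistic magnitude — not that it would survive every
artifact of real MPRA data.

## Trend classification and model selection

Activity-vs-site-number trends are classified per affinity level by
least-squares fits under four shape constraints — flat (grand mean),
isotonic increasing, isotonic decreasing, and unimodal (for every split
point: isotonic up on site counts ≤ split, isotonic down above; any such
composite is unimodal) — compared by Gaussian AIC
`n·log(RSS/n) + 2(p+1)`.  This deliberately replaces shape-constrained
additive models (SCAM) with isotonic/unimodal regression: the decision
structure (flat vs increasing vs bell vs decreasing by AIC) is identical,
without spline machinery.

The complexity `p` charged to a constrained fit is the *dimension of the
model class searched* — `K` (number of distinct site counts) for a
monotone fit, `K+1` for the bell with its free peak — not the number of
level blocks the isotonic solution happens to realize.  The realized-block
plug-in was evaluated and rejected: blocks are chosen adaptively by the
fit, so charging only for them makes selection strongly anti-conservative
(simulations with six site-count groups show a pure-noise level being
called non-flat ~35% of the time, and an all-flat six-level assay almost
never occurring), which would make the assay useless as evidence.  With
the model-dimension penalty, a pure-noise level is read as flat ~98% of
the time while a bell of amplitude three residual standard deviations with
30 observations per site count is still detected essentially always.

Because observations are fitted as exchangeable, technical replicates of
the same sequence (which share the background offset) inflate the
between-group signal relative to the residual variance and partially
de-calibrate the null; the null-calibration guarantee applies to the
one-replicate design (one measurement per sequence).  A random-effects
treatment of background is a known omission.

**Benchmark for end-to-end recovery.**  Under the default affinity table
(six `KT` values log-spaced over `[1e-3, 1e1] /nM`), the mechanism's
intermediate-affinity level (`KT ≈ 6.3e-3`) is a bell whose downturn is
only ~0.005 log units — two orders of magnitude below the default noise
and hence undetectable by any statistical method, so its exact class
cannot be recovered (the pipeline reads it as increasing, which is the
trend at any resolvable scale).  The recovery benchmark
(`benchmark_mpra_config`) therefore pins the intermediate level at the
mechanism's most balanced bell (`KT = 1.25e-2 /nM`; rise ≈ 0.11, fall
≈ 0.12 log units) and sets `σ_bg = σ_e` to one third of the smallest trend
feature — the conventional 3-sigma edge of detectability, the same scale at
which the bell-power guarantee is stated — with two replicates (54
observations per affinity × site-count cell).  True classes across the six
levels are increasing, increasing, bell, decreasing ×3, and the pipeline
recovers all six in ≥ 90% of seeded replicates.

## Numerical choices and defaults

| quantity | default | note |
| --- | --- | --- |
| cycle-condition rtol | 1e-9 | Kolmogorov products on a cycle basis |
| monotonicity rtol | 1e-6 on log F | below this, differences are noise |
| spanning-tree enumeration limit | 12 vertices | nullspace fallback beyond |
| high-precision digits | 100 | mpmath backend for tree sums |
| ODE oracle residual | 1e-10 (rescaled) | 10^(−digits/2) in mp mode |
| regime-map grids | 25 × 25 (x: 50/curve) | log-spaced |
| MPRA noise | σ = 0.1 × dynamic range | benchmark: smallest feature / 3 |

## Known limitations

* Steady states are numeric, never symbolic rational functions; transient
  dynamics exist only inside the test oracle.
* Monotonicity "theorems" are enforced as large randomized property
  suites, not symbolic proofs; they certify the sampled parameter regions.
* The multisite models assume identical, independent sites; heterogeneous
  affinities and TF–TF cooperativity are out of scope.
* The MPRA trend fitter cannot reproduce spline-based SCAM AIC values;
  only the shape decision is comparable.
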