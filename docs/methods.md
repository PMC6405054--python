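# Methods

This note documents the models, numerical methods, analysis procedures and
design choices behind `gtpatterns`. Everything is dimensionless: time is
scaled by the GTPase inactivation rate, space by the diffusion length of
active GTPase, so the active-GTPase diffusion coefficient is 1 and all other
diffusion coefficients are ratios to it.

## Reaction–diffusion models

Two polarisation motifs form the base. The *wave-pinning* (WP) motif has a
single GTPase cycling between a slow, membrane-bound active form `u` and a
fast, cytosolic inactive form `v` (diffusion ratio `Dv ≫ 1`), with
interconversion

    f(u, v) = (b + γ·uⁿ/(1 + uⁿ))·v − u,

i.e. basal activation `b`, saturating self-activation with strength `γ` and
Hill exponent `n`, and linear inactivation. The *mutual-inhibition* (MI)
motif has two GTPases whose activation is suppressed by the other's active
form:

    fᵢ(uᵢ, vᵢ, uⱼ) = (bᵢ + γᵢ/(1 + uⱼⁿ))·vᵢ − uᵢ.

Both base models conserve each GTPase's total `T` (mean of `u + v`), and
both robustly polarise: a single cluster survives.

Two modifications allow multiple clusters to coexist stably:

* **Turnover** (WPT, MIT): production `σ` of the inactive form and
  degradation `ξ` of the active form break mass conservation. The
  homogeneous active level is then `σ/ξ` exactly.
* **GAP feedback** (WPGAP, MIGAP1, MIGAP2): a conserved GAP cycle (active
  `G`, inactive `g`, total `Tg`) is activated by the GTPase (`c·u·g`),
  inactivated at rate `d`, and adds an extra GTPase inactivation flux
  `G·u`. Active GAP diffuses at ratio `DG`, inactive at `Dg`.

Model variants, variable counts and conservation properties are tabulated
in `gtpatterns.models`; `make_model` applies the default dimensionless
parameter registry (`b = 0.1`, `γ = 2`, `n = 2`, `c = d = 1`, `Tg = 10`,
`Dv = DG = Dg = 100`) with overrides.

### Choice of the "variable" parameters

The parameter registry marks the total GTPase `T` and the production rate
`σ` as experiment-dependent. Defaults were fixed once as follows:

* WP: `T = 1.43`, the canonical spot-forming value, which sits inside the
  linear-stability Turing window `T ∈ (1.41, 1.77)` at `γ = 2`.
* WPT: `σ = 0.05` with `ξ = 0.1`. The homogeneous active level `σ/ξ` must
  lie in the range where self-activation is sensitive; the Turing window at
  these rates is `σ ∈ (0.030, 0.079)` and the default is its centre. (Note
  that `σ = 0.1`, although convenient for closed-form checks because
  `σ/ξ = 1`, is linearly *stable* and forms no pattern.)
* MIT: `σ₁ = σ₂ = 0.2`, `ξ = 0.1`.
* MI: `T₁ = T₂ = 5` (patterning requires similar amounts of the two
  GTPases); MIGAP1: `T₁ = 20, T₂ = 5` (the GAP-free second GTPase must be
  scarcer); MIGAP2: `T₁ = T₂ = 20`.
* WPGAP: `T = 4.86`, the centre of the fast-GAP LPA Turing interval
  `T ∈ (3.74, 5.98)` at `Tg = 10`.

### Homogeneous steady states

Turnover models have closed-form uniform equilibria (`u = σ/ξ`). The
mass-conserved single-GTPase models reduce to a scalar root problem in `u`
(with `v = T − u` and, for GAP models, the GAP cycle slaved as
`G = c·u·Tg/(d + c·u)`); roots are bracketed on a mixed log/linear grid of
600 points and polished by bisection to ~1e-14. Two-GTPase models reduce to
a 2-D root problem solved by multi-start Newton–hybrid iteration (symmetric
guess plus a 7×7 log-spaced grid of starts), with duplicates merged. All
non-negative roots are reported; the *default* root is the one with the
lowest total active GTPase, i.e. the branch continuously connected to the
low-activity state — the natural background around which noise is applied.
Multiplicity (possible at weak basal activation, e.g. `b = 0.01`) is
surfaced through `HomogeneousState.all_roots`, never hidden.

## Pseudospectral solver

The domain is an open cylinder: periodic in x, zero-flux or periodic in y.
Fields are advanced with an IMEX scheme in transform space: Fourier modes in
x, and in y either Fourier modes (periodic) or a cosine expansion on a
cell-centred grid (type-II DCT), which enforces the zero-flux condition
exactly in the basis. Diffusion is treated implicitly (unconditionally
stable division by `1 + dt·D·k²`), reactions explicitly on the collocation
grid. Two steppers are available: first-order IMEX Euler (default) and a
second-order Crank–Nicolson/Heun combination (`scheme="imex2"`).

Nonlinear reaction terms are evaluated directly on the collocation grid
without dealiasing padding. The reaction terms are rational (not
polynomial) functions, for which zero-padding is inexact anyway; the
one-step solver error against a dense explicit finite-difference oracle is
below 1e-4 relative, and doubling the resolution of a reference coexistence
run leaves the final cluster count unchanged (both asserted in the test
suite), which bounds the aliasing effect at the resolutions used.

Time steps: the implicit diffusion step is unconditionally stable, so `dt`
is limited by the explicit reaction terms (rates of order one, GAP-flux
terms up to ~15 at elevated `Tg`). Production runs use `dt = 0.05` on
tip-growth domains and `dt = 0.1` for the slower panel runs; the library
default is a conservative `dt = 0.01`. On a non-finite blow-up a run is
retried once with the step halved.

**Initial conditions** follow the mass-conserving noise protocol: per pixel,
the active form of each cycle gains `ε ~ N(0, 1e-6)` and its inactive
partner loses exactly the same amount, so per-pixel totals are untouched;
single-cluster protocols inject fresh noise of the same construction every
10 time units. A single integer seed drives all noise in a run.

**Parameter schedules** are applied abruptly: the new parameters take over
the running state, as when restarting a simulation from its final state.
Changing a conserved total (`T`, `Tg`) has no direct term in the equations,
so the material difference is added to (or removed from) the inactive pool
uniformly — delivery and removal act on the cytosolic form.

**Steadiness.** A pattern drifting at constant speed along the periodic
direction is a steady state (any shift of a solution is a solution), so the
steadiness test compares consecutive snapshots after the optimal cyclic
x-shift: steady when the shift-minimised relative L2 change stays below
`tol = 1e-6` across a trailing window of 100 time units (both
configurable); the drift velocity is the optimal shift per unit time.

## Linear stability analysis

The growth rate of a spatial mode `k` about the uniform state is the
eigenvalue spectrum of `J − k²·D`, with `J` the analytic reaction Jacobian
and `D = diag(1, Dv, DG, Dg, …)`. Mass conservation forces a zero
eigenvalue at `k² = 0` (each conserved pair contributes a zero row sum).
Admissible wave numbers of a finite domain are
`k = sqrt((2πp/W)² + (qπ/H)²)` (cosine modes in y under zero flux; `2πq/H`
when periodic). Regime maps label a parameter cell *turing* when some
`k² > 0` on a geometric grid (1e-4…30, covering the order-one unstable
band) carries a positive real part — *turing_hopf* when the dominant
unstable eigenvalue is complex — using dense eigensolves of the ≤ 8×8
matrices; map boundaries can be refined by bisection between differing
neighbour cells.

## Local perturbation analysis

LPA follows a narrow pulse of the slow variables on a uniform background in
the asymptotic limit (slow diffusion → 0, fast diffusion → ∞). Fast
variables are global; each slow variable has a global value and a local
pulse value; the pulse has measure zero, so global equations never see
local variables (a triangular structure asserted in the tests). Mass
conservation fixes fast partners algebraically (`v = T − u_G`); turnover
models keep `v` dynamic. Active GAP is treated in both limits: fast
(`DG → ∞`, global) and slow (`DG → 0`, the pulse carries a local GAP copy);
the MI GAP variants use fast GAP only. Regime labels:

* *turing* — homogeneous equilibrium unstable through a real eigenvalue of
  the local block (a pulse grows: patterns self-nucleate);
* *turing_hopf* — an unstable complex pair is (also) present anywhere in
  the block spectrum (tolerance 1e-9 on the real part guards marginal
  pairs);
* *bistable_het* — homogeneous equilibrium stable, but a *stable*
  equilibrium with pulse level ≠ background exists (patterns persist or can
  be triggered by a finite perturbation). Requiring stability of the
  heterogeneous proxy is a deliberate choice: an unstable proxy marks a
  threshold, not a reachable state;
* *stable* — neither.

Global equilibria coincide with the uniform equilibria of the full model,
so they are taken from the homogeneous-steady-state solver (all roots, not
just the default); local-pulse equilibria are found by sign-change
bracketing (one local variable) or multi-start root finding (two), with the
local GAP copy started from its slaved value. Equilibrium classification
replaces arclength continuation: regime maps are produced by dense grid
classification with bisection-refined boundaries, which yields the same
regime geometry without continuation bookkeeping.

## Cluster-competition ODE models

The simplified models treat each cluster as a compartment with amount
`h_c[n]` ∝ cluster area; recruitment is `α·h_c·h_p`, boundary loss
`β·h_c^η` (η = ½ for circular clusters: circumference ∝ √area) and constant
inactivation `δ·h_c`. The pairwise ratio `r = h_i/h_k` obeys, in the basic
shared-pool model,

    dr/dt = β·h_k^(η−1)·(r − r^η),

positive for `h_i > h_k` whenever `0 < η < 1`: differences always grow and
the largest initial cluster wins. Per-compartment pools add
`α·r·(h_p,i − h_p,k)`; GAP feedback adds `−ε·(G_i·h_k − G_k·h_i)/h_k²`,
and slaving the GAP cycle (fast-GAP quasi-steady state) turns the latter
into an always-equalising term proportional to `ε·Tg` — more GAP, more
coexistence.

Numerics: `solve_ivp`/LSODA at `rtol = 1e-9`, `atol = 1e-11`, with
per-cluster terminal events at an extinction floor of 1e-12. An
extinguished cluster is frozen at zero (its residual material and its GAP
return to the pool, keeping totals exact); the `h^(η−1)` GAP-shedding
factor is defined as 0 at `h = 0` (no cluster, no boundary). This prevents
numerical resurrection of eliminated clusters, whose dynamics are singular
at zero. The five-cluster preset starts at amounts (1, 2, 3, 4, 5) with a
shared pool of 6 (total `T = 21`), `α = β = ε = 1`, `δ = 5`, `η = ½`,
GAP activation and shedding rates `γ = ζ = 10`. The GAP inactivation rate
`δ_g` is not fixed by that preset; the default is `δ_g = 1` and it is an
exposed parameter. The compartment variant exposes both degradation knobs
(`ξ` for clusters, `ξ_p` for pools) separately; with degradation only in
the pools, surviving clusters grow without bound (linearly, at the net
production rate) — the simplified model has no mechanism to stop growth,
unlike the full PDE.

Survivors are counted as clusters whose final amount exceeds 1e-3 of the
largest (threshold exposed); a non-converged trajectory (`max |dh/dt|`
above tolerance at the end) flags its count with a warning.

## Pattern metrics

Cluster counting thresholds a field at `min + level·(max − min)`
(`level = 0.5`; counts of separated clusters are insensitive over
`level ∈ [0.3, 0.7]`, asserted in tests) and labels 8-connected components,
merging across the periodic seam(s) by union–find. Classes: *stripes* when
both phases contain components spanning a full domain direction (bands);
*spots* when the high phase is a minority of isolated components; *gaps*
for the inverse; *homogeneous* below a relative amplitude of 1e-4; *mixed*
otherwise. The 50%-area rule and the wrap rule are operationalisations of
the visual classes. 8-connectivity avoids double-counting diagonal-touching
spots on coarse grids. Oscillation detection linearly detrends a scalar
probe (default: spatial maximum of the first active variable), and reports
an oscillation when the dominant Hann-windowed spectral peak exceeds 5× the
median background and the detrended amplitude exceeds 1e-3 relative.

## Scenario design and problem sizes

All end-to-end runs use desk-scale domains chosen once:

* **Tip growth**: doubly periodic squares as in the single-cluster
  protocol — 19.0×19.0 for WPGAP (96×96 grid) and 31.6×31.6 for WPT —
  sized to hold exactly one cluster; re-noising every 10 time units keeps
  unstable states from lingering.
* **WPGAP operating point**: base `T = 4.0`, inside the fast-GAP LPA
  Turing interval (3.74, 5.98) at `Tg = 10`, in its lower quarter. This
  choice is deliberate: an established cluster survives Tg increases far
  beyond the Turing boundary (it persists while a stable heterogeneous LPA
  state exists), and from the interval centre the required Tg increase for
  cap loss would exceed the ~50% scale of plausible physiological
  regulation. From `T = 4.0` the cap disappears at a +48% Tg increase,
  while leaving the Turing regime already at ~+20% — the cluster outlives
  the Turing regime but dies well before the heterogeneous regime closes
  (beyond +160%).
* **Cap-loss search**: Tg is raised in ×1.05 steps, each held 300 time
  units from the prior final state; the cap counts as gone when the spatial
  maximum of `u` stays below 1.2× the homogeneous level for 50 consecutive
  time units.
* **Pattern panels**: a 65×65 doubly periodic square (96×96 grid), which
  holds a handful of clusters of the coexistence models while the
  mass-conserved models coarsen to a single spot. Panel runs integrate to
  6000 time units with the shift-invariant steadiness early stop. The
  torus rather than the open cylinder is used here deliberately: at the
  WP spot coverage (~0.3, close to the interface-energy break-even 1/π
  between a spot and a band) the no-flux walls pin interfaces and
  kinetically trap single-band end states on desk-scale cylinders, while
  on the torus the droplet coarsening pathway reliably ends in a spot
  (verified across noise seeds). Both geometries are supported by the
  solver; the open cylinder remains the default elsewhere.
* **Turnover series**: `σ` and `ξ` divided by a common factor (fixed
  `σ/ξ`); the integration horizon scales with √factor because the
  redistribution length `sqrt(Dv/ξ)` and the relaxation time both grow as
  turnover slows.

What the desk-scale domains do *not* reproduce: the paper-scale domains
hold dozens of clusters and show the full Ostwald-ripening phenomenology
with long secondary coarsening; on desk-scale open cylinders (~60×60) the
minority-phase coverage of the WP model (~0.3) is close to the
interface-energy break-even between a spot and a band around the cylinder
(coverage 1/π), so the mass-conserved end state can be a single band
instead of a single spot depending on the noise realisation — both are
single-object polarised states (hence the torus panel domain above). Tests on mini domains therefore establish the mechanism contrasts
(one object vs several; ordered class progression; event-driven cluster
regulation), not the quantitative cluster densities of large-domain runs.

## Known limitations

* The cylinder geometry ignores 3-D cytosolic diffusion and realistic cell
  shapes; no moving or growing domains.
* The LPA reductions assume sharp scale separation (`Dv, DG → ∞` or `→ 0`);
  at the finite ratios of the PDEs (100), LSA and LPA regime boundaries
  agree closely but not exactly.
* Only dimensionless parameterisation is supported.
* First-order IMEX time stepping is accurate for steady-state questions;
  transient-sensitive quantities should use `scheme="imex2"` and reduced
  `dt`.
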