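# gtpatterns

Reaction–diffusion and cluster-competition models of small-GTPase membrane
patterning: when does a cell membrane polarise into a **single** cluster of
active GTPase, and what does it take to stabilise the **coexistence** of
several clusters?

Small GTPases (Rho, ROP, Rac, Cdc42, …) are molecular switches that cycle
between a slow-diffusing active membrane-bound form and a fast-diffusing
inactive cytosolic form. Positive feedback on activation plus this
diffusion asymmetry makes them natural pattern formers. The classical
mass-conserved polarisation models — wave pinning (WP, direct
self-activation) and mutual inhibition (MI, two antagonistic GTPases) —
always end in a single cluster: larger clusters drain the shared inactive
pool and starve smaller ones. Many real patterns, however, need several
stable clusters (metaxylem wall pits, pavement-cell lobes, branching fungal
hyphae). `gtpatterns` implements and analyses seven dimensionless models
showing that either of two biologically plausible modifications stabilises
coexistence:

* **turnover** — production of inactive GTPase and degradation of the
  *active* form (WPT, MIT models), or
* **negative feedback** — activation of a GAP by the GTPase cluster itself
  (WPGAP, MIGAP1, MIGAP2 models).

The package is aimed at modellers of cell polarity and membrane patterning
who want a self-contained, tested implementation of these motifs and of
the analyses around them.

## What is inside

| module          | contents |
|-----------------|----------|
| `models`        | the seven dimensionless PDE models: reaction terms, analytic Jacobians, parameter registry, homogeneous steady states, conservation audits |
| `solver`        | 2-D pseudospectral IMEX integrator (periodic x; zero-flux or periodic y), mass-conserving noise protocol, parameter schedules, shift-invariant steadiness detection |
| `stability`     | linear stability analysis: dispersion relations `eig(J − k²D)`, admissible wave numbers, 2-parameter Turing/Hopf regime maps |
| `lpa`           | local perturbation analysis: asymptotic local+global ODE reductions, equilibrium classification, regime maps incl. the bistable-heterogeneous regime |
| `cluster_ode`   | simplified cluster-competition ODE models (shared pool / per-cluster compartments / GAP feedback) with closed-form cluster-size-ratio dynamics and the fast-GAP quasi-steady-state reduction |
| `metrics`       | cluster counting with periodic wrap handling, spots/stripes/gaps classification, oscillation detection |
| `scenarios`     | scripted experiments: pattern panels, turnover series, tip-growth schedules (pulsing, disappearing, splitting caps), minimal-parameter-change search |
| `plotting`      | optional matplotlib helpers: field heatmaps, regime-map rasters |

A thin `gtpatterns` command-line interface wraps the library
(`simulate`, `lsa-map`, `lpa-map`, `ode`, `scenario`).

## The core model

All models share the GTPase cycling backbone (eq. per GTPase *i*):

    ∂u/∂t =  f(u, v) [− ξu] [− G·u] + ∇²u
    ∂v/∂t = −f(u, v) [+ σ]  [+ G·u] + Dv·∇²v

with wave-pinning interconversion `f(u,v) = (b + γuⁿ/(1+uⁿ))v − u` or
mutual-inhibition `fᵢ = (bᵢ + γᵢ/(1+uⱼⁿ))vᵢ − uᵢ`, and optionally a
conserved GAP cycle `∂G/∂t = c·u·g − d·G + DG∇²G` (inactive `g` with
`Dg∇²g`). Bracketed terms belong to the turnover and GAP variants. The
simplified competition models reduce each cluster to an amount `h_c,n`
with recruitment `α·h_c·h_p`, boundary loss `β·h_c^η` (η = ½ for circular
clusters) and inactivation `δ·h_c`; the pairwise size ratio `r = h_i/h_k`
obeys `dr/dt = β·h_k^(η−1)(r − r^η)` — always amplifying differences —
plus variant-specific terms that can reverse the competition.

## Worked example

```python
import numpy as np
from gtpatterns import models, lpa, scenarios

# polarisation vs coexistence on the same 65x65 doubly periodic domain
for model_id, param, value in [("WP", "T", 1.43), ("WPT", "sigma", 0.05)]:
    [summary] = scenarios.run_pattern_panel(model_id, param, [value], seed=1)
    print(model_id, summary.n_clusters_high, summary.pattern_class)

# where does the GAP model pattern? (fast-GAP local perturbation analysis)
sys = lpa.lpa_reduce(models.make_model("WPGAP", {"T": 4.0}), "fast")
print("WPGAP T=4, Tg=10:", lpa.classify_regime(sys))
```

prints

```
WP 1 spots
WPT 2 spots
WPGAP T=4, Tg=10: turing
```

The mass-conserved wave-pinning model coarsens to a **single spot**
(polarisation), while the turnover model supports **two coexisting
clusters** on the very same domain — the polarisation/coexistence contrast
at the heart of the package. The LPA call confirms the GAP-feedback
operating point sits in the Turing regime, where patterns self-nucleate
from noise.

Cluster competition in the simplified ODE models:

```python
from gtpatterns import cluster_ode as co

params, state = co.five_cluster_preset()  # five clusters, amounts 1..5
traj = co.simulate_clusters("basic", state, params, t_end=2000.0)
print(co.surviving_clusters(traj), np.argmax(traj.final_state.h_c))
# -> 1 4      (a single winner: the cluster that started largest)
```

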