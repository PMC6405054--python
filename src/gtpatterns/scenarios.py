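"""Scripted end-to-end experiments: pattern panels, turnover series, tip growth.

These reproduce the characteristic phenomenology of the patterning models at
configurable scale: the polarisation-versus-coexistence contrast between
mass-conserved and turnover/GAP models, the spots-to-stripes-to-gaps
progression with increasing GTPase supply, the loss of coexistence at low
turnover, and schedule-driven regulation of a single GTPase cap (pulsing,
disappearance, splitting) as in tip-growing cells.

Default domains are desk-scale: the 19x19 (WPGAP) and 31.6x31.6 (WPT)
doubly periodic single-cluster domains, and a 65x65 doubly periodic panel
domain that holds a handful of clusters (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gtpatterns import metrics as _metrics
from gtpatterns import models as _models
from gtpatterns import solver as _solver
from gtpatterns.metrics import PatternSummary
from gtpatterns.solver import Grid, Schedule, Trajectory

__all__ = [
    "PANEL_GRID",
    "TIP_GROWTH",
    "panel_grid",
    "tip_growth_grid",
    "run_pattern_panel",
    "run_turnover_series",
    "run_tip_growth",
    "find_min_relative_change",
]

#: pattern-panel domain: a doubly periodic square large enough for several
#: coexisting clusters of the turnover/GAP models while the mass-conserved
#: models coarsen to a single spot.  The torus avoids the wall-induced
#: trapping of metastable bands seen on same-size open cylinders (see
#: docs/methods.md).
PANEL_GRID = dict(W=65.0, H=65.0, nx=96, ny=96, bc_y="periodic")

#: single-cluster (tip) set-ups: doubly periodic squares, base parameters,
#: and the schedule presets used for the pulsing / disappearance / splitting
#: experiments.  The WPGAP base total GTPase T=4.0 sits in the lower quarter
#: of the fast-GAP LPA Turing interval at Tg=10 (see docs/methods.md).
TIP_GROWTH = {
    "WPGAP": dict(
        domain=dict(W=19.0, H=19.0, nx=96, ny=96, bc_y="periodic"),
        base={"T": 4.0, "Tg": 10.0},
        presets={
            # factors applied to the base value of the scheduled parameter;
            # the cap-loss threshold sits near +48% Tg, so the pulse stays
            # below it and the second disappearance step crosses it
            "pulse": [("Tg", 1.25), ("Tg", 1.0)],
            "disappear": [("Tg", 1.35), ("Tg", 1.55), ("Tg", 1.0)],
            "split": [(("T", "Tg"), (2.0, 2.5))],
        },
    ),
    "WPT": dict(
        domain=dict(W=31.6, H=31.6, nx=96, ny=96, bc_y="periodic"),
        base={"sigma": 0.05, "xi": 0.1},
        presets={
            # degradation must rise well past the Turing boundary to kill
            # the cap: clusters persist into the bistable regime
            "pulse": [("xi", 1.5), ("xi", 1.0)],
            "disappear": [("xi", 1.5), ("xi", 2.5), ("xi", 1.0)],
        },
    ),
}

_DEFAULT_DT = 0.05
_PHASE_HOLD = 500.0  # time units per schedule phase (or until steady)
_DISAPPEAR_FACTOR = 1.2  # "cap gone" when max u < factor * homogeneous level
_DISAPPEAR_HOLD = 50.0  # ... for this long


def panel_grid(scale: float = 1.0) -> Grid:
    g = PANEL_GRID
    return Grid(W=g["W"] * scale, H=g["H"] * scale,
                nx=max(32, int(g["nx"] * scale) // 2 * 2),
                ny=max(32, int(g["ny"] * scale) // 2 * 2), bc_y=g["bc_y"])


def tip_growth_grid(model_id: str) -> Grid:
    return Grid(**TIP_GROWTH[model_id]["domain"])


def run_pattern_panel(
    model_id: str,
    parameter: str,
    values,
    grid: Grid | None = None,
    seed: int = 1,
    t_end: float = 6000.0,
    dt: float = 0.1,
    base_overrides: dict | None = None,
) -> list[PatternSummary]:
    """Simulate to (near) steady state for each control-parameter value.

    Returns one :class:`PatternSummary` per value, in input order.  Runs
    that did not settle are flagged by ``drift_velocity = nan``.
    """
    grid = grid or panel_grid()
    out: list[PatternSummary] = []
    for value in values:
        model = _models.make_model(model_id, {**(base_overrides or {}), parameter: value})
        traj = _solver.simulate(
            model, grid, t_end=t_end, dt=dt, snapshot_stride=max(t_end / 30, 1.0),
            seed=seed, stop_when_steady=True,
            steady_window=t_end / 10, steady_tol=1e-6,
        )
        u = traj.final_state.fields[model.variables[0]]
        summary = _metrics.classify_pattern(u, grid)
        if not traj.steady_reached:
            summary.drift_velocity = float("nan")
        out.append(summary)
    return out


def run_turnover_series(
    factors,
    grid: Grid | None = None,
    seed: int = 1,
    base_sigma: float = 0.05,
    base_xi: float = 0.1,
    dt: float = 0.1,
) -> list[int]:
    """Steady-state cluster counts of the WPT model at reduced turnover.

    Production and degradation are divided by each factor (their ratio, the
    homogeneous active level, stays fixed); ``factor=inf`` runs the
    mass-conservation limit: the WP model at the WPT total concentration.
    Slower turnover needs proportionally longer to settle, so the
    integration horizon scales with the factor.
    """
    grid = grid or panel_grid()
    counts: list[int] = []
    for factor in factors:
        if factor < 1:
            raise ValueError("turnover reduction factors must be >= 1")
        if np.isinf(factor):
            wpt = _models.make_model("WPT", {"sigma": base_sigma, "xi": base_xi})
            hss = _models.homogeneous_steady_state(wpt).values
            model = _models.make_model("WP", {"T": hss["u"] + hss["v"]})
            t_end = 20000.0
        else:
            model = _models.make_model(
                "WPT", {"sigma": base_sigma / factor, "xi": base_xi / factor}
            )
            t_end = min(6000.0 * factor ** 0.25, 20000.0)
        traj = _solver.simulate(
            model, grid, t_end=t_end, dt=dt, snapshot_stride=t_end / 30,
            seed=seed, stop_when_steady=True, steady_window=t_end / 10,
            steady_tol=1e-6,
        )
        u = traj.final_state.fields["u"]
        counts.append(_metrics.count_clusters(u, grid))
    return counts


@dataclass
class TipGrowthResult:
    trajectory: Trajectory
    events: list[dict] = field(default_factory=list)

    def cluster_counts(self) -> list[int]:
        return [e["n_clusters"] for e in self.events]


def _establish_single_cluster(
    model_id: str, seed: int, dt: float, t_end: float = 500.0,
    extra_overrides: dict | None = None,
):
    conf = TIP_GROWTH[model_id]
    grid = tip_growth_grid(model_id)
    model = _models.make_model(model_id, {**conf["base"], **(extra_overrides or {})})
    schedule = Schedule(noise_interval=10.0, noise_sd=1e-6)
    traj = _solver.simulate(
        model, grid, t_end=t_end, dt=dt, schedule=schedule,
        snapshot_stride=25.0, seed=seed,
    )
    return model, grid, schedule, traj


def _cap_present(state, model, grid) -> bool:
    hss = _models.homogeneous_steady_state(model).values
    u_name = model.variables[0]
    return bool(state.fields[u_name].max() >= _DISAPPEAR_FACTOR * hss[u_name])


def run_tip_growth(
    model_id: str,
    preset: str,
    seed: int = 1,
    dt: float = _DEFAULT_DT,
    phase_hold: float = _PHASE_HOLD,
) -> TipGrowthResult:
    """Run a scheduled single-cluster experiment on the tip domain.

    Establishes a single cluster at base parameters, then applies the
    preset's parameter factors phase by phase (each held for ``phase_hold``
    time units with continued re-noising), logging cluster count and cap
    presence after every phase.
    """
    conf = TIP_GROWTH[model_id]
    if preset not in conf["presets"]:
        raise ValueError(f"unknown preset {preset!r} for {model_id}")
    model, grid, schedule, traj = _establish_single_cluster(model_id, seed, dt)
    state = traj.final_state
    events = [{
        "phase": "base", "t": traj.times[-1], "params": dict(model.params),
        "n_clusters": _metrics.count_clusters(state.fields[model.variables[0]], grid),
        "cap_present": _cap_present(state, model, grid),
    }]
    all_times = list(traj.times)
    all_states = list(traj.states)
    base_params = dict(model.params)
    current = model
    t_offset = traj.times[-1]
    for phase_idx, (names, factors) in enumerate(conf["presets"][preset]):
        if isinstance(names, str):
            names, factors = (names,), (factors,)
        overrides = {nm: base_params[nm] * fac for nm, fac in zip(names, factors)}
        new_model = current.with_overrides(overrides)
        st = state.copy()
        _solver._apply_total_change(current, new_model, st)
        st.t = 0.0
        current = new_model
        ph = _solver.simulate(
            current, grid, t_end=phase_hold, dt=dt, schedule=schedule,
            snapshot_stride=10.0, seed=seed + 1000 * (phase_idx + 1),
            initial_state=st,
        )
        state = ph.final_state
        all_times.extend(t_offset + np.asarray(ph.times[1:]))
        all_states.extend(ph.states[1:])
        t_offset += ph.times[-1]
        label = ", ".join(f"{nm} x{fac:g}" for nm, fac in zip(names, factors))
        events.append({
            "phase": label, "t": t_offset,
            "params": dict(current.params),
            "n_clusters": _metrics.count_clusters(
                state.fields[current.variables[0]], grid),
            "cap_present": _cap_present(state, current, grid),
        })
    full = Trajectory(
        times=all_times, states=all_states, model_id=model_id,
        params=dict(current.params), grid=grid, seed=seed,
    )
    return TipGrowthResult(trajectory=full, events=events)


def find_min_relative_change(
    model_id: str = "WPGAP",
    parameter: str = "Tg",
    goal: str = "disappear",
    step: float = 0.05,
    direction: str = "increase",
    seed: int = 1,
    dt: float = _DEFAULT_DT,
    phase_hold: float = 300.0,
    max_change: float = 2.0,
) -> dict:
    """Smallest relative parameter change that destroys an established cap.

    Starting from a single-cluster steady state at the tip-growth base
    parameters, the parameter is changed in multiplicative steps of
    ``1 + step`` (each phase re-simulated from the prior final state).  The
    cap counts as *disappeared* when the spatial maximum of active GTPase
    stays below ``1.2x`` its homogeneous level for 50 consecutive time
    units; *shrink* requires the maximum to drop by 25% from its base value.

    Returns the achieved relative change as a fraction (e.g. ``0.477``), or
    ``inf`` if the goal is not reached within ``max_change``.
    """
    if goal not in ("shrink", "disappear"):
        raise ValueError("goal must be 'shrink' or 'disappear'")
    model, grid, schedule, traj = _establish_single_cluster(model_id, seed, dt)
    state = traj.final_state
    u_name = model.variables[0]
    base_value = model.params[parameter]
    base_max = state.fields[u_name].max()
    factor = (1.0 + step) if direction == "increase" else 1.0 / (1.0 + step)
    current = model
    k = 0
    while True:
        k += 1
        value = base_value * factor ** k
        rel_change = abs(value - base_value) / base_value
        if rel_change > max_change + 1e-9:
            return {"achieved": False, "relative_change": float("inf"),
                    "steps": k - 1, "parameter": parameter}
        new_model = current.with_overrides({parameter: value})
        st = state.copy()
        _solver._apply_total_change(current, new_model, st)
        st.t = 0.0
        current = new_model
        ph = _solver.simulate(
            current, grid, t_end=phase_hold, dt=dt, schedule=schedule,
            snapshot_stride=10.0, seed=seed + 100 * k, initial_state=st,
        )
        state = ph.final_state
        hss_u = _models.homogeneous_steady_state(current).values[u_name]
        tail = [s.fields[u_name].max() for s in ph.states
                if s.t >= ph.times[-1] - _DISAPPEAR_HOLD]
        gone = all(v < _DISAPPEAR_FACTOR * hss_u for v in tail)
        shrunk = state.fields[u_name].max() < 0.75 * base_max
        hit = gone if goal == "disappear" else (shrunk or gone)
        if hit:
            return {"achieved": True, "relative_change": float(rel_change),
                    "steps": k, "parameter": parameter,
                    "final_value": float(value)}
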