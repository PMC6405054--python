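"""Pseudospectral IMEX integration of the patterning models on a 2-D domain.

The domain is an open cylinder: periodic in x, and either zero-flux
(cosine expansion on a cell-centred grid) or periodic in y.  Diffusion is
treated implicitly in transform space, reactions explicitly on the
collocation grid -- a first-order IMEX Euler step by default, or a
second-order Crank--Nicolson/Heun combination (``scheme="imex2"``).

Initial conditions follow the mass-conserving noise protocol: every active
variable receives i.i.d. Gaussian noise per pixel and its paired inactive
variable the exact negative, so per-pixel totals are untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from gtpatterns import models as _models
from gtpatterns.models import ModelSpec

__all__ = [
    "Grid",
    "FieldState",
    "Schedule",
    "Trajectory",
    "initial_condition",
    "step",
    "simulate",
    "detect_steady_state",
]


@dataclass(frozen=True)
class Grid:
    """Rectangular domain: x periodic with extent ``W``, y of extent ``H``."""

    W: float
    H: float
    nx: int
    ny: int
    bc_y: str = "noflux"

    def __post_init__(self):
        if self.W <= 0 or self.H <= 0:
            raise ValueError("domain extents must be positive")
        if self.nx < 16 or self.ny < 16 or self.nx % 2 or self.ny % 2:
            raise ValueError("nx and ny must be even and >= 16")
        if self.bc_y not in ("noflux", "periodic"):
            raise ValueError("bc_y must be 'noflux' or 'periodic'")
        ratio = (self.W / self.nx) / (self.H / self.ny)
        if not 0.5 <= ratio <= 2.0:
            warnings.warn(
                f"grid spacings differ by more than 2x (dx/dy = {ratio:.3g})",
                stacklevel=2,
            )

    @property
    def dx(self) -> float:
        return self.W / self.nx

    @property
    def dy(self) -> float:
        return self.H / self.ny

    @property
    def x(self) -> np.ndarray:
        return self.W * np.arange(self.nx) / self.nx

    @property
    def y(self) -> np.ndarray:
        if self.bc_y == "noflux":  # cell-centred for the cosine basis
            return (np.arange(self.ny) + 0.5) * self.dy
        return self.H * np.arange(self.ny) / self.ny

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)


@dataclass
class FieldState:
    """Concentration fields for every model variable at one time point."""

    t: float
    fields: dict[str, np.ndarray]

    def copy(self) -> "FieldState":
        return FieldState(self.t, {k: v.copy() for k, v in self.fields.items()})

    def __getitem__(self, key: str) -> np.ndarray:
        return self.fields[key]


@dataclass
class Schedule:
    """Piecewise-constant parameter overrides plus periodic re-noising.

    ``changes`` is an ordered list of ``(t_start, overrides)``; each override
    is applied abruptly, re-using the running state as initial condition.
    If ``noise_interval`` is set, fresh mass-conserving noise of standard
    deviation ``noise_sd`` is injected at that interval.
    """

    changes: list[tuple[float, dict[str, float]]] = field(default_factory=list)
    noise_interval: float | None = None
    noise_sd: float = 1e-6

    def __post_init__(self):
        times = [t for t, _ in self.changes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("schedule times must be strictly increasing")


@dataclass
class Trajectory:
    """Snapshots of a simulation at a fixed stride, plus run metadata."""

    times: list[float]
    states: list[FieldState]
    model_id: str
    params: dict[str, float]
    grid: Grid
    seed: int | None = None
    schedule: Schedule | None = None
    steady_reached: bool = False
    param_history: list[tuple[float, dict[str, float]]] = field(default_factory=list)

    @property
    def final_state(self) -> FieldState:
        return self.states[-1]

    def field_series(self, var: str) -> np.ndarray:
        return np.stack([s.fields[var] for s in self.states])

    def save(self, path) -> None:
        """Persist as HDF5: one (time, y, x) array per variable + attributes."""
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("t", data=np.asarray(self.times))
            for var in self.states[0].fields:
                fh.create_dataset(var, data=self.field_series(var))
            fh.attrs["model_id"] = self.model_id
            for k, v in self.params.items():
                fh.attrs[f"param_{k}"] = v
            for k in ("W", "H", "nx", "ny"):
                fh.attrs[k] = getattr(self.grid, k)
            fh.attrs["bc_y"] = self.grid.bc_y
            if self.seed is not None:
                fh.attrs["seed"] = self.seed
            fh.attrs["steady_reached"] = self.steady_reached

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            times = [float(t) for t in fh["t"][...]]
            varnames = [k for k in fh.keys() if k != "t"]
            arrays = {v: fh[v][...] for v in varnames}
            params = {
                k[len("param_"):]: float(v)
                for k, v in fh.attrs.items() if k.startswith("param_")
            }
            grid = Grid(
                W=float(fh.attrs["W"]), H=float(fh.attrs["H"]),
                nx=int(fh.attrs["nx"]), ny=int(fh.attrs["ny"]),
                bc_y=str(fh.attrs["bc_y"]),
            )
            states = [
                FieldState(t, {v: arrays[v][i] for v in varnames})
                for i, t in enumerate(times)
            ]
            return cls(
                times=times, states=states,
                model_id=str(fh.attrs["model_id"]), params=params, grid=grid,
                seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
                steady_reached=bool(fh.attrs.get("steady_reached", False)),
            )


# ---------------------------------------------------------------------------
# spectral machinery
# ---------------------------------------------------------------------------

class _Spectral:
    """Forward/inverse transforms and Laplacian symbols for one grid."""

    def __init__(self, grid: Grid):
        self.grid = grid
        kx = 2.0 * np.pi * np.fft.rfftfreq(grid.nx, d=grid.dx)
        if grid.bc_y == "periodic":
            ky = 2.0 * np.pi * np.fft.fftfreq(grid.ny, d=grid.dy)
        else:
            ky = np.pi * np.arange(grid.ny) / grid.H
        self.k2 = ky[:, None] ** 2 + kx[None, :] ** 2

    def fwd(self, a: np.ndarray) -> np.ndarray:
        if self.grid.bc_y == "periodic":
            return sfft.rfft2(a, axes=(-2, -1))
        return sfft.rfft(sfft.dct(a, type=2, axis=-2, norm="ortho"), axis=-1)

    def inv(self, ah: np.ndarray) -> np.ndarray:
        if self.grid.bc_y == "periodic":
            return sfft.irfft2(ah, s=self.grid.shape, axes=(-2, -1))
        return sfft.idct(
            sfft.irfft(ah, n=self.grid.nx, axis=-1), type=2, axis=-2, norm="ortho"
        )


def _stack(model: ModelSpec, state: FieldState) -> np.ndarray:
    return np.stack([state.fields[v] for v in model.variables])


def _unstack(model: ModelSpec, A: np.ndarray, t: float) -> FieldState:
    return FieldState(t, {v: A[i] for i, v in enumerate(model.variables)})


def _rates_stacked(model: ModelSpec, A: np.ndarray) -> np.ndarray:
    point = {v: A[i] for i, v in enumerate(model.variables)}
    rates = model.reaction_terms(point)
    return np.stack([rates[v] for v in model.variables])


def _advance(model, sp: _Spectral, A: np.ndarray, dt: float, scheme: str) -> np.ndarray:
    """One IMEX step on the stacked field array (nvar, ny, nx)."""
    D = np.array([model.diffusion_coeffs()[v] for v in model.variables])
    Dk2 = D[:, None, None] * sp.k2[None, :, :]
    Ah = sp.fwd(A)
    R = _rates_stacked(model, A)
    Rh = sp.fwd(R)
    if scheme == "imex1":
        return sp.inv((Ah + dt * Rh) / (1.0 + dt * Dk2))
    if scheme == "imex2":  # CN diffusion + Heun reaction
        A1 = sp.inv((Ah + dt * Rh) / (1.0 + dt * Dk2))
        R1h = sp.fwd(_rates_stacked(model, A1))
        return sp.inv(
            ((1.0 - 0.5 * dt * Dk2) * Ah + 0.5 * dt * (Rh + R1h)) / (1.0 + 0.5 * dt * Dk2)
        )
    raise ValueError(f"unknown scheme {scheme!r}")


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def _paired_noise(model: ModelSpec, shape, rng, sd: float) -> dict[str, np.ndarray]:
    """Mass-conserving perturbation: +eps on each active form, -eps on its pair."""
    eps: dict[str, np.ndarray] = {}
    single = model.n_gtpases == 1
    for i in range(1, model.n_gtpases + 1):
        e = rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)
        eps["u" if single else f"u{i}"] = e
        eps["v" if single else f"v{i}"] = -e
    for gi in model.gap_targets:
        e = rng.normal(0.0, sd, shape) if sd > 0 else np.zeros(shape)
        eps["G" if single else f"G{gi}"] = e
        eps["g" if single else f"g{gi}"] = -e
    return eps


def initial_condition(
    model: ModelSpec, grid: Grid, noise_sd: float = 1e-6,
    seed: int | np.random.Generator | None = 0,
) -> FieldState:
    """Homogeneous steady state plus per-pixel mass-conserving noise.

    The noise emulates random local interconversion between active and
    inactive forms: per pixel the active form gains ``eps ~ N(0, noise_sd)``
    and the paired inactive form loses exactly the same amount.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    hss = _models.homogeneous_steady_state(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = _paired_noise(model, grid.shape, rng, noise_sd)
    fields = {
        v: np.full(grid.shape, hss.values[v], dtype=float) + eps[v]
        for v in model.variables
    }
    return FieldState(0.0, fields)


def step(
    model: ModelSpec, grid: Grid, state: FieldState, dt: float,
    scheme: str = "imex1", _sp: _Spectral | None = None,
) -> FieldState:
    """Advance one time step; raises on non-finite fields."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    sp = _sp or _Spectral(grid)
    A = _advance(model, sp, _stack(model, state), dt, scheme)
    if not np.all(np.isfinite(A)):
        raise FloatingPointError(
            f"non-finite field values after step at t={state.t} (dt={dt})"
        )
    return _unstack(model, A, state.t + dt)


def _min_shift_l2(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """min over cyclic x-shifts of ||shift(a) - b||, and the argmin shift."""
    fa = np.fft.rfft(a, axis=1)
    fb = np.fft.rfft(b, axis=1)
    corr = np.fft.irfft(fb * np.conj(fa), n=a.shape[1], axis=1).sum(axis=0)
    s = int(np.argmax(corr))
    d2 = float((a * a).sum() + (b * b).sum() - 2.0 * corr[s])
    return np.sqrt(max(d2, 0.0)), s


def detect_steady_state(
    traj: Trajectory, window: float = 100.0, tol: float = 1e-6,
    var: str | None = None,
) -> dict:
    """Decide steadiness of the trailing ``window`` of a trajectory.

    A pattern drifting at constant speed along the periodic direction counts
    as steady: each consecutive snapshot pair is compared after the optimal
    cyclic x-shift, and the drift velocity is estimated from that shift.
    """
    if len(traj.times) < 3:
        raise ValueError("need at least 3 snapshots")
    t_end = traj.times[-1]
    idx = [i for i, t in enumerate(traj.times) if t >= t_end - window]
    if len(idx) < 2:
        raise ValueError("window contains fewer than 2 snapshots")
    var = var or next(iter(traj.states[0].fields))
    grid = traj.grid
    rels, vels = [], []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        a = traj.states[i0].fields[var]
        b = traj.states[i1].fields[var]
        dist, s = _min_shift_l2(a, b)
        norm = np.sqrt((a * a).sum())
        rels.append(dist / norm if norm > 0 else 0.0)
        if s > grid.nx // 2:
            s -= grid.nx
        dt_pair = traj.times[i1] - traj.times[i0]
        vels.append(s * grid.dx / dt_pair if dt_pair > 0 else 0.0)
    steady = bool(np.max(rels) < tol)
    return {
        "steady": steady,
        "drift_velocity": float(np.mean(vels)) if steady else 0.0,
        "max_rel_change": float(np.max(rels)),
    }


_CONSERVED_TOTAL_KEYS = {
    "T": "v", "T_1": "v1", "T_2": "v2",
    "Tg": "g", "Tg_1": "g1", "Tg_2": "g2",
}


def _apply_total_change(model, new_model, state: FieldState) -> None:
    """Changing a conserved total adds/removes material uniformly from the
    inactive pool (delivery and removal act on the cytosolic form)."""
    for key, var in _CONSERVED_TOTAL_KEYS.items():
        if key in model.params and var in state.fields:
            delta = new_model.params[key] - model.params[key]
            if delta != 0.0:
                state.fields[var] = np.maximum(state.fields[var] + delta, 0.0)


def simulate(
    model: ModelSpec,
    grid: Grid,
    t_end: float,
    dt: float = 0.01,
    schedule: Schedule | None = None,
    snapshot_stride: float | None = None,
    seed: int | None = 0,
    scheme: str = "imex1",
    initial_state: FieldState | None = None,
    stop_when_steady: bool = False,
    steady_window: float = 100.0,
    steady_tol: float = 1e-6,
    _retry: bool = True,
) -> Trajectory:
    """Integrate from noisy homogeneous initial conditions to ``t_end``.

    Parameter overrides in ``schedule`` are applied abruptly at their start
    times (the running state carries over); changes to a conserved total
    adjust the inactive pool uniformly.  If ``schedule.noise_interval`` is
    set, fresh mass-conserving noise is injected periodically.  On a
    non-finite blow-up the run is retried once with ``dt/2``.

    With ``stop_when_steady``, integration halts early once the trailing
    ``steady_window`` passes the shift-invariant steadiness test.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    schedule = schedule or Schedule()
    for _, ov in schedule.changes:  # validate before starting
        _models._expand_overrides(model.model_id, ov)
    rng = np.random.default_rng(seed)
    if initial_state is None:
        state = initial_condition(model, grid, schedule.noise_sd, rng)
    else:
        state = initial_state.copy()
    if snapshot_stride is None:
        snapshot_stride = max(t_end / 100.0, dt)

    sp = _Spectral(grid)
    current = model
    t = state.t
    t0 = t
    times = [t]
    states = [state.copy()]
    param_history = [(t, dict(current.params))]
    pending = list(schedule.changes)
    next_noise = (
        t + schedule.noise_interval if schedule.noise_interval else np.inf
    )
    next_snap = t + snapshot_stride
    steady_reached = False
    A = _stack(current, state)

    try:
        while t < t_end - 1e-12:
            if pending and t >= pending[0][0] - 1e-12:
                _, overrides = pending.pop(0)
                new_model = current.with_overrides(overrides)
                st = _unstack(current, A, t)
                _apply_total_change(current, new_model, st)
                current = new_model
                A = _stack(current, st)
                param_history.append((t, dict(current.params)))
            if t >= next_noise - 1e-12:
                eps = _paired_noise(current, grid.shape, rng, schedule.noise_sd)
                for i, v in enumerate(current.variables):
                    A[i] += eps[v]
                next_noise += schedule.noise_interval
            h = min(dt, t_end - t)
            if pending:
                h = min(h, max(pending[0][0] - t, dt * 1e-3))
            if np.isfinite(next_noise):
                h = min(h, max(next_noise - t, dt * 1e-3))
            A = _advance(current, sp, A, h, scheme)
            t += h
            if not np.all(np.isfinite(A)):
                raise FloatingPointError(f"blow-up at t={t}")
            if t >= next_snap - 1e-12 or t >= t_end - 1e-12:
                times.append(t)
                states.append(_unstack(current, A.copy(), t))
                next_snap += snapshot_stride
                if stop_when_steady and times[-1] - t0 >= steady_window:
                    probe = Trajectory(times, states, current.model_id,
                                       dict(current.params), grid)
                    try:
                        res = detect_steady_state(
                            probe, window=steady_window, tol=steady_tol
                        )
                    except ValueError:
                        res = {"steady": False}
                    if res["steady"]:
                        steady_reached = True
                        break
    except FloatingPointError:
        if _retry:
            return simulate(
                model, grid, t_end, dt / 2.0, schedule, snapshot_stride, seed,
                scheme, initial_state, stop_when_steady, steady_window,
                steady_tol, _retry=False,
            )
        raise

    if not steady_reached and len(times) >= 3:
        try:
            res = detect_steady_state(
                Trajectory(times, states, current.model_id, dict(current.params), grid),
                window=steady_window, tol=steady_tol,
            )
            steady_reached = bool(res["steady"])
        except ValueError:
            steady_reached = False

    return Trajectory(
        times=times, states=states, model_id=current.model_id,
        params=dict(current.params), grid=grid, seed=seed, schedule=schedule,
        steady_reached=steady_reached, param_history=param_history,
    )
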