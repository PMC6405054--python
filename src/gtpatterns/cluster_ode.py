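"""Simplified cluster-competition ODE models.

Each active-GTPase cluster is a well-mixed compartment holding an amount
``h_c[n]`` (proportional to cluster area); inactive GTPase lives in a shared
pool ``h_p`` or in per-cluster local pools ``h_p[n]``.  Clusters recruit in
proportion to their amount (``alpha*h_c*h_p``), lose material across their
circumference (``beta*h_c**eta``, with ``eta = 1/2`` for circular clusters)
and through constant inactivation (``delta*h_c``).

Three variants:

* *basic* -- shared pool, mass conserved.  The pairwise size-ratio obeys
  ``d(h_i/h_k)/dt = beta*h_k**(eta-1) * (r - r**eta)`` with ``r = h_i/h_k``,
  which is positive whenever ``h_i > h_k`` for any ``0 < eta < 1``: size
  differences always grow and the initially largest cluster wins.
* *compartment* -- per-cluster pools with all-to-all exchange ``phi`` and
  optional turnover (production ``sigma``, degradation ``xi`` of cluster
  GTPase and ``xi_p`` of pool GTPase).  The ratio equation gains the term
  ``alpha*r*(h_p[i] - h_p[k])``, so local pool depletion feeds back.
* *gap* -- shared pool plus per-cluster active GAP recruited by the cluster
  (``gamma_g*h_c*G_p``), inactivated at ``delta_g`` and lost across the
  circumference at ``zeta*h_c**(eta-1)*G_c``; GAP inactivates cluster GTPase
  at rate ``epsilon*G_c``.  The ratio equation gains a term that punishes
  the larger cluster, enabling stable coexistence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "ClusterParams",
    "ClusterState",
    "ClusterTrajectory",
    "five_cluster_preset",
    "basic_rhs",
    "compartment_rhs",
    "gap_rhs",
    "simulate_clusters",
    "ratio_rate",
    "gap_qss_ratio_rate",
    "surviving_clusters",
]

_EXTINCT = 1e-12


@dataclass(frozen=True)
class ClusterParams:
    """Rates and totals of the cluster-competition models (all dimensionless)."""

    alpha: float = 1.0      # self-activation (recruitment) rate
    beta: float = 1.0       # boundary loss rate (per circumference)
    delta: float = 5.0      # constant inactivation rate
    eta: float = 0.5        # circumference exponent; 1/2 for circular clusters
    sigma: float = 0.0      # production rate (compartment variant)
    xi: float = 0.0         # degradation of cluster (active) GTPase
    xi_p: float = 0.0       # degradation of pool (inactive) GTPase
    phi: float = 0.0        # inter-compartment exchange rate
    gamma_g: float = 10.0   # GTPase-dependent GAP activation rate
    delta_g: float = 1.0    # constant GAP inactivation rate
    zeta: float = 10.0      # GAP boundary-loss rate
    epsilon: float = 1.0    # GAP-dependent GTPase inactivation rate

    def __post_init__(self):
        if not 0.0 < self.eta < 1.0:
            raise ValueError("eta must lie strictly between 0 and 1")
        for name in ("alpha", "beta", "delta", "sigma", "xi", "xi_p", "phi",
                     "gamma_g", "delta_g", "zeta", "epsilon"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ClusterState:
    """Amounts per cluster and per pool; shapes select the model variant."""

    h_c: np.ndarray                  # per-cluster active GTPase
    h_p: float | np.ndarray = 0.0    # shared pool (scalar) or per-compartment pools
    G_c: np.ndarray | None = None    # per-cluster active GAP
    G_p: float = 0.0                 # shared inactive-GAP pool

    def __post_init__(self):
        self.h_c = np.asarray(self.h_c, dtype=float)
        if np.any(self.h_c < 0) or np.any(np.asarray(self.h_p) < 0):
            raise ValueError("amounts must be non-negative")
        if self.G_c is not None:
            self.G_c = np.asarray(self.G_c, dtype=float)
            if np.any(self.G_c < 0) or self.G_p < 0:
                raise ValueError("GAP amounts must be non-negative")

    @property
    def total_gtpase(self) -> float:
        return float(self.h_c.sum() + np.sum(self.h_p))

    @property
    def total_gap(self) -> float:
        g = 0.0 if self.G_c is None else float(self.G_c.sum())
        return g + self.G_p


def five_cluster_preset() -> tuple[ClusterParams, ClusterState]:
    """The five-cluster competition preset: starts (1..5), shared pool 6.

    alpha, beta and epsilon are scaled out to 1; delta=5, eta=1/2,
    gamma_g=zeta=10 (total GTPase T=21).  The GAP inactivation rate
    delta_g defaults to 1 (an exposed choice, see docs/methods.md).
    """
    params = ClusterParams()
    state = ClusterState(h_c=np.array([1.0, 2.0, 3.0, 4.0, 5.0]), h_p=6.0)
    return params, state


def _pow_eta(h: np.ndarray, eta: float) -> np.ndarray:
    return np.where(h > 0, np.power(np.maximum(h, 0.0), eta), 0.0)


def _pow_eta_m1(h: np.ndarray, eta: float) -> np.ndarray:
    """h**(eta-1), defined as 0 for empty clusters (no boundary, no loss)."""
    return np.where(h > _EXTINCT, np.power(np.maximum(h, _EXTINCT), eta - 1.0), 0.0)


def basic_rhs(state: ClusterState, params: ClusterParams):
    """Shared-pool mass-conserved competition; derivatives sum to zero exactly."""
    h, p = state.h_c, float(np.asarray(state.h_p))
    if np.any(h < 0) or p < 0:
        raise ValueError("negative amounts")
    gain = params.alpha * h * p
    loss = params.beta * _pow_eta(h, params.eta) + params.delta * h
    dh = gain - loss
    dp = -(gain.sum()) + loss.sum()
    return dh, dp


def compartment_rhs(state: ClusterState, params: ClusterParams):
    """Per-compartment pools with all-to-all exchange and optional turnover."""
    h = state.h_c
    p = np.asarray(state.h_p, dtype=float)
    if p.shape != h.shape:
        raise ValueError("compartment variant needs one pool per cluster")
    if np.any(h < 0) or np.any(p < 0):
        raise ValueError("negative amounts")
    gain = params.alpha * h * p
    loss = params.beta * _pow_eta(h, params.eta) + params.delta * h
    dh = gain - loss - params.xi * h
    exchange = params.phi * (p.sum() - p.size * p)
    dp = params.sigma - gain + loss - params.xi_p * p + exchange
    return dh, dp


def gap_rhs(state: ClusterState, params: ClusterParams):
    """Shared-pool competition with per-cluster GAP feedback.

    GAP boundary loss follows ``zeta * h**(eta-1) * G_c``: smaller clusters
    shed their GAP faster per unit (amount-based form of a circumference-
    to-area ratio).  GTPase and GAP totals are conserved by construction.
    """
    h, p = state.h_c, float(np.asarray(state.h_p))
    if state.G_c is None:
        raise ValueError("gap variant needs GAP amounts")
    G, Gp = state.G_c, state.G_p
    if np.any(h < 0) or p < 0 or np.any(G < 0) or Gp < 0:
        raise ValueError("negative amounts")
    gain = params.alpha * h * p
    loss = params.beta * _pow_eta(h, params.eta) + params.delta * h
    gap_kill = params.epsilon * G
    dh = gain - loss - gap_kill
    dp = -gain.sum() + loss.sum() + gap_kill.sum()
    g_gain = params.gamma_g * h * Gp
    g_loss = params.delta_g * G + params.zeta * _pow_eta_m1(h, params.eta) * G
    dG = g_gain - g_loss
    dGp = -g_gain.sum() + g_loss.sum()
    return dh, dp, dG, dGp


def ratio_rate(h_i: float, h_k: float, params: ClusterParams,
               h_p_i: float | None = None, h_p_k: float | None = None,
               G_i: float | None = None, G_k: float | None = None) -> float:
    """Closed-form rate of change of the cluster-size ratio ``h_i/h_k``.

    With no extras this is the basic-model form
    ``beta*h_k**(eta-1)*(r - r**eta)``; passing local pools adds
    ``alpha*r*(h_p_i - h_p_k)`` (compartment variant); passing GAP amounts
    adds ``-epsilon*(G_i*h_k - G_k*h_i)/h_k**2`` (GAP variant).
    """
    if h_k <= 0:
        raise ValueError("reference cluster must be positive")
    r = h_i / h_k
    rate = params.beta * h_k ** (params.eta - 1.0) * (r - r ** params.eta)
    if (h_p_i is None) != (h_p_k is None):
        raise ValueError("supply both local pools or neither")
    if h_p_i is not None:
        rate += params.alpha * r * (h_p_i - h_p_k)
    if (G_i is None) != (G_k is None):
        raise ValueError("supply both GAP amounts or neither")
    if G_i is not None:
        rate -= params.epsilon * (G_i * h_k - G_k * h_i) / h_k ** 2
    return float(rate)


def gap_qss_ratio_rate(h: np.ndarray, i: int, k: int, params: ClusterParams,
                       Tg: float) -> float:
    """Ratio rate with GAP slaved to cluster sizes (fast-GAP quasi-steady state).

    Eliminating the GAP amounts through their steady state yields a
    competition term (identical to the basic form) plus a coexistence term
    proportional to ``epsilon*Tg`` that always shrinks size differences.
    """
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("all cluster amounts must be positive")
    hi, hk = h[i], h[k]
    r = hi / hk
    first = params.beta * hk ** (params.eta - 1.0) * (r - r ** params.eta)
    dg_over_z = params.delta_g / params.zeta
    w = h ** (params.eta - 1.0) + dg_over_z
    denom = params.zeta / params.gamma_g + np.sum(h / w)
    second = params.epsilon * Tg * r * (1.0 / w[i] - 1.0 / w[k]) / denom
    return float(first - second)


def _pack(state: ClusterState, variant: str) -> np.ndarray:
    if variant == "basic":
        return np.concatenate([state.h_c, [float(np.asarray(state.h_p))]])
    if variant == "compartment":
        return np.concatenate([state.h_c, np.asarray(state.h_p, float)])
    if variant == "gap":
        return np.concatenate([
            state.h_c, [float(np.asarray(state.h_p))], state.G_c, [state.G_p]
        ])
    raise ValueError(f"unknown variant {variant!r}")


def _unpack(y: np.ndarray, n: int, variant: str) -> ClusterState:
    y = np.maximum(y, 0.0)
    if variant == "basic":
        return ClusterState(h_c=y[:n], h_p=float(y[n]))
    if variant == "compartment":
        return ClusterState(h_c=y[:n], h_p=y[n:2 * n])
    return ClusterState(h_c=y[:n], h_p=float(y[n]),
                        G_c=y[n + 1:2 * n + 1], G_p=float(y[2 * n + 1]))


@dataclass
class ClusterTrajectory:
    times: np.ndarray
    states: list[ClusterState]
    variant: str
    params: ClusterParams
    converged: bool

    @property
    def final_state(self) -> ClusterState:
        return self.states[-1]

    def h_c_series(self) -> np.ndarray:
        return np.stack([s.h_c for s in self.states])


def simulate_clusters(
    variant: str,
    init: ClusterState,
    params: ClusterParams,
    t_end: float,
    n_out: int = 400,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> ClusterTrajectory:
    """Integrate a cluster-competition variant with extinction handling.

    When a cluster's amount crosses the extinction floor it is frozen at
    zero (its GAP, if any, returns to the shared pool), preventing
    numerical resurrection of eliminated clusters.
    """
    n = init.h_c.size
    mask = init.h_c > _EXTINCT  # live clusters

    def rhs(t, y):
        st = _unpack(y, n, variant)
        st.h_c = np.where(mask, st.h_c, 0.0)
        if variant == "basic":
            dh, dp = basic_rhs(st, params)
            dh = np.where(mask, dh, 0.0)
            return np.concatenate([dh, [dp]])
        if variant == "compartment":
            dh, dp = compartment_rhs(st, params)
            dh = np.where(mask, dh, 0.0)
            return np.concatenate([dh, dp])
        dh, dp, dG, dGp = gap_rhs(st, params)
        dh = np.where(mask, dh, 0.0)
        dG = np.where(mask, dG, 0.0)
        return np.concatenate([dh, [dp], dG, [dGp]])

    def make_event(idx):
        def ev(t, y):
            return y[idx] - _EXTINCT
        ev.terminal = True
        ev.direction = -1.0
        return ev

    t0 = 0.0
    y = _pack(init, variant)
    t_eval = np.linspace(0.0, t_end, n_out)
    times: list[float] = []
    states: list[ClusterState] = []
    converged = True
    while t0 < t_end:
        events = [make_event(i) for i in range(n) if mask[i]]
        live_idx = [i for i in range(n) if mask[i]]
        sol = solve_ivp(
            rhs, (t0, t_end), y, method="LSODA", rtol=rtol, atol=atol,
            t_eval=t_eval[(t_eval >= t0) & (t_eval <= t_end)], events=events,
            dense_output=False,
        )
        if not sol.success and sol.status != 1:
            raise RuntimeError(f"cluster ODE integration failed: {sol.message}")
        if len(sol.t):
            for tt, yy in zip(sol.t, np.asarray(sol.y).T):
                times.append(float(tt))
                states.append(_unpack(yy, n, variant))
        if sol.status == 1:  # an extinction event fired
            t_ev, y_ev = np.inf, None
            for te, ye in zip(sol.t_events, sol.y_events):
                if te.size and te[0] < t_ev:
                    t_ev, y_ev = float(te[0]), ye[0]
            st = _unpack(np.asarray(y_ev), n, variant)
            newly = mask & (st.h_c <= _EXTINCT * (1.0 + 1e-6))
            if not newly.any():  # numerical corner: kill the smallest live one
                live = np.where(mask)[0]
                newly = np.zeros_like(mask)
                newly[live[np.argmin(st.h_c[live])]] = True
            # residual material returns to the (local) pool: totals stay exact
            if variant == "compartment":
                st.h_p = np.asarray(st.h_p, float)
                st.h_p[newly] += st.h_c[newly]
            else:
                st.h_p = float(np.asarray(st.h_p)) + float(st.h_c[newly].sum())
            st.h_c[newly] = 0.0
            if variant == "gap" and st.G_c is not None:
                st.G_p += float(st.G_c[newly].sum())
                st.G_c[newly] = 0.0
            mask[newly] = False
            y = _pack(st, variant)
            t0 = t_ev
        else:
            break
    # convergence: max |dh/dt| small at the end
    final = states[-1]
    dy = rhs(times[-1], _pack(final, variant))
    converged = bool(np.max(np.abs(dy)) < 1e-6)
    return ClusterTrajectory(
        times=np.asarray(times), states=states, variant=variant,
        params=params, converged=converged,
    )


def surviving_clusters(traj: ClusterTrajectory, threshold: float = 1e-3) -> int:
    """Clusters whose final amount exceeds ``threshold`` of the largest one."""
    h = traj.final_state.h_c
    top = h.max()
    if top <= 0:
        return 0
    if not traj.converged:
        import warnings

        warnings.warn("trajectory had not converged; survivor count may be transient",
                      stacklevel=2)
    return int(np.sum(h > threshold * top))
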