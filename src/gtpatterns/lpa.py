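"""Local perturbation analysis (LPA).

LPA probes pattern-forming capability by following a narrow pulse of the
slowly diffusing variables on top of a uniform background, in the asymptotic
limit where slow diffusion coefficients go to zero and fast ones to
infinity.  Fast variables are then spatially uniform ("global"), while each
slow variable carries both a global value and a local pulse value; the pulse
occupies zero measure, so global dynamics never see the local variables.
The PDE model thus reduces to a small ODE system whose equilibria and their
stability chart the patterning regimes:

* ``turing``        -- the homogeneous equilibrium is unstable to the local
                       pulse through a real eigenvalue: patterns self-nucleate;
* ``turing_hopf``   -- an unstable complex pair is (also) present;
* ``bistable_het``  -- the homogeneous equilibrium is stable but a stable
                       equilibrium with pulse level != background exists:
                       patterns persist or can be triggered by a finite
                       perturbation, but do not form spontaneously;
* ``stable``        -- only the stable homogeneous equilibrium.

Active GTPases are always slow.  Inactive GTPase and inactive GAP are fast;
mass conservation then fixes them algebraically (``v = T - u_G``), while
turnover models keep ``v`` as a dynamic fast variable.  Active GAP may be
taken fast (``DG -> inf``) or slow (``DG -> 0``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from gtpatterns import models as _models
from gtpatterns.models import ModelSpec
from gtpatterns.stability import RegimeMap

__all__ = ["LPASystem", "LPAEquilibrium", "lpa_reduce", "lpa_equilibria",
           "classify_regime", "regime_map_lpa"]

_EIG_TOL = 1e-9
_HET_TOL = 1e-6


def _f_wp(u, v, b, gamma, n):
    un = u ** n
    return (b + gamma * un / (1.0 + un)) * v - u


def _f_mi(ui, vi, uj, bi, gi, n):
    return (bi + gi / (1.0 + uj ** n)) * vi - ui


@dataclass
class LPASystem:
    """The reduced local+global ODE system for one model and GAP limit.

    State vector layout: global variables first (``global_names``), then the
    local pulse copies of the slow variables (``local_names``).  ``rhs``
    consumes the stacked state; the global block is independent of the local
    one (the pulse has measure zero).
    """

    model: ModelSpec
    gap_limit: str
    global_names: tuple[str, ...]
    local_names: tuple[str, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return self.global_names + self.local_names

    @property
    def n_global(self) -> int:
        return len(self.global_names)

    # -- right-hand side -------------------------------------------------
    def rhs(self, y: np.ndarray) -> np.ndarray:
        m = self.model
        p = m.p
        g = dict(zip(self.global_names, y[: self.n_global]))
        l = dict(zip(self.local_names, y[self.n_global:]))
        mid = m.model_id
        out_g: list = []
        out_l: list = []

        if mid == "WP":
            v = p("T") - g["u_G"]
            out_g = [_f_wp(g["u_G"], v, p("b"), p("gamma"), p("n"))]
            out_l = [_f_wp(l["u_L"], v, p("b"), p("gamma"), p("n"))]
        elif mid == "WPT":
            fG = _f_wp(g["u_G"], g["v"], p("b"), p("gamma"), p("n"))
            out_g = [fG - p("xi") * g["u_G"], -fG + p("sigma")]
            out_l = [_f_wp(l["u_L"], g["v"], p("b"), p("gamma"), p("n")) - p("xi") * l["u_L"]]
        elif mid == "WPGAP":
            v = p("T") - g["u_G"]
            gap_inactive = p("Tg") - g["G_G"]
            fG = _f_wp(g["u_G"], v, p("b"), p("gamma"), p("n"))
            out_g = [
                fG - g["G_G"] * g["u_G"],
                p("c") * g["u_G"] * gap_inactive - p("d") * g["G_G"],
            ]
            fL = _f_wp(l["u_L"], v, p("b"), p("gamma"), p("n"))
            if self.gap_limit == "fast":
                out_l = [fL - g["G_G"] * l["u_L"]]
            else:  # slow active GAP: pulse carries its own GAP
                out_l = [
                    fL - l["G_L"] * l["u_L"],
                    p("c") * l["u_L"] * gap_inactive - p("d") * l["G_L"],
                ]
        elif mid in ("MI", "MIGAP1", "MIGAP2"):
            u1g, u2g = g["u1_G"], g["u2_G"]
            v1, v2 = p("T", 1) - u1g, p("T", 2) - u2g
            r1 = _f_mi(u1g, v1, u2g, p("b", 1), p("gamma", 1), p("n"))
            r2 = _f_mi(u2g, v2, u1g, p("b", 2), p("gamma", 2), p("n"))
            r1l = _f_mi(l["u1_L"], v1, l["u2_L"], p("b", 1), p("gamma", 1), p("n"))
            r2l = _f_mi(l["u2_L"], v2, l["u1_L"], p("b", 2), p("gamma", 2), p("n"))
            out_g = [r1, r2]
            for gi, ti in self.model.gap_targets.items():
                Gg = g[f"G{gi}_G"]
                gap_inactive = p("Tg", gi) - Gg
                ug = u1g if ti == 1 else u2g
                out_g[ti - 1] = out_g[ti - 1] - Gg * ug
                out_g.append(p("c", gi) * ug * gap_inactive - p("d", gi) * Gg)
                ul = l["u1_L"] if ti == 1 else l["u2_L"]
                if ti == 1:
                    r1l = r1l - Gg * ul
                else:
                    r2l = r2l - Gg * ul
            out_l = [r1l, r2l]
        elif mid == "MIT":
            u1g, u2g, v1, v2 = g["u1_G"], g["u2_G"], g["v1"], g["v2"]
            r1 = _f_mi(u1g, v1, u2g, p("b", 1), p("gamma", 1), p("n"))
            r2 = _f_mi(u2g, v2, u1g, p("b", 2), p("gamma", 2), p("n"))
            out_g = [
                r1 - p("xi", 1) * u1g, -r1 + p("sigma", 1),
                r2 - p("xi", 2) * u2g, -r2 + p("sigma", 2),
            ]
            out_l = [
                _f_mi(l["u1_L"], v1, l["u2_L"], p("b", 1), p("gamma", 1), p("n")) - p("xi", 1) * l["u1_L"],
                _f_mi(l["u2_L"], v2, l["u1_L"], p("b", 2), p("gamma", 2), p("n")) - p("xi", 2) * l["u2_L"],
            ]
        else:  # pragma: no cover
            raise ValueError(mid)
        return np.array(out_g + out_l, dtype=float)

    # -- helpers ---------------------------------------------------------
    def homogeneous_state(self, root: dict[str, float] | None = None) -> np.ndarray:
        """Project a uniform model equilibrium onto LPA coordinates."""
        if root is None:
            root = _models.homogeneous_steady_state(self.model).values
        vals = {}
        for name in self.names:
            base = name.rsplit("_", 1)[0] if name.endswith(("_G", "_L")) else name
            vals[name] = root[base]
        return np.array([vals[n] for n in self.names])

    def jacobian(self, y: np.ndarray, eps: float = 1e-7) -> np.ndarray:
        n = y.size
        J = np.empty((n, n))
        for j in range(n):
            h = eps * max(1.0, abs(y[j]))
            yp, ym = y.copy(), y.copy()
            yp[j] += h
            ym[j] -= h
            J[:, j] = (self.rhs(yp) - self.rhs(ym)) / (2 * h)
        return J

    def local_block(self, y: np.ndarray) -> np.ndarray:
        J = self.jacobian(y)
        ng = self.n_global
        return J[ng:, ng:]

    def global_block(self, y: np.ndarray) -> np.ndarray:
        return self.jacobian(y)[: self.n_global, : self.n_global]


def lpa_reduce(model: ModelSpec, gap_limit: str = "fast") -> LPASystem:
    """Reduce a PDE model to its local-perturbation ODE system.

    ``gap_limit`` selects the asymptotic treatment of active GAP:
    ``"fast"`` (``DG -> inf``, GAP is global) or ``"slow"`` (``DG -> 0``,
    the pulse carries a local GAP copy).  Models without GAPs ignore it.
    """
    if gap_limit not in ("fast", "slow"):
        raise ValueError("gap_limit must be 'fast' or 'slow'")
    mid = model.model_id
    if mid == "WP":
        return LPASystem(model, gap_limit, ("u_G",), ("u_L",))
    if mid == "WPT":
        return LPASystem(model, gap_limit, ("u_G", "v"), ("u_L",))
    if mid == "WPGAP":
        if gap_limit == "fast":
            return LPASystem(model, gap_limit, ("u_G", "G_G"), ("u_L",))
        return LPASystem(model, gap_limit, ("u_G", "G_G"), ("u_L", "G_L"))
    if mid == "MI":
        return LPASystem(model, gap_limit, ("u1_G", "u2_G"), ("u1_L", "u2_L"))
    if mid == "MIT":
        return LPASystem(model, gap_limit, ("u1_G", "v1", "u2_G", "v2"), ("u1_L", "u2_L"))
    if mid == "MIGAP1":
        return LPASystem(model, "fast", ("u1_G", "u2_G", "G1_G"), ("u1_L", "u2_L"))
    if mid == "MIGAP2":
        return LPASystem(model, "fast", ("u1_G", "u2_G", "G1_G", "G2_G"), ("u1_L", "u2_L"))
    raise ValueError(mid)


@dataclass
class LPAEquilibrium:
    point: dict[str, float]
    eigenvalues: np.ndarray
    stable: bool
    heterogeneous: bool  # local pulse differs from the global background


def _hom_name_map(name: str) -> str:
    """Global counterpart of a local variable name (u1_L -> u1_G)."""
    return name[:-2] + "_G"


def _local_equilibria(sys: LPASystem, y_global: np.ndarray) -> list[np.ndarray]:
    """Equilibria of the local block with the global background frozen."""
    m = sys.model
    p = m.p
    scales = [10.0]
    if "T" in m.params:
        scales.append(10.0 * m.params["T"])
    for i in (1, 2):
        if f"T_{i}" in m.params:
            scales.append(10.0 * m.params[f"T_{i}"])
        if f"sigma_{i}" in m.params and f"xi_{i}" in m.params and m.params[f"xi_{i}"] > 0:
            scales.append(10.0 * m.params[f"sigma_{i}"] / m.params[f"xi_{i}"])
    if "sigma" in m.params and m.params.get("xi", 0) > 0:
        scales.append(10.0 * m.params["sigma"] / m.params["xi"])
    hi = max(scales)

    nl = len(sys.local_names)
    ng = sys.n_global

    def local_rhs(x):
        y = np.concatenate([y_global, x])
        return sys.rhs(y)[ng:]

    # GTPase local variables only (local GAP, if present, is slaved at
    # equilibrium, handled by the root solver jointly)
    found: list[np.ndarray] = []

    def push(x):
        x = np.asarray(x, float)
        if np.any(x < -1e-9):
            return
        x = np.maximum(x, 0.0)
        if np.max(np.abs(local_rhs(x))) > 1e-9:
            return
        for r in found:
            if np.allclose(r, x, rtol=1e-6, atol=1e-8):
                return
        found.append(x)

    if nl == 1:
        grid = np.geomspace(1e-6, hi, 400)
        vals = np.array([local_rhs([u])[0] for u in grid])
        for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
            if fa == 0.0:
                push([a])
            elif fa * fb < 0:
                push([optimize.brentq(lambda u: local_rhs([u])[0], a, b,
                                      xtol=1e-14, rtol=8.9e-16)])
    else:
        starts = []
        ax = np.geomspace(1e-6, hi, 14)
        if nl == 2:
            if "G_L" in sys.local_names:  # (u_L, G_L): start G at slaved value
                for u in np.geomspace(1e-6, hi, 24):
                    gi = 1
                    gap_inactive = p("Tg", gi) - y_global[sys.global_names.index("G_G")]
                    GL = p("c", gi) * u * gap_inactive / p("d", gi)
                    starts.append([u, max(GL, 0.0)])
            else:
                starts = [[a, b] for a in ax for b in ax]
        for x0 in starts:
            sol = optimize.root(local_rhs, x0, method="hybr", tol=1e-13)
            if sol.success:
                push(sol.x)
    return found


def lpa_equilibria(sys: LPASystem) -> list[LPAEquilibrium]:
    """All non-negative equilibria of the reduced system, classified.

    Global equilibria coincide with the uniform equilibria of the full model
    (every root of the homogeneous steady-state problem); for each, the
    local block is scanned for pulse equilibria by bracketing/multi-start
    root finding.
    """
    try:
        hss = _models.homogeneous_steady_state(sys.model)
    except ValueError:
        return []
    out: list[LPAEquilibrium] = []
    ng = sys.n_global
    for root in hss.all_roots:
        yg = sys.homogeneous_state(root)[:ng]
        for xl in _local_equilibria(sys, yg):
            y = np.concatenate([yg, xl])
            Jg = sys.global_block(y)
            Jl = sys.local_block(y)
            eig = np.concatenate([np.linalg.eigvals(Jg), np.linalg.eigvals(Jl)])
            stable = bool(np.all(eig.real < _EIG_TOL))
            het = any(
                abs(y[ng + i] - y[list(sys.names).index(_hom_name_map(nm))]) >
                _HET_TOL * max(1.0, abs(y[ng + i]))
                for i, nm in enumerate(sys.local_names) if nm.startswith("u")
            )
            out.append(LPAEquilibrium(
                point=dict(zip(sys.names, y)), eigenvalues=eig,
                stable=stable, heterogeneous=het,
            ))
    return out


def classify_regime(sys: LPASystem) -> str:
    """Regime label at the system's current parameters (see module docstring)."""
    try:
        hss = _models.homogeneous_steady_state(sys.model)
    except ValueError:
        return "no_hss"
    y0 = sys.homogeneous_state(hss.values)
    Jg = sys.global_block(y0)
    Jl = sys.local_block(y0)
    eg = np.linalg.eigvals(Jg)
    el = np.linalg.eigvals(Jl)
    alleig = np.concatenate([eg, el])
    unstable_real_local = bool(np.any((el.real > _EIG_TOL) & (np.abs(el.imag) <= _EIG_TOL)))
    unstable_complex = bool(np.any((alleig.real > _EIG_TOL) & (np.abs(alleig.imag) > _EIG_TOL)))
    if unstable_complex:
        return "turing_hopf"
    if unstable_real_local:
        return "turing"
    hom_unstable = bool(np.any(alleig.real > _EIG_TOL))
    if hom_unstable:
        return "turing"
    # homogeneous state stable: look for a stable heterogeneous pulse state
    for eq in lpa_equilibria(sys):
        if eq.heterogeneous and eq.stable:
            return "bistable_het"
    return "stable"


def regime_map_lpa(
    model_id: str,
    p1_name: str,
    p1_values,
    p2_name: str,
    p2_values,
    base_overrides: dict | None = None,
    gap_limit: str = "fast",
    refine: bool = False,
) -> RegimeMap:
    """Classify a 2-parameter grid with LPA (grid + optional boundary bisection)."""
    p1_values = np.asarray(p1_values, dtype=float)
    p2_values = np.asarray(p2_values, dtype=float)
    base = dict(base_overrides or {})

    def label_at(p1: float, p2: float) -> str:
        try:
            model = _models.make_model(model_id, {**base, p1_name: p1, p2_name: p2})
            return classify_regime(lpa_reduce(model, gap_limit))
        except ValueError:
            return "no_hss"

    labels = np.empty((p1_values.size, p2_values.size), dtype=object)
    for i, p1 in enumerate(p1_values):
        for j, p2 in enumerate(p2_values):
            labels[i, j] = label_at(p1, p2)
    rmap = RegimeMap(p1_name, p2_name, p1_values, p2_values, labels)
    if refine:
        rmap.refine_boundaries(label_at)
    return rmap
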