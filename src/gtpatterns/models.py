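"""Dimensionless reaction--diffusion models of small-GTPase membrane patterning.

Seven interaction motifs are supported, all sharing the same GTPase cycling
backbone (active, membrane-bound form ``u`` and inactive, fast-diffusing form
``v``):

=========  ==================  =================  ========  ======  =========
model_id   positive feedback   mass conservation  GTPases   GAPs    variables
=========  ==================  =================  ========  ======  =========
WP         direct              yes                1         0       2
MI         double negative     yes                2         0       4
WPT        direct              no (turnover)      1         0       2
MIT        double negative     no (turnover)      2         0       4
WPGAP      direct              yes                1         1       4
MIGAP1     double negative     yes                2         1       6
MIGAP2     double negative     yes                2         2       8
=========  ==================  =================  ========  ======  =========

The wave-pinning (WP) interconversion term is
``f(u, v) = (b + gamma*u**n/(1 + u**n))*v - u`` (saturating self-activation),
the mutual-inhibition (MI) term is
``f_i(u_i, v_i, u_j) = (b_i + gamma_i/(1 + u_j**n))*v_i - u_i``.
Turnover variants add production ``sigma`` of the inactive form and linear
degradation ``xi`` of the active form.  GAP variants add a conserved
GAP cycle (active ``G``, inactive ``g``) with GTPase-dependent activation
``c*u*g`` and an extra GTPase inactivation flux ``G*u``.

All quantities are dimensionless; diffusion coefficients are expressed
relative to the active-GTPase coefficient (``Dv``, ``DG``, ``Dg``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = [
    "MODEL_IDS",
    "ModelSpec",
    "HomogeneousState",
    "make_model",
    "applicable_parameters",
    "default_parameters",
    "reaction_rates",
    "reaction_jacobian_matrix",
    "homogeneous_steady_state",
    "conserved_totals",
]

MODEL_IDS = ("WP", "MI", "WPT", "MIT", "WPGAP", "MIGAP1", "MIGAP2")

#: variable layout per model; active forms first within each conserved pair
_VARIABLES = {
    "WP": ("u", "v"),
    "WPT": ("u", "v"),
    "MI": ("u1", "v1", "u2", "v2"),
    "MIT": ("u1", "v1", "u2", "v2"),
    "WPGAP": ("u", "v", "G", "g"),
    "MIGAP1": ("u1", "v1", "u2", "v2", "G1", "g1"),
    "MIGAP2": ("u1", "v1", "u2", "v2", "G1", "g1", "G2", "g2"),
}

_N_GTPASES = {"WP": 1, "WPT": 1, "WPGAP": 1, "MI": 2, "MIT": 2, "MIGAP1": 2, "MIGAP2": 2}
_N_GAPS = {"WP": 0, "WPT": 0, "MI": 0, "MIT": 0, "WPGAP": 1, "MIGAP1": 1, "MIGAP2": 2}
_MASS_CONSERVED = {
    "WP": True, "MI": True, "WPT": False, "MIT": False,
    "WPGAP": True, "MIGAP1": True, "MIGAP2": True,
}
#: which GTPase index each GAP index acts on (1-based)
_GAP_TARGETS = {"WPGAP": {1: 1}, "MIGAP1": {1: 1}, "MIGAP2": {1: 1, 2: 2}}

# Default total GTPase for the WPGAP single-cluster operating point: the
# centre of the fast-GAP local-perturbation Turing interval at Tg=10,
# which spans T in (3.74, 5.98) (see docs/methods.md).
_WPGAP_DEFAULT_T = 4.86

_DEFAULTS = {
    "WP": {"b": 0.1, "gamma": 2.0, "n": 2.0, "T": 1.43, "Dv": 100.0},
    "MI": {
        "b_1": 0.1, "b_2": 0.1, "gamma_1": 2.0, "gamma_2": 2.0, "n": 2.0,
        "T_1": 5.0, "T_2": 5.0, "Dv": 100.0,
    },
    "WPT": {"b": 0.1, "gamma": 2.0, "n": 2.0, "sigma": 0.05, "xi": 0.1, "Dv": 100.0},
    "MIT": {
        "b_1": 0.1, "b_2": 0.1, "gamma_1": 2.0, "gamma_2": 2.0, "n": 2.0,
        "sigma_1": 0.2, "sigma_2": 0.2, "xi_1": 0.1, "xi_2": 0.1, "Dv": 100.0,
    },
    "WPGAP": {
        "b": 0.1, "gamma": 2.0, "n": 2.0, "c": 1.0, "d": 1.0,
        "T": _WPGAP_DEFAULT_T, "Tg": 10.0, "Dv": 100.0, "DG": 100.0, "Dg": 100.0,
    },
    "MIGAP1": {
        "b_1": 0.1, "b_2": 0.1, "gamma_1": 2.0, "gamma_2": 2.0, "n": 2.0,
        "c_1": 1.0, "d_1": 1.0, "T_1": 20.0, "T_2": 5.0, "Tg_1": 10.0,
        "Dv": 100.0, "DG": 100.0, "Dg": 100.0,
    },
    "MIGAP2": {
        "b_1": 0.1, "b_2": 0.1, "gamma_1": 2.0, "gamma_2": 2.0, "n": 2.0,
        "c_1": 1.0, "c_2": 1.0, "d_1": 1.0, "d_2": 1.0,
        "T_1": 20.0, "T_2": 20.0, "Tg_1": 10.0, "Tg_2": 10.0,
        "Dv": 100.0, "DG": 100.0, "Dg": 100.0,
    },
}

#: parameters that may be given without an index suffix for two-GTPase
#: models; the bare name then sets every applicable index.
_SUFFIXABLE = ("b", "gamma", "c", "d", "sigma", "xi", "T", "Tg")


@dataclass(frozen=True)
class HomogeneousState:
    """A spatially uniform equilibrium of a model.

    ``values`` is the default root (the one continuously connected to the
    lowest-activity root); ``all_roots`` lists every non-negative root found,
    sorted by total active GTPase.
    """

    values: dict[str, float]
    all_roots: list[dict[str, float]] = field(default_factory=list)

    @property
    def multiple(self) -> bool:
        return len(self.all_roots) > 1

    def __getitem__(self, key: str) -> float:
        return self.values[key]


@dataclass(frozen=True)
class ModelSpec:
    """A model identity plus its dimensionless parameter record."""

    model_id: str
    params: dict[str, float]

    @property
    def variables(self) -> tuple[str, ...]:
        return _VARIABLES[self.model_id]

    @property
    def n_gtpases(self) -> int:
        return _N_GTPASES[self.model_id]

    @property
    def n_gaps(self) -> int:
        return _N_GAPS[self.model_id]

    @property
    def mass_conserved_gtpase(self) -> bool:
        return _MASS_CONSERVED[self.model_id]

    @property
    def gap_targets(self) -> dict[int, int]:
        return _GAP_TARGETS.get(self.model_id, {})

    # -- convenience indexing: p("b", 1) -> params["b_1"] or params["b"]
    def p(self, name: str, index: int | None = None) -> float:
        if index is not None and f"{name}_{index}" in self.params:
            return self.params[f"{name}_{index}"]
        return self.params[name]

    def diffusion_coeffs(self) -> dict[str, float]:
        """Diffusion coefficient per variable (active GTPase defines unity)."""
        out: dict[str, float] = {}
        for var in self.variables:
            if var.startswith("u"):
                out[var] = 1.0
            elif var.startswith("v"):
                out[var] = self.params["Dv"]
            elif var.startswith("G"):
                out[var] = self.params["DG"]
            else:  # inactive GAP
                out[var] = self.params["Dg"]
        return out

    def reaction_terms(self, point):
        return reaction_rates(self, point, validate=False)

    def with_overrides(self, overrides: dict[str, float]) -> "ModelSpec":
        merged = dict(self.params)
        merged.update(_expand_overrides(self.model_id, overrides))
        return make_model(self.model_id, merged)


def applicable_parameters(model_id: str) -> tuple[str, ...]:
    """Names of the parameters a model accepts (with index suffixes)."""
    _check_model_id(model_id)
    return tuple(_DEFAULTS[model_id])


def default_parameters(model_id: str) -> dict[str, float]:
    _check_model_id(model_id)
    return dict(_DEFAULTS[model_id])


def _check_model_id(model_id: str) -> None:
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}; expected one of {MODEL_IDS}")


def _expand_overrides(model_id: str, overrides: dict[str, float]) -> dict[str, float]:
    """Map bare names onto suffixed parameters where the model uses suffixes."""
    allowed = _DEFAULTS[model_id]
    expanded: dict[str, float] = {}
    for key, value in overrides.items():
        if key in allowed:
            expanded[key] = float(value)
        elif key in _SUFFIXABLE and any(f"{key}_{i}" in allowed for i in (1, 2)):
            for i in (1, 2):
                if f"{key}_{i}" in allowed:
                    expanded[f"{key}_{i}"] = float(value)
        else:
            raise ValueError(
                f"parameter {key!r} is not applicable to model {model_id}"
            )
    return expanded


def make_model(model_id: str, overrides: dict[str, float] | None = None) -> ModelSpec:
    """Build a :class:`ModelSpec` from registry defaults plus ``overrides``.

    Unknown or inapplicable parameter names and negative values are rejected.
    ``Dv``/``Dg`` below 1 (inactive forms diffusing slower than active) are
    permitted but trigger a warning, as the patterning mechanisms rely on the
    inactive forms being the fast ones.
    """
    _check_model_id(model_id)
    params = dict(_DEFAULTS[model_id])
    if overrides:
        params.update(_expand_overrides(model_id, overrides))
    for key, value in params.items():
        if value < 0:
            raise ValueError(f"parameter {key} must be non-negative, got {value}")
    if params["n"] < 1:
        raise ValueError(f"Hill exponent n must be >= 1, got {params['n']}")
    for key in ("Dv", "Dg"):
        if key in params and params[key] <= 1.0:
            warnings.warn(
                f"{key} = {params[key]} <= 1: inactive form does not diffuse "
                "faster than active GTPase", stacklevel=2,
            )
    return ModelSpec(model_id=model_id, params=params)


# ---------------------------------------------------------------------------
# reaction terms
# ---------------------------------------------------------------------------

def _f_wp(u, v, b, gamma, n):
    un = u ** n
    return (b + gamma * un / (1.0 + un)) * v - u


def _f_mi(ui, vi, uj, bi, gammai, n):
    return (bi + gammai / (1.0 + uj ** n)) * vi - ui


def _interconversion(model: ModelSpec, point, i: int):
    """f_i for GTPase ``i`` (1-based), vectorised over array-valued points."""
    if model.n_gtpases == 1:
        return _f_wp(point["u"], point["v"], model.p("b"), model.p("gamma"), model.p("n"))
    j = 2 if i == 1 else 1
    return _f_mi(
        point[f"u{i}"], point[f"v{i}"], point[f"u{j}"],
        model.p("b", i), model.p("gamma", i), model.p("n"),
    )


def reaction_rates(model: ModelSpec, point, validate: bool = True):
    """Non-diffusive right-hand side for every model variable.

    ``point`` maps variable names to concentrations (scalars or equally
    shaped arrays).  For mass-conserved pairs the returned rates sum to zero
    exactly by construction.
    """
    missing = [v for v in model.variables if v not in point]
    if missing:
        raise ValueError(f"point is missing variables {missing}")
    if validate:
        for var in model.variables:
            if np.any(np.asarray(point[var]) < 0):
                raise ValueError(f"negative concentration for {var!r}")

    rates: dict[str, float | np.ndarray] = {}
    single = model.n_gtpases == 1
    for i in range(1, model.n_gtpases + 1):
        su = "u" if single else f"u{i}"
        sv = "v" if single else f"v{i}"
        f = _interconversion(model, point, i)
        du = f
        dv = -f
        if not model.mass_conserved_gtpase:  # turnover: production + degradation
            du = du - model.p("xi", i) * point[su]
            dv = dv + model.p("sigma", i)
        rates[su] = du
        rates[sv] = dv
    for gi, ti in model.gap_targets.items():
        sG = "G" if single else f"G{gi}"
        sg = "g" if single else f"g{gi}"
        su = "u" if single else f"u{ti}"
        sv = "v" if single else f"v{ti}"
        gap_flux = point[sG] * point[su]  # GAP-driven GTPase inactivation
        rates[su] = rates[su] - gap_flux
        rates[sv] = rates[sv] + gap_flux
        act = model.p("c", gi) * point[su] * point[sg] - model.p("d", gi) * point[sG]
        rates[sG] = act
        rates[sg] = -act
    return rates


# ---------------------------------------------------------------------------
# analytic Jacobian of the reaction terms
# ---------------------------------------------------------------------------

def _df_wp(u, v, b, gamma, n):
    """(df/du, df/dv) for the wave-pinning interconversion term."""
    un = u ** n
    sat = un / (1.0 + un)
    dsat = n * u ** (n - 1.0) / (1.0 + un) ** 2
    return gamma * dsat * v - 1.0, b + gamma * sat


def _df_mi(ui, vi, uj, bi, gammai, n):
    """(df/du_i, df/dv_i, df/du_j) for the mutual-inhibition term."""
    ujn = uj ** n
    inh = 1.0 / (1.0 + ujn)
    dinh = -n * uj ** (n - 1.0) / (1.0 + ujn) ** 2
    return -1.0, bi + gammai * inh, gammai * dinh * vi


def reaction_jacobian_matrix(model: ModelSpec, point: dict[str, float]) -> np.ndarray:
    """Partial derivatives of all reaction rates w.r.t. all variables.

    Rows/columns follow ``model.variables``.  Derivatives are assembled from
    the closed-form derivatives of the interconversion terms plus the
    turnover and GAP couplings.
    """
    var_index = {v: k for k, v in enumerate(model.variables)}
    m = len(model.variables)
    J = np.zeros((m, m))
    single = model.n_gtpases == 1

    for i in range(1, model.n_gtpases + 1):
        su = "u" if single else f"u{i}"
        sv = "v" if single else f"v{i}"
        iu, iv = var_index[su], var_index[sv]
        if single:
            dfu, dfv = _df_wp(point[su], point[sv], model.p("b"), model.p("gamma"), model.p("n"))
            dfuj = None
        else:
            j = 2 if i == 1 else 1
            dfu, dfv, dfuj = _df_mi(
                point[su], point[sv], point[f"u{j}"],
                model.p("b", i), model.p("gamma", i), model.p("n"),
            )
            iuj = var_index[f"u{j}"]
        J[iu, iu] += dfu
        J[iu, iv] += dfv
        J[iv, iu] += -dfu
        J[iv, iv] += -dfv
        if dfuj is not None:
            J[iu, iuj] += dfuj
            J[iv, iuj] += -dfuj
        if not model.mass_conserved_gtpase:
            J[iu, iu] += -model.p("xi", i)

    for gi, ti in model.gap_targets.items():
        sG = "G" if single else f"G{gi}"
        sg = "g" if single else f"g{gi}"
        su = "u" if single else f"u{ti}"
        sv = "v" if single else f"v{ti}"
        iu, iv = var_index[su], var_index[sv]
        iG, ig = var_index[sG], var_index[sg]
        c, d = model.p("c", gi), model.p("d", gi)
        u, G, g = point[su], point[sG], point[sg]
        # -G*u on du, +G*u on dv
        J[iu, iu] += -G
        J[iu, iG] += -u
        J[iv, iu] += G
        J[iv, iG] += u
        # GAP activation c*u*g - d*G
        J[iG, iu] += c * g
        J[iG, ig] += c * u
        J[iG, iG] += -d
        J[ig, iu] += -c * g
        J[ig, ig] += -c * u
        J[ig, iG] += d
    return J


# ---------------------------------------------------------------------------
# homogeneous steady states
# ---------------------------------------------------------------------------

def _gap_qss_G(u, c, d, Tg):
    """Active GAP at GAP-cycle equilibrium given active GTPase ``u``."""
    return c * u * Tg / (d + c * u)


def _wp_family_residual(model: ModelSpec, u):
    """Residual of the active-GTPase equilibrium condition, 1-GTPase models."""
    T = model.p("T")
    f = _f_wp(u, T - u, model.p("b"), model.p("gamma"), model.p("n"))
    if model.n_gaps:
        f = f - _gap_qss_G(u, model.p("c", 1), model.p("d", 1), model.p("Tg")) * u
    return f


def _scan_roots_1d(fun, lo, hi, n_grid=600):
    """Bracket sign changes of ``fun`` on a mixed log/linear grid, refine by brentq."""
    grid = np.unique(np.concatenate([
        np.geomspace(max(lo, 1e-10), hi, n_grid // 2),
        np.linspace(max(lo, 1e-10), hi, n_grid // 2),
    ]))
    vals = np.array([fun(u) for u in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            roots.append(optimize.brentq(fun, a, b, xtol=1e-14, rtol=8.9e-16))
    if len(vals) and vals[-1] == 0.0:
        roots.append(grid[-1])
    # dedupe
    out: list[float] = []
    for r in sorted(roots):
        if not out or abs(r - out[-1]) > 1e-9 * max(1.0, abs(r)):
            out.append(r)
    return out


def _state_from_u_single(model: ModelSpec, u: float) -> dict[str, float]:
    T = model.p("T")
    state = {"u": u, "v": T - u}
    if model.n_gaps:
        G = _gap_qss_G(u, model.p("c", 1), model.p("d", 1), model.p("Tg"))
        state["G"] = G
        state["g"] = model.p("Tg") - G
    return state


def _mi_family_roots(model: ModelSpec) -> list[dict[str, float]]:
    """Non-negative equilibria of the two-GTPase mass-conserved models."""
    T1, T2 = model.p("T", 1), model.p("T", 2)

    def resid(x):
        u1, u2 = x
        point = {"u1": u1, "v1": T1 - u1, "u2": u2, "v2": T2 - u2}
        r1 = _f_mi(u1, T1 - u1, u2, model.p("b", 1), model.p("gamma", 1), model.p("n"))
        r2 = _f_mi(u2, T2 - u2, u1, model.p("b", 2), model.p("gamma", 2), model.p("n"))
        for gi, ti in model.gap_targets.items():
            u_t = point[f"u{ti}"]
            G = _gap_qss_G(u_t, model.p("c", gi), model.p("d", gi), model.p("Tg", gi))
            if ti == 1:
                r1 -= G * u_t
            else:
                r2 -= G * u_t
        return [r1, r2]

    starts = [(T1 / 2, T2 / 2)]
    for a in np.geomspace(1e-3, max(T1, 1e-2), 7):
        for b in np.geomspace(1e-3, max(T2, 1e-2), 7):
            starts.append((a, b))
    roots: list[tuple[float, float]] = []
    for x0 in starts:
        sol = optimize.root(resid, x0, method="hybr", tol=1e-13)
        if not sol.success:
            continue
        u1, u2 = sol.x
        if not (-1e-12 <= u1 <= T1 + 1e-12 and -1e-12 <= u2 <= T2 + 1e-12):
            continue
        u1, u2 = max(u1, 0.0), max(u2, 0.0)
        if max(abs(np.asarray(resid((u1, u2))))) > 1e-10:
            continue
        if not any(abs(u1 - r1) < 1e-7 * max(1, abs(u1)) and
                   abs(u2 - r2) < 1e-7 * max(1, abs(u2)) for r1, r2 in roots):
            roots.append((u1, u2))

    states = []
    for u1, u2 in sorted(roots, key=lambda r: r[0] + r[1]):
        st = {"u1": u1, "v1": T1 - u1, "u2": u2, "v2": T2 - u2}
        for gi, ti in model.gap_targets.items():
            u_t = st[f"u{ti}"]
            G = _gap_qss_G(u_t, model.p("c", gi), model.p("d", gi), model.p("Tg", gi))
            st[f"G{gi}"] = G
            st[f"g{gi}"] = model.p("Tg", gi) - G
        states.append(st)
    return states


def homogeneous_steady_state(model: ModelSpec) -> HomogeneousState:
    """All non-negative uniform equilibria; the default is the lowest-activity root.

    For turnover models the state is in closed form (active GTPase equals
    ``sigma/xi``); mass-conserved single-GTPase models reduce to a 1-D root
    problem in the active concentration, two-GTPase models to a 2-D one.
    """
    mid = model.model_id
    if mid in ("WP", "WPGAP"):
        T = model.p("T")
        if T == 0:
            root = _state_from_u_single(model, 0.0)
            return HomogeneousState(values=root, all_roots=[root])
        roots = _scan_roots_1d(lambda u: _wp_family_residual(model, u), 1e-8, T)
        if not roots:
            raise ValueError(f"no non-negative homogeneous steady state for {mid}")
        all_states = [_state_from_u_single(model, r) for r in roots]
        return HomogeneousState(values=all_states[0], all_roots=all_states)
    if mid == "WPT":
        u = model.p("sigma") / model.p("xi")
        denom = model.p("b") + model.p("gamma") * u ** model.p("n") / (1.0 + u ** model.p("n"))
        v = (u + model.p("sigma")) / denom if denom > 0 else np.inf
        # f(u, v) = sigma  <=>  denom*v - u = sigma
        root = {"u": u, "v": v}
        return HomogeneousState(values=root, all_roots=[root])
    if mid == "MIT":
        us = [model.p("sigma", i) / model.p("xi", i) for i in (1, 2)]
        root = {}
        for i, (u, uj) in enumerate(zip(us, us[::-1]), start=1):
            denom = model.p("b", i) + model.p("gamma", i) / (1.0 + uj ** model.p("n"))
            root[f"u{i}"] = u
            root[f"v{i}"] = (u + model.p("sigma", i)) / denom
        root = {k: root[k] for k in model.variables}
        return HomogeneousState(values=root, all_roots=[root])
    # MI / MIGAP1 / MIGAP2
    states = _mi_family_roots(model)
    if not states:
        raise ValueError(f"no non-negative homogeneous steady state for {mid}")
    return HomogeneousState(values=states[0], all_roots=states)


def conserved_totals(model: ModelSpec, state) -> dict[str, float]:
    """Spatial means of the conserved totals (u+v per GTPase, G+g per GAP).

    Accepts a mapping of variable name to scalar or array.  Only reported for
    quantities the model actually conserves; turnover models return an empty
    GTPase entry set.
    """
    fields = state.fields if hasattr(state, "fields") else state
    totals: dict[str, float] = {}
    single = model.n_gtpases == 1
    if model.mass_conserved_gtpase:
        for i in range(1, model.n_gtpases + 1):
            su = "u" if single else f"u{i}"
            sv = "v" if single else f"v{i}"
            key = "T" if single else f"T_{i}"
            totals[key] = float(np.mean(fields[su]) + np.mean(fields[sv]))
    for gi in model.gap_targets:
        sG = "G" if single else f"G{gi}"
        sg = "g" if single else f"g{gi}"
        key = "Tg" if single else f"Tg_{gi}"
        totals[key] = float(np.mean(fields[sG]) + np.mean(fields[sg]))
    return totals
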