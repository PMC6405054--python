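"""Linear stability analysis about the homogeneous steady state.

For a model linearised about its uniform equilibrium, the growth rate of a
spatial mode with wave number ``k`` is an eigenvalue of ``J - k^2 * D``,
where ``J`` is the reaction Jacobian and ``D`` the diagonal matrix of
diffusion coefficients.  A parameter point lies in the Turing regime when
some admissible ``k > 0`` carries an eigenvalue with positive real part; a
positive complex pair marks a Hopf (oscillatory) instability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gtpatterns import models as _models
from gtpatterns.models import ModelSpec, HomogeneousState

__all__ = [
    "DispersionRelation",
    "RegimeMap",
    "reaction_jacobian",
    "dispersion",
    "admissible_wavenumbers",
    "turing_map_lsa",
    "default_k2_grid",
]

#: canonical regime labels shared with the LPA module
LABELS = ("stable", "turing", "turing_hopf", "bistable_het", "no_hss")

_EIG_TOL = 1e-9


def reaction_jacobian(model: ModelSpec, hss: HomogeneousState | dict) -> np.ndarray:
    """Reaction Jacobian at a uniform state (analytic, closed form)."""
    point = hss.values if isinstance(hss, HomogeneousState) else hss
    return _models.reaction_jacobian_matrix(model, point)


@dataclass
class DispersionRelation:
    """max-Re eigenvalue of ``J - k^2 D`` over a grid of squared wave numbers."""

    k2_values: np.ndarray
    lambda_max: np.ndarray
    is_complex: np.ndarray  # whether the dominant eigenvalue is part of a complex pair

    @property
    def max_growth_rate(self) -> float:
        return float(self.lambda_max.max())


def _diffusion_vector(model: ModelSpec) -> np.ndarray:
    d = model.diffusion_coeffs()
    return np.array([d[v] for v in model.variables])


def dispersion(model: ModelSpec, hss, k2_list) -> DispersionRelation:
    """Evaluate the dispersion relation on ``k2_list`` (squared wave numbers)."""
    k2 = np.atleast_1d(np.asarray(k2_list, dtype=float))
    if np.any(k2 < 0):
        raise ValueError("squared wave numbers must be non-negative")
    J = reaction_jacobian(model, hss)
    D = _diffusion_vector(model)
    lam = np.empty_like(k2)
    cplx = np.zeros(k2.shape, dtype=bool)
    for i, kk in enumerate(k2):
        w = np.linalg.eigvals(J - kk * np.diag(D))
        j = int(np.argmax(w.real))
        lam[i] = w[j].real
        cplx[i] = abs(w[j].imag) > _EIG_TOL
    return DispersionRelation(k2_values=k2, lambda_max=lam, is_complex=cplx)


def admissible_wavenumbers(grid, max_modes: int = 50) -> np.ndarray:
    """Wave numbers admitted by the domain geometry, sorted ascending.

    x is periodic (``k_x = 2*pi*p/W``); y contributes cosine modes
    ``q*pi/H`` under no-flux conditions or full Fourier modes ``2*pi*q/H``
    when periodic.  The uniform mode (0, 0) is excluded.
    """
    W, H = grid.W, grid.H
    ks = []
    # enough integer modes that the smallest max_modes combinations are covered
    pmax = max_modes + 1
    qmax = max_modes + 1
    for p in range(pmax):
        kx = 2.0 * np.pi * p / W
        for q in range(qmax):
            if p == 0 and q == 0:
                continue
            ky = (q * np.pi / H) if grid.bc_y == "noflux" else (2.0 * np.pi * q / H)
            ks.append(np.hypot(kx, ky))
    ks = np.sort(np.asarray(ks))
    return ks[:max_modes]


def default_k2_grid(model: ModelSpec | None = None, n: int = 80) -> np.ndarray:
    """Squared-wave-number grid covering the unstable band of these models.

    Reaction rates are O(1) and the active-form diffusion coefficient is 1,
    so instabilities live at k^2 of order one; the grid spans 1e-4..30.
    """
    return np.geomspace(1e-4, 30.0, n)


def _classify_lsa_cell(model: ModelSpec, k2_grid: np.ndarray) -> str:
    try:
        hss = _models.homogeneous_steady_state(model)
    except ValueError:
        return "no_hss"
    rel = dispersion(model, hss, k2_grid)
    unstable = rel.lambda_max > _EIG_TOL
    if not unstable.any():
        return "stable"
    if (unstable & rel.is_complex).any():
        return "turing_hopf"
    return "turing"


@dataclass
class RegimeMap:
    """A 2-parameter grid of stability-regime labels.

    ``labels[i, j]`` is the regime at ``(p1_values[i], p2_values[j])``.
    ``boundary_points`` holds bisection-refined points lying on label
    transitions, keyed by the (sorted) label pair.
    """

    p1_name: str
    p2_name: str
    p1_values: np.ndarray
    p2_values: np.ndarray
    labels: np.ndarray  # dtype=object / str
    boundary_points: dict = field(default_factory=dict)

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))

    def agreement(self, other: "RegimeMap", collapse: dict | None = None) -> float:
        """Fraction of cells with equal labels (optionally collapsed)."""
        a, b = self.labels, other.labels
        if collapse:
            a = np.vectorize(lambda s: collapse.get(s, s))(a)
            b = np.vectorize(lambda s: collapse.get(s, s))(b)
        return float(np.mean(a == b))

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{self.p1_name},{self.p2_name},label\n")
            for i, p1 in enumerate(self.p1_values):
                for j, p2 in enumerate(self.p2_values):
                    fh.write(f"{p1},{p2},{self.labels[i, j]}\n")

    def refine_boundaries(self, label_fn, rel_tol: float = 1e-3) -> None:
        """Bisect between horizontally/vertically adjacent differing cells.

        ``label_fn(p1, p2) -> str`` re-classifies a single point.  Refined
        transition points are stored in ``boundary_points``.
        """
        pts: dict = {}
        lab = self.labels
        for i in range(lab.shape[0]):
            for j in range(lab.shape[1]):
                for di, dj in ((1, 0), (0, 1)):
                    i2, j2 = i + di, j + dj
                    if i2 >= lab.shape[0] or j2 >= lab.shape[1]:
                        continue
                    if lab[i, j] == lab[i2, j2]:
                        continue
                    a = np.array([self.p1_values[i], self.p2_values[j]], float)
                    b = np.array([self.p1_values[i2], self.p2_values[j2]], float)
                    la = lab[i, j]
                    scale = np.linalg.norm(b - a)
                    while np.linalg.norm(b - a) > rel_tol * max(scale, 1e-30):
                        mid = 0.5 * (a + b)
                        if label_fn(*mid) == la:
                            a = mid
                        else:
                            b = mid
                    mid = 0.5 * (a + b)
                    key = tuple(sorted((str(lab[i, j]), str(lab[i2, j2]))))
                    pts.setdefault(key, []).append((float(mid[0]), float(mid[1])))
        self.boundary_points = pts


def turing_map_lsa(
    model_id: str,
    p1_name: str,
    p1_values,
    p2_name: str,
    p2_values,
    base_overrides: dict | None = None,
    k2_grid: np.ndarray | None = None,
    refine: bool = False,
) -> RegimeMap:
    """Classify a 2-parameter grid by linear stability of the uniform state."""
    p1_values = np.asarray(p1_values, dtype=float)
    p2_values = np.asarray(p2_values, dtype=float)
    base = dict(base_overrides or {})
    if k2_grid is None:
        k2_grid = default_k2_grid()

    def label_at(p1: float, p2: float) -> str:
        try:
            model = _models.make_model(model_id, {**base, p1_name: p1, p2_name: p2})
        except ValueError:
            return "no_hss"
        return _classify_lsa_cell(model, k2_grid)

    labels = np.empty((p1_values.size, p2_values.size), dtype=object)
    for i, p1 in enumerate(p1_values):
        for j, p2 in enumerate(p2_values):
            labels[i, j] = label_at(p1, p2)
    rmap = RegimeMap(p1_name, p2_name, p1_values, p2_values, labels)
    if refine:
        rmap.refine_boundaries(label_at)
    return rmap
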