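"""Optional matplotlib helpers for fields and regime maps.

Import requires the ``plot`` extra (matplotlib); the rest of the package
does not depend on it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_field", "plot_regime_map"]

_REGIME_COLORS = {
    "stable": "#f0f0f0",
    "turing": "#111111",
    "turing_hopf": "#00b7c3",
    "bistable_het": "#d62728",
    "no_hss": "#ffffff",
}


def plot_field(field: np.ndarray, grid, ax=None, cmap: str = "viridis",
               colorbar: bool = True, title: str | None = None):
    """Heatmap of a concentration field on its domain (returns the axes)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        field, origin="lower", extent=(0, grid.W, 0, grid.H),
        cmap=cmap, interpolation="nearest", aspect="equal",
    )
    if colorbar:
        ax.figure.colorbar(im, ax=ax, label="[GTPase]")
    if title:
        ax.set_title(title)
    ax.set_xlabel("x")
    ax.set_ylabel("y")
    return ax


def plot_regime_map(rmap, ax=None, show_boundaries: bool = True):
    """Raster of a 2-parameter regime map (black = Turing, cyan = Hopf,
    red = bistable-heterogeneous), with refined boundary points overlaid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap
    from matplotlib.patches import Patch

    if ax is None:
        _, ax = plt.subplots()
    labels = sorted({str(l) for l in rmap.labels.ravel()})
    lut = {lab: i for i, lab in enumerate(labels)}
    data = np.vectorize(lut.get)(rmap.labels.astype(str))
    cmap = ListedColormap([_REGIME_COLORS.get(lab, "#888888") for lab in labels])

    def _extent(vals):
        half = (vals[-1] - vals[0]) / max(2 * (len(vals) - 1), 1) or 0.5
        return vals[0] - half, vals[-1] + half

    ax.imshow(
        data.T, origin="lower", aspect="auto", cmap=cmap,
        extent=(*_extent(rmap.p1_values), *_extent(rmap.p2_values)),
        interpolation="nearest", vmin=-0.5, vmax=len(labels) - 0.5,
    )
    if show_boundaries and rmap.boundary_points:
        for pts in rmap.boundary_points.values():
            arr = np.asarray(pts)
            ax.plot(arr[:, 0], arr[:, 1], ".", ms=2, color="#666666")
    ax.set_xlabel(rmap.p1_name)
    ax.set_ylabel(rmap.p2_name)
    ax.legend(
        handles=[Patch(color=_REGIME_COLORS.get(lab, "#888888"), label=lab)
                 for lab in labels],
        loc="upper right", fontsize="small",
    )
    return ax
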