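"""Pattern quantification: cluster counts, spots/stripes/gaps, oscillations.

Cluster counting thresholds the field at a fraction of its range and labels
8-connected components, merging components across the periodic x seam (and
the y seam when y is periodic).  Pattern classes operationalise the visual
categories: isolated high-phase components are *spots*, isolated low-phase
components inside a dominant high phase are *gaps*, and any phase component
wrapping a periodic direction (or spanning the full no-flux extent) makes
the pattern *stripes*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["PatternSummary", "count_clusters", "classify_pattern", "oscillation_detect"]

_EIGHT = np.ones((3, 3), dtype=int)
_HOMOGENEOUS_REL_AMP = 1e-4


@dataclass
class PatternSummary:
    n_clusters_high: int
    n_clusters_low: int
    pattern_class: str  # homogeneous | spots | stripes | gaps | mixed
    amplitude: float
    drift_velocity: float = 0.0


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, a):
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _label_periodic(mask: np.ndarray, periodic_x: bool, periodic_y: bool):
    """8-connected labelling with seam merging; returns (labels, count)."""
    labels, n = ndimage.label(mask, structure=_EIGHT)
    if n == 0:
        return labels, 0
    uf = _UnionFind(n + 1)
    if periodic_x:
        left, right = labels[:, 0], labels[:, -1]
        for dy in (-1, 0, 1):  # 8-connectivity across the seam
            a = np.roll(left, dy)
            both = (a > 0) & (right > 0)
            for la, lb in zip(a[both], right[both]):
                uf.union(int(la), int(lb))
    if periodic_y:
        top, bottom = labels[0, :], labels[-1, :]
        for dx in (-1, 0, 1):
            a = np.roll(top, dx)
            both = (a > 0) & (bottom > 0)
            for la, lb in zip(a[both], bottom[both]):
                uf.union(int(la), int(lb))
    roots = {uf.find(i) for i in range(1, n + 1)}
    remap = {r: k + 1 for k, r in enumerate(sorted(roots))}
    out = np.zeros_like(labels)
    nz = labels > 0
    out[nz] = np.vectorize(lambda l: remap[uf.find(int(l))])(labels[nz])
    return out, len(roots)


def count_clusters(field: np.ndarray, grid, level: float = 0.5) -> int:
    """Number of connected high-phase components at a relative threshold.

    The threshold is ``min + level*(max - min)``; a field whose relative
    amplitude is below the homogeneity tolerance has zero clusters.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie strictly between 0 and 1")
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise ValueError("field contains non-finite values")
    lo, hi = field.min(), field.max()
    scale = max(abs(field.mean()), 1e-300)
    if hi - lo <= _HOMOGENEOUS_REL_AMP * scale:
        return 0
    mask = field > lo + level * (hi - lo)
    _, n = _label_periodic(mask, periodic_x=True, periodic_y=grid.bc_y == "periodic")
    return n


def _any_component_wraps(labels: np.ndarray, n: int) -> bool:
    """Whether any component spans the full x extent or the full y extent.

    A band around the periodic direction touches every column (or row);
    under no-flux conditions a stripe spanning wall to wall does the same.
    """
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.any(axis=0).all() or comp.any(axis=1).all():
            return True
    return False


def classify_pattern(field: np.ndarray, grid, level: float = 0.5) -> PatternSummary:
    """Classify a single concentration field into the standard pattern classes.

    *spots*: isolated high-phase components in a connected low background;
    *gaps*: the inverse; *stripes*: both phases contain domain-spanning
    (wrapping) components, as for bands around the cylinder.
    """
    field = np.asarray(field, dtype=float)
    lo, hi = field.min(), field.max()
    amp = hi - lo
    scale = max(abs(field.mean()), 1e-300)
    periodic_y = grid.bc_y == "periodic"
    if amp <= _HOMOGENEOUS_REL_AMP * scale:
        return PatternSummary(0, 0, "homogeneous", float(amp))
    mask_high = field > lo + level * amp
    labels_hi, n_hi = _label_periodic(mask_high, True, periodic_y)
    labels_lo, n_lo = _label_periodic(~mask_high, True, periodic_y)
    frac_high = mask_high.mean()
    high_wraps = _any_component_wraps(labels_hi, n_hi)
    low_wraps = _any_component_wraps(labels_lo, n_lo)
    if high_wraps and low_wraps:
        cls = "stripes"
    elif not high_wraps and n_hi >= 1 and frac_high < 0.5:
        cls = "spots"
    elif not low_wraps and n_lo >= 1 and frac_high > 0.5:
        cls = "gaps"
    else:
        cls = "mixed"
    return PatternSummary(n_hi, n_lo, cls, float(amp))


def oscillation_detect(
    traj, probe=None, t_min: float | None = None,
    peak_factor: float = 5.0, min_rel_amplitude: float = 1e-3,
) -> dict:
    """Detect periodic oscillation of a scalar probe of the trajectory.

    ``probe`` maps a field dict to a scalar (default: spatial max of the
    first variable).  The series is linearly detrended; an oscillation is
    reported when the dominant discrete-spectrum peak exceeds
    ``peak_factor`` times the median spectral background and the detrended
    amplitude exceeds ``min_rel_amplitude`` of the series mean.
    """
    if probe is None:
        first = next(iter(traj.states[0].fields))
        probe = lambda fields: float(np.max(fields[first]))  # noqa: E731
    times = np.asarray(traj.times)
    keep = slice(None) if t_min is None else times >= t_min
    t = times[keep]
    series = np.array([probe(s.fields) for s in traj.states])[keep]
    if series.size < 20:
        raise ValueError("need at least 20 snapshots after the transient cut")
    # linear detrend
    coef = np.polyfit(t, series, 1)
    resid = series - np.polyval(coef, t)
    scale = max(abs(series.mean()), 1e-300)
    amp_rel = (resid.max() - resid.min()) / scale
    spec = np.abs(np.fft.rfft(resid * np.hanning(resid.size))) ** 2
    spec[0] = 0.0
    if spec[1:].size < 3:
        return {"oscillating": False, "period": None}
    background = np.median(spec[1:])
    j = int(np.argmax(spec))
    peak_ok = background > 0 and spec[j] > peak_factor * background
    dt_snap = np.mean(np.diff(t))
    freq = np.fft.rfftfreq(resid.size, d=dt_snap)
    oscillating = bool(peak_ok and amp_rel > min_rel_amplitude and j > 0)
    return {
        "oscillating": oscillating,
        "period": float(1.0 / freq[j]) if oscillating else None,
        "relative_amplitude": float(amp_rel),
    }
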