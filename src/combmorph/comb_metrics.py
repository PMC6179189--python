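"""Morphometrics of simulated combs.

Quantities reported per simulation:

* alpha -- the rotation angle: the angle in [0, 180) degrees between the
  line joining the centres of mass (CoM) of the two extreme teeth
  (base -> tip) and the -x axis.  0 means horizontal (unrotated, tip
  pointing toward -x), 90 fully vertical.
* beta_1..beta_{n-1} -- orientations (vs +x) of the vectors joining
  consecutive tooth CoMs, unwrapped to a continuous branch around their
  circular mean; their sample SD (the "angle between adjacent teeth" SD)
  measures comb curvature: 0 for a straight comb.
* intact -- whether the union of all SCT pixels forms a single connected
  component (8-connectivity by default, periodic in x), i.e. a continuous
  path can be traced along the comb without crossing other cell types.

Tooth identity and base-to-tip order follow the persistent cell ids
recorded at generation, so the metrics are robust to bent combs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._kernels import EP1, EP2, SCT
from .cpm_core import LatticeState


class MetricError(ValueError):
    pass


@dataclass
class MetricsRecord:
    alpha: float
    betas: list[float]
    abasct_sd: float
    intact: bool
    mean_area_ep1: float | None
    mean_area_ep2: float | None
    time: int
    n_teeth: int


@dataclass
class SetSummary:
    n_runs: int
    n_intact: int
    abasct_sd_distribution: list[float]  # intact runs only
    alpha_distribution: list[float]

    @property
    def intact_ratio(self) -> float:
        return self.n_intact / self.n_runs


def tooth_coms(lattice: LatticeState) -> list[tuple[int, tuple[float, float]]]:
    """CoMs of surviving teeth in persistent base-to-tip order.

    CoMs are periodic-aware (x reported in [0, n_x)).  Retired teeth are
    omitted with a warning.
    """
    if not lattice.tooth_ids:
        raise MetricError("lattice has no recorded tooth ordering")
    out = []
    for sig in lattice.tooth_ids:
        if lattice.area[sig] == 0:
            warnings.warn(f"tooth cell {sig} was retired; omitting", stacklevel=2)
            continue
        c = lattice.cell(sig)
        out.append((sig, c.com))
    if len(out) < 2:
        raise MetricError("fewer than 2 surviving SCT teeth")
    return out


def _consecutive_vectors(coms: list[tuple[float, float]], n_x: int) -> np.ndarray:
    """Minimal-image displacement vectors between consecutive tooth CoMs.
    Individual steps are short (a tooth width), so the minimal image is
    unambiguous even when the whole comb spans more than half the lattice."""
    v = []
    for (x0, y0), (x1, y1) in zip(coms[:-1], coms[1:]):
        dx = x1 - x0
        dx -= n_x * round(dx / n_x)
        v.append((dx, y1 - y0))
    return np.asarray(v)


def alpha_from_coms(coms: list[tuple[float, float]], n_x: int | None = None) -> float:
    """Rotation angle from an ordered base->tip CoM list (degrees from -x)."""
    steps = _consecutive_vectors(coms, n_x or 10**9)
    vx, vy = steps.sum(axis=0)  # base->tip, accumulated through short steps
    norm = math.hypot(vx, vy)
    if norm < 1e-12:
        raise MetricError("base and tip CoMs coincide")
    return math.degrees(math.acos(max(-1.0, min(1.0, -vx / norm))))


def compute_alpha(lattice: LatticeState) -> float:
    """Rotation angle between the base->tip tooth line and the -x axis."""
    return alpha_from_coms([c for _, c in tooth_coms(lattice)], lattice.params.n_x)


def betas_from_coms(coms: list[tuple[float, float]], n_x: int | None = None) -> list[float]:
    """Inter-tooth orientations from an ordered CoM list (see
    :func:`compute_abasct`)."""
    steps = _consecutive_vectors(coms, n_x or 10**9)
    raw = np.degrees(np.arctan2(steps[:, 1], steps[:, 0]))
    rad = np.radians(raw)
    mean = math.degrees(math.atan2(np.sin(rad).mean(), np.cos(rad).mean()))
    dev = raw - mean
    dev -= 360.0 * np.round(dev / 360.0)
    return [float(b) for b in mean + dev]


def compute_abasct(lattice: LatticeState) -> list[float]:
    """Orientations (degrees vs +x) of consecutive inter-tooth vectors,
    unwrapped to the continuous branch around their circular mean."""
    return betas_from_coms([c for _, c in tooth_coms(lattice)], lattice.params.n_x)


def abasct_sd(betas: list[float]) -> float:
    """Sample standard deviation (n-1 denominator) of the unwrapped angle
    list; 0 for a straight comb."""
    if len(betas) < 2:
        raise MetricError("need at least 2 inter-tooth angles")
    return float(np.std(betas, ddof=1))


def is_intact(lattice: LatticeState, connectivity: int = 8) -> bool:
    """True iff all SCT pixels form one connected component (periodic in x)."""
    mask = (lattice.ctype[lattice.grid] == SCT)
    if not mask.any():
        raise MetricError("no SCT pixels in the lattice")
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    elif connectivity == 4:
        structure = ndimage.generate_binary_structure(2, 1)
    else:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(mask, structure=structure)
    if n <= 1:
        return n == 1
    # merge labels across the periodic x seam
    parent = list(range(n + 1))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    ny = lattice.params.n_y
    left, right = labels[0, :], labels[-1, :]
    offsets = (0,) if connectivity == 4 else (-1, 0, 1)
    for y in range(ny):
        if right[y] == 0:
            continue
        for oy in offsets:
            yy = y + oy
            if 0 <= yy < ny and left[yy] != 0:
                union(int(right[y]), int(left[yy]))
    roots = {find(l) for l in range(1, n + 1)}
    return len(roots) == 1


def intact_ratio(records: list[MetricsRecord]) -> float:
    if not records:
        raise MetricError("empty record list")
    return sum(r.intact for r in records) / len(records)


def distal_area_summary(lattice: LatticeState) -> tuple[float | None, float | None]:
    """Mean current areas of surviving EP1 and EP2 cells (None when a class
    has no survivors)."""
    out = []
    for code in (EP1, EP2):
        mask = (lattice.ctype == code) & (lattice.area > 0)
        out.append(float(lattice.area[mask].mean()) if mask.any() else None)
    return tuple(out)


def measure(lattice: LatticeState) -> MetricsRecord:
    """Full morphometric record of the current lattice state."""
    betas = compute_abasct(lattice)
    m_ep1, m_ep2 = distal_area_summary(lattice)
    return MetricsRecord(
        alpha=compute_alpha(lattice),
        betas=betas,
        abasct_sd=abasct_sd(betas),
        intact=is_intact(lattice),
        mean_area_ep1=m_ep1,
        mean_area_ep2=m_ep2,
        time=lattice.time,
        n_teeth=len(lattice.tooth_ids),
    )
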