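"""Initial comb configurations, default parameter bundles, and PIF I/O.

The generator lays out the modelled first-tarsal epithelium on the periodic
lattice: two frozen barrier (BA) rows at the bottom, a contiguous
near-horizontal chain of square SCT teeth (base tooth on the right, the
pivot of rotation; tip pointing in -x and tilted slightly upward), a distal
band of expanding epithelial cells between barrier and comb, and proximal
EP3 cells filling everything above.  Distal seed areas decay from base to
tip: larger cells (EP1) near the base, smaller cells (EP2) near the tip.
It is this inhomogeneity that later converts roughly uniform terminal
target areas into a differential push that rotates the comb; the
``homogeneous_mode`` control removes the gradient.

Generation is fully deterministic; the same spec always yields the same
lattice, bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
import numpy as np
import pandas as pd

from ._kernels import BA, EP1, EP2, EP3, SCT
from .cpm_core import TYPE_CODE, TYPE_NAME, AdhesionTable, LatticeState, SimParams
from .morphodynamics import ExpansionSchedule, TypeParams

# Table-derived per-length defaults: terminal target areas (pixels) and the
# expansion time constant (mcs) grow with comb length.
A_TERM_EP1 = {5: 9.0, 7: 9.0, 9: 9.8, 11: 9.8}
A_TERM_EP2 = {5: 13.0, 7: 13.2, 9: 12.8, 11: 12.6}
A_TERM_EP3 = 5.0
TAU = {5: 100.0, 7: 160.0, 9: 220.0, 11: 280.0}

J_EP_EP = 1000.0
J_EP_SCT = 10000.0


@dataclass(frozen=True)
class CombLayoutSpec:
    """Declarative description of an initial configuration.

    ``base_anchor`` is the lower-left pixel of the base (pivot) tooth; teeth
    run toward -x, each raised to follow ``initial_angle``.  The distal seed
    areas decay from ``area_near_base`` at the base tooth to
    ``area_near_tip`` at the tip tooth (clamped beyond); EP1/EP2 demarcation
    is at the comb's half-length.  With ``homogeneous_mode`` every distal
    cell is seeded at ``homogeneous_area`` (default: the tip seed, i.e.
    uniformly small cells).  Shipped defaults are the calibrated
    configuration under which the default parameter bundles produce proper
    rotation of intact combs.
    """

    n_teeth: int = 9
    tooth_side: int = 6
    initial_angle: float = 18.0
    base_anchor: tuple[int, int] = (88, 12)
    area_near_base: float = 9.8
    area_near_tip: float = 3.3
    ep3_cell_area: int = 9
    ba_rows: int = 2
    n_x: int = 114
    n_y: int = 84
    scale: int = 1
    homogeneous_mode: bool = False
    homogeneous_area: float | None = None
    # shape of the base->tip seed-area decay: 1 = linear in comb position,
    # <1 concentrates the drop near the tip, >1 near the base
    gradient_power: float = 0.6
    # "linear": seed area interpolates linearly between the two end areas.
    # "factor": the linear expansion ratio sqrt(a_term/seed) interpolates
    # linearly instead, which keeps the realized push profile continuous
    # across the EP1/EP2 boundary despite their different terminal targets.
    interpolation: str = "factor"
    # distal band depth beyond the comb tip: keep the tip-level depth
    # ("deep"), drop to base-level depth ("shallow"), interpolate linearly
    # from tip level at the tip to base level at x = 0 ("taper"), or place
    # no distal cells beyond the tip at all ("none": proximal tissue there,
    # so the tip tooth sits at the edge of the expanding distal fan)
    beyond_tip: str = "deep"

    def __post_init__(self):
        if self.n_teeth not in (5, 7, 9, 11):
            raise ValueError("n_teeth must be one of 5, 7, 9, 11")
        if self.scale not in (1, 2):
            raise ValueError("scale must be 1 or 2")

    def tooth_origin(self, i: int) -> tuple[int, int]:
        """Lower-left pixel of tooth i (0 = base)."""
        ts = self.tooth_side
        x0 = self.base_anchor[0] - ts * i
        y0 = self.base_anchor[1] + int(round(i * ts * math.tan(math.radians(self.initial_angle))))
        return x0, y0

    def seed_area(self, x: float) -> float:
        if self.homogeneous_mode:
            if self.homogeneous_area is not None:
                return float(self.homogeneous_area)
            # uniformly small cells: the tip seed everywhere, so the control
            # expands strongly but without any base->tip differential
            return float(self.area_near_tip)
        half = 0.5 * self.tooth_side
        xb = self.base_anchor[0] + half
        xt = self.tooth_origin(self.n_teeth - 1)[0] + half
        f = (x - xt) / (xb - xt)
        f = min(max(f, 0.0), 1.0)
        f = f ** self.gradient_power
        if self.interpolation == "linear":
            return self.area_near_tip + f * (self.area_near_base - self.area_near_tip)
        if self.interpolation != "factor":
            raise ValueError(f"unknown interpolation {self.interpolation!r}")
        at_base = A_TERM_EP1[self.n_teeth]
        at_tip = A_TERM_EP2[self.n_teeth]
        g_base = math.sqrt(at_base / self.area_near_base)
        g_tip = math.sqrt(at_tip / self.area_near_tip)
        g = g_tip + f * (g_base - g_tip)
        a_term = at_base if x >= 0.5 * (xb + xt) else at_tip
        return a_term / (g * g)


@dataclass(frozen=True)
class ParamBundle:
    """Everything needed to run one simulation: system parameters, adhesion
    table and the expansion schedule, assembled for a comb length and a
    tooth-tooth adhesion J(SCT, SCT)."""

    sim: SimParams
    adhesion: AdhesionTable
    schedule: ExpansionSchedule
    n_teeth: int
    j_sct_sct: float


def default_params(
    n_teeth: int,
    j_sct_sct: float,
    seed: int = 0,
    duration: int = 2000,
    a_term_ep1: float | None = None,
    a_term_ep2: float | None = None,
) -> ParamBundle:
    """Standard parameter bundle for a given comb length.

    ``a_term_ep1`` / ``a_term_ep2`` override the terminal target areas of
    the distal cells (used by the rotation-angle and homogeneous-expansion
    control experiments); all other values follow the standard tables.
    """
    if n_teeth not in TAU:
        raise ValueError(f"unsupported comb length {n_teeth}; choose from {sorted(TAU)}")
    tau = TAU[n_teeth]
    at1 = A_TERM_EP1[n_teeth] if a_term_ep1 is None else float(a_term_ep1)
    at2 = A_TERM_EP2[n_teeth] if a_term_ep2 is None else float(a_term_ep2)
    type_params = {
        "EP1": TypeParams("initial-area", at1, 1e4, tau, 0.03, 3.0, 0, True),
        "EP2": TypeParams("initial-area", at2, 1e4, tau, 0.03, 3.0, 0, True),
        "EP3": TypeParams(9.0, A_TERM_EP3, 500.0, tau, 0.0, 0.0, 0, True),
        "SCT": TypeParams(36.0, 36.0, 1e4, math.inf, 0.0, 1000.0, 0, False),
        "BA": TypeParams("initial-area", 0.0, 0.0, math.inf, 0.0, 0.0, 0, False),
    }
    adhesion = AdhesionTable()
    for c1 in ("EP1", "EP2", "EP3"):
        for c2 in ("EP1", "EP2", "EP3"):
            adhesion.set(c1, c2, J_EP_EP)
        adhesion.set(c1, "SCT", J_EP_SCT)
    adhesion.set("SCT", "SCT", j_sct_sct)
    # BA is frozen, so J rows involving BA never drive dynamics; keep them 0
    # so flips adjacent to the barrier carry no spurious term.
    for c in ("EP1", "EP2", "EP3", "SCT", "BA"):
        adhesion.set(c, "BA", 0.0)
    sim = SimParams(duration=duration, seed=seed)
    return ParamBundle(sim, adhesion, ExpansionSchedule(type_params), n_teeth, j_sct_sct)


# --------------------------------------------------------------------------
# lattice generation
# --------------------------------------------------------------------------


class GenerationError(ValueError):
    pass


def _comb_profiles(spec: CombLayoutSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (bottom, top) of the SCT band and tooth id per column
    (-1 outside the comb's x-span).  Outside the span the distal/proximal
    boundary extends flat at base level (right of the base) and tip level
    (left of the tip)."""
    nx = spec.n_x
    ts = spec.tooth_side
    bottom = np.empty(nx, dtype=np.int64)
    top = np.empty(nx, dtype=np.int64)
    tooth = np.full(nx, -1, dtype=np.int64)
    x_tip = spec.tooth_origin(spec.n_teeth - 1)[0]
    x_base_hi = spec.base_anchor[0] + ts
    if x_tip < 0 or x_base_hi > nx:
        raise GenerationError("comb does not fit in the lattice x-range")
    y_base = spec.base_anchor[1]
    y_tip = spec.tooth_origin(spec.n_teeth - 1)[1]
    xs = np.arange(nx)
    if spec.beyond_tip == "deep":
        left = np.full(nx, y_tip)
    elif spec.beyond_tip == "shallow":
        left = np.full(nx, y_base)
    elif spec.beyond_tip == "taper":
        left = np.rint(y_base + (y_tip - y_base) * xs / max(x_tip, 1)).astype(np.int64)
    elif spec.beyond_tip == "none":
        left = np.full(nx, spec.ba_rows)  # zero-height distal band
    else:
        raise GenerationError(f"unknown beyond_tip mode {spec.beyond_tip!r}")
    bottom[:] = np.where(xs < x_tip, left, y_base)
    for i in range(spec.n_teeth):
        x0, y0 = spec.tooth_origin(i)
        if y0 < spec.ba_rows + 2 or y0 + ts > spec.n_y:
            raise GenerationError(f"tooth {i} does not fit in the lattice y-range")
        bottom[x0:x0 + ts] = y0
        tooth[x0:x0 + ts] = i
    top[:] = bottom
    top[tooth >= 0] += ts
    return bottom, top, tooth


def generate_initial_lattice(
    spec: CombLayoutSpec,
    bundle: ParamBundle | None = None,
) -> LatticeState:
    """Deterministically tile the lattice described by ``spec``.

    Returns a ready-to-run :class:`LatticeState`; ``lattice.tooth_ids``
    records the SCT cell ids in base-to-tip order for the morphometrics.
    """
    if bundle is None:
        bundle = default_params(spec.n_teeth, j_sct_sct=4000.0)
    nx, ny, ts = spec.n_x, spec.n_y, spec.tooth_side
    grid = np.full((nx, ny), -1, dtype=np.int64)
    types: list[int] = []  # type code of cell sigma = index+1

    def new_cell(code: int) -> int:
        types.append(code)
        return len(types)

    # barrier rows
    if spec.ba_rows > 0:
        x = 0
        while x < nx:
            w = min(ts, nx - x)
            sig = new_cell(BA)
            grid[x:x + w, 0:spec.ba_rows] = sig
            x += w

    bottom, top, tooth_of_col = _comb_profiles(spec)

    # teeth, base -> tip (ascending cell ids preserve the ordering)
    tooth_ids = []
    for i in range(spec.n_teeth):
        x0, y0 = spec.tooth_origin(i)
        if np.any(grid[x0:x0 + ts, y0:y0 + ts] != -1):
            raise GenerationError(f"tooth {i} overlaps previously placed cells")
        sig = new_cell(SCT)
        grid[x0:x0 + ts, y0:y0 + ts] = sig
        tooth_ids.append(sig)

    # distal band: [ba_rows, bottom(x)) per column, strip-tiled; strips are
    # clipped at the comb-end breakpoints so a strip never mixes a
    # zero-height region with the band under the comb
    x_mid = spec.base_anchor[0] + ts / 2.0 - ts * (spec.n_teeth - 1) / 2.0
    x_tip0 = spec.tooth_origin(spec.n_teeth - 1)[0]
    breakpoints = sorted(b for b in (x_tip0, spec.base_anchor[0] + ts) if 0 < b < nx)
    x = 0
    while x < nx:
        s = spec.seed_area(x + 0.5)
        w = max(2, int(round(math.sqrt(s))))
        w = min(w, nx - x)
        for b in breakpoints:
            if x < b < x + w:
                w = b - x
        cols = np.arange(x, x + w)
        lo = spec.ba_rows
        hi_cols = bottom[cols]
        hi = int(hi_cols.min())
        height = hi - lo
        if height == 0:
            x += w
            continue
        if height < 2:
            raise GenerationError(
                f"distal band under columns {x}..{x + w - 1} is only {height} px tall"
            )
        code = EP1 if (x + 0.5 * w) >= x_mid else EP2
        k = max(1, int(round(height * w / s)))
        edges = np.linspace(lo, hi, k + 1).round().astype(int)
        top_sig = None
        for j in range(k):
            if edges[j + 1] <= edges[j]:
                continue
            sig = new_cell(code)
            grid[x:x + w, edges[j]:edges[j + 1]] = sig
            top_sig = sig
        # ragged pixels between the strip minimum and each column's comb line
        for c in cols:
            if bottom[c] > hi:
                grid[c, hi:bottom[c]] = top_sig
        x += w

    # proximal EP3 region: [top(x), ny) per column
    w3 = max(2, int(round(math.sqrt(spec.ep3_cell_area))))
    x = 0
    while x < nx:
        w = min(w3, nx - x)
        cols = np.arange(x, x + w)
        lo_cols = top[cols]
        lo = int(lo_cols.max())
        height = ny - lo
        if height < 2:
            raise GenerationError(
                f"proximal region above columns {x}..{x + w - 1} is only {height} px tall"
            )
        k = max(1, int(round(height * w / spec.ep3_cell_area)))
        edges = np.linspace(lo, ny, k + 1).round().astype(int)
        bottom_sig = None
        for j in range(k):
            if edges[j + 1] <= edges[j]:
                continue
            sig = new_cell(EP3)
            grid[x:x + w, edges[j]:edges[j + 1]] = sig
            if j == 0:
                bottom_sig = sig
        for c in cols:
            if top[c] < lo:
                grid[c, top[c]:lo] = bottom_sig
        x += w

    if np.any(grid == -1):
        xs, ys = np.nonzero(grid == -1)
        raise GenerationError(f"unassigned pixels, first at ({xs[0]}, {ys[0]})")

    lattice = assemble_state(grid, types, bundle, spec)
    lattice.tooth_ids = tooth_ids
    return lattice


def assemble_state(
    grid: np.ndarray,
    types: list[int],
    bundle: ParamBundle,
    spec: CombLayoutSpec | None = None,
) -> LatticeState:
    """Attach per-cell mechanical parameters to a typed grid."""
    nx, ny = grid.shape
    sim = bundle.sim
    if (sim.n_x, sim.n_y) != (nx, ny):
        sim = replace(sim, n_x=nx, n_y=ny, flips_per_mcs=nx * ny)
    eps = {name: tp.epsilon for name, tp in bundle.schedule.type_params.items()}
    lattice = LatticeState(
        grid, types, sim, bundle.adhesion.copy(), eps_type=eps, strict_unwrap=True
    )
    for name, tp in bundle.schedule.type_params.items():
        code = TYPE_CODE[name]
        mask = (lattice.ctype == code) & (lattice.area > 0)
        if not mask.any():
            continue
        a0 = np.array([tp.a_target0(a) for a in lattice.area[mask]])
        lattice.a_target[mask] = a0
        lattice.l_target[mask] = np.ceil(np.sqrt(a0))
        lattice.lambda_a[mask] = tp.lambda_a
        lattice.lambda_l[mask] = tp.lambda_l
    return lattice


# --------------------------------------------------------------------------
# PIF I/O
# --------------------------------------------------------------------------


def write_pif(lattice: LatticeState, path) -> str:
    """Write the lattice as PIF records ``id type x_low x_high y_low y_high``
    (inclusive 0-based bounds), one record per maximal rectangular block."""
    lines = []
    nx, ny = lattice.grid.shape
    for sig in lattice.alive_sigmas():
        name = TYPE_NAME[int(lattice.ctype[sig])]
        xs, ys = np.nonzero(lattice.grid == sig)
        # row runs keyed by (x_start, x_end), merged across consecutive rows
        runs_by_y: dict[int, list[tuple[int, int]]] = {}
        for y in np.unique(ys):
            row = np.sort(xs[ys == y])
            breaks = np.nonzero(np.diff(row) != 1)[0]
            starts = np.concatenate(([0], breaks + 1))
            ends = np.concatenate((breaks, [len(row) - 1]))
            runs_by_y[int(y)] = [(int(row[a]), int(row[b])) for a, b in zip(starts, ends)]
        open_rects: dict[tuple[int, int], int] = {}  # (x0, x1) -> y_start
        prev_y = None
        for y in sorted(runs_by_y):
            cur = set(runs_by_y[y])
            if prev_y is not None and y != prev_y + 1:
                for (x0, x1), y0 in open_rects.items():
                    lines.append(f"{int(sig)} {name} {x0} {x1} {y0} {prev_y}")
                open_rects = {}
            closed = [k for k in open_rects if k not in cur]
            for k in closed:
                x0, x1 = k
                lines.append(f"{int(sig)} {name} {x0} {x1} {open_rects.pop(k)} {prev_y}")
            for k in cur:
                open_rects.setdefault(k, y)
            prev_y = y
        for (x0, x1), y0 in open_rects.items():
            lines.append(f"{int(sig)} {name} {x0} {x1} {y0} {prev_y}")
    text = "\n".join(lines) + "\n"
    with open(path, "w") as fh:
        fh.write(text)
    return str(path)


class PifParseError(ValueError):
    pass


def read_pif(
    path,
    bundle: ParamBundle | None = None,
    dims: tuple[int, int] | None = None,
) -> LatticeState:
    """Parse a PIF file back into a LatticeState.

    Dimensions are taken from ``dims`` or (failing that) inferred from the
    maximal coordinates.  Overlapping blocks, unknown type names and
    malformed records raise :class:`PifParseError` with the line number.
    ``tooth_ids`` are the SCT cell ids in ascending order (the generator's
    base-to-tip convention).
    """
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise PifParseError(f"line {lineno}: expected 6 fields, got {len(parts)}")
            try:
                sig = int(parts[0])
                x0, x1, y0, y1 = map(int, parts[2:])
            except ValueError as e:
                raise PifParseError(f"line {lineno}: {e}") from None
            name = parts[1]
            if name not in TYPE_CODE:
                raise PifParseError(f"line {lineno}: unknown cell type {name!r}")
            if sig < 1 or x0 > x1 or y0 > y1 or min(x0, y0) < 0:
                raise PifParseError(f"line {lineno}: malformed bounds")
            records.append((lineno, sig, TYPE_CODE[name], x0, x1, y0, y1))
    if not records:
        raise PifParseError("empty PIF file")
    if dims is None:
        dims = (max(r[4] for r in records) + 1, max(r[6] for r in records) + 1)
    nx, ny = dims
    grid = np.zeros((nx, ny), dtype=np.int64)
    n_cells = max(r[1] for r in records)
    types = [0] * n_cells
    for lineno, sig, code, x0, x1, y0, y1 in records:
        if x1 >= nx or y1 >= ny:
            raise PifParseError(f"line {lineno}: block outside lattice {dims}")
        block = grid[x0:x1 + 1, y0:y1 + 1]
        clash = (block != 0) & (block != sig)
        if clash.any():
            raise PifParseError(f"line {lineno}: block overlaps another cell")
        if types[sig - 1] not in (0, code):
            raise PifParseError(f"line {lineno}: cell {sig} redeclared with a new type")
        types[sig - 1] = code
        block[:] = sig
    if np.any(grid == 0):
        raise PifParseError("PIF does not cover the lattice (unassigned pixels)")
    if bundle is None:
        n_sct = sum(1 for t in types if t == SCT)
        bundle = default_params(n_sct if n_sct in TAU else 9, j_sct_sct=4000.0)
    lattice = assemble_state(grid, types, bundle)
    lattice.tooth_ids = [i + 1 for i, t in enumerate(types) if t == SCT]
    return lattice


# --------------------------------------------------------------------------
# resolution scaling
# --------------------------------------------------------------------------


def scale_lattice(lattice: LatticeState, factor: int = 2) -> LatticeState:
    """Double the lattice resolution: each pixel becomes a factor x factor
    block, areas scale by factor^2, lengths by factor, attempts per mcs by
    factor^2, and the axial weight switches to its R^2 form."""
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    grid = np.kron(lattice.grid, np.ones((factor, factor), dtype=lattice.grid.dtype))
    sim = replace(
        lattice.params,
        n_x=lattice.params.n_x * factor,
        n_y=lattice.params.n_y * factor,
        flips_per_mcs=lattice.params.flips_per_mcs * factor * factor,
    )
    new = LatticeState(
        grid,
        lattice.ctype[1:],
        sim,
        lattice.adhesion.copy(),
        r_squared_mode=True,
    )
    new.eps_type = lattice.eps_type.copy()
    new.a_target = lattice.a_target * factor * factor
    new.l_target = lattice.l_target * factor
    new.lambda_a = lattice.lambda_a.copy()
    new.lambda_l = lattice.lambda_l.copy()
    new.extruded = lattice.extruded.copy()
    new.tooth_ids = list(lattice.tooth_ids)
    return new


def scale_schedule(schedule: ExpansionSchedule, factor: int = 2) -> ExpansionSchedule:
    """Companion transform for the expansion schedule (terminal areas and any
    fixed initial targets scale by factor^2)."""
    if factor != 2:
        raise ValueError("only factor 2 is supported")
    f2 = factor * factor
    tp = {}
    for name, p in schedule.type_params.items():
        pol = p.a_target0_policy
        if pol != "initial-area":
            pol = float(pol) * f2
        tp[name] = replace(p, a_target0_policy=pol, a_term=p.a_term * f2)
    return replace(
        schedule,
        type_params=tp,
        extrusion_threshold=schedule.extrusion_threshold * f2,
    )


# --------------------------------------------------------------------------
# synthetic apical-area time courses
# --------------------------------------------------------------------------


def generate_area_timecourse(
    groups: tuple[str, ...] = ("EP2", "EP1"),
    onsets: tuple[float, ...] = (23.3, 27.4),
    asymptotes: tuple[float, ...] = (150.0, 100.0),
    slopes: tuple[float, ...] = (20.0, 15.0),
    noise_sd: float = 0.05,
    oscillation: tuple[float, float] | None = None,
    seed: int = 0,
    n_cells_per_group: int = 10,
    t_start: float = 22.0,
    t_end: float = 41.5,
    dt_hours: float = 0.5,
    cell_sd: float = 0.0,
    onset_jitter: float = 0.0,
) -> pd.DataFrame:
    """Synthetic per-cell apical-area expansion series.

    Emulates the measured confocal time courses: per-group logistic growth of
    percentage area change on an hourly grid between ``t_start`` and
    ``t_end`` hours after pupariation, multiplicative Gaussian measurement
    noise and (optionally) a slow sinusoidal modulation
    ``oscillation=(amplitude_fraction, period_hours)``.  ``cell_sd`` and
    ``onset_jitter`` add per-cell heterogeneity in asymptote and onset
    (off by default: the group curve is shared and cells differ only by
    measurement noise).  Onsets and slopes must be positive.  Returns a tidy
    frame with columns (cell_id, group, time_h, pct_area_change); the first
    value of each cell's series is exactly 0 by construction.
    """
    if min(onsets) <= 0 or min(slopes) <= 0:
        raise ValueError("onsets and slopes must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(t_start, t_end + 1e-9, dt_hours)
    rows = []
    cid = 0
    for g, onset, A, mu in zip(groups, onsets, asymptotes, slopes):
        for _ in range(n_cells_per_group):
            cid += 1
            A_c = A * float(rng.lognormal(0.0, cell_sd))
            onset_c = onset + float(rng.normal(0.0, onset_jitter))
            pct = A_c / (1.0 + np.exp((4.0 * mu / A_c) * (onset_c - t) + 2.0))
            area = 1.0 + pct / 100.0
            if oscillation is not None:
                amp, period = oscillation
                phase = float(rng.uniform(0.0, 2.0 * math.pi))
                area = area * (1.0 + amp * np.sin(2.0 * math.pi * (t - t_start) / period + phase))
            if noise_sd > 0:
                area = area * (1.0 + noise_sd * rng.standard_normal(t.shape))
            pct_obs = 100.0 * (area / area[0] - 1.0)
            for tt, p in zip(t, pct_obs):
                rows.append((cid, g, float(tt), float(p)))
    return pd.DataFrame(rows, columns=["cell_id", "group", "time_h", "pct_area_change"])
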