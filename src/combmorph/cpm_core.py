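"""2D cellular Potts engine for epithelial tissue simulation.

The model: the plane is a ``n_x x n_y`` pixel lattice, periodic in x (the
leg epithelium is a cylinder) and open in y (no-flux at the top; an
immobile barrier of BA cells forms the bottom).  Each pixel carries a cell
index sigma; a cell is the set of pixels with that index and has a type
``c`` in {EP1, EP2, EP3, SCT, BA}.  The effective energy is

    H = H_boundary + H_length + H_area

with an adhesion term J(c1, c2) summed once over every unordered
heterocellular contact pair (von Neumann neighbourhood) -- the convention
of the standard contact-energy implementations, so published J tables keep
their meaning -- and quadratic penalties on the deviation of each cell's
principal-axis length and area from per-cell targets.  Cells with an axial
expansion preference (epsilon > 0) use a direction-weighted area term
during flip attempts.

Dynamics are Metropolis pixel-copy attempts: a random target pixel may be
conquered by a random Moore-neighbouring pixel's cell; the move is accepted
with probability min(1, exp(-dH/T)).  BA cells are frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _kernels
from ._kernels import BA, EP1, EP2, EP3, SCT

CELL_TYPES = ("EP1", "EP2", "EP3", "SCT", "BA")
TYPE_CODE = {"EP1": EP1, "EP2": EP2, "EP3": EP3, "SCT": SCT, "BA": BA}
TYPE_NAME = {v: k for k, v in TYPE_CODE.items()}


def seed_rng(seed: int) -> None:
    """Seed the in-kernel RNG used by :func:`run_mcs` / :func:`attempt_flip`."""
    _kernels.seed_rng(int(seed) & 0x7FFFFFFF)


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimParams:
    """System-wide run parameters (defaults: the standard single-resolution
    comb setup: T = 100, order-2 flip neighbourhood, 9576 attempts per mcs,
    2000 mcs on a 114 x 84 lattice)."""

    temperature: float = 100.0
    neighbour_order: int = 2
    flips_per_mcs: int = 9576
    duration: int = 2000
    n_x: int = 114
    n_y: int = 84
    seed: int = 0

    def __post_init__(self):
        if self.flips_per_mcs <= 0:
            raise ValueError("flips_per_mcs must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


class AdhesionTable:
    """Symmetric contact-energy table J(c1, c2) over cell-type names."""

    def __init__(self, entries: Mapping[tuple[str, str], float] | None = None):
        self._J = np.zeros((6, 6), dtype=np.float64)
        if entries:
            for (c1, c2), v in entries.items():
                self.set(c1, c2, v)

    def set(self, c1: str, c2: str, value: float) -> None:
        i, j = TYPE_CODE[c1], TYPE_CODE[c2]
        self._J[i, j] = value
        self._J[j, i] = value

    def get(self, c1: str, c2: str) -> float:
        return float(self._J[TYPE_CODE[c1], TYPE_CODE[c2]])

    @property
    def matrix(self) -> np.ndarray:
        """6x6 lookup indexed by type code (row/col 0 unused)."""
        return self._J

    def copy(self) -> "AdhesionTable":
        t = AdhesionTable()
        t._J = self._J.copy()
        return t


# --------------------------------------------------------------------------
# lattice state
# --------------------------------------------------------------------------


@dataclass
class CellState:
    """Read-only snapshot of one cell's bookkeeping."""

    sigma: int
    type: str
    area: int
    com: tuple[float, float]
    length: float
    a_target: float
    l_target: float
    lambda_a: float
    lambda_l: float
    extruded: bool


@dataclass
class FlipProposal:
    """A candidate pixel flip: ``target`` taken over by ``invading``'s cell.

    ``com_target`` / ``com_invading`` freeze the pre-flip centres of mass of
    the two cells so the axial weight is evaluated with one consistent
    geometry in both the before and after energies.
    """

    target: tuple[int, int]
    invading: tuple[int, int]
    target_sigma: int
    invading_sigma: int
    com_target: tuple[float, float] | None = None
    com_invading: tuple[float, float] | None = None

    def theta_r(self, which: str, n_x: int, ) -> tuple[float, float]:
        """Angle (degrees, from +x axis) and distance from the chosen cell's
        pre-flip CoM to the target pixel, minimal-image in x."""
        com = self.com_target if which == "target" else self.com_invading
        dx = self.target[0] - com[0]
        dx -= n_x * round(dx / n_x)
        dy = self.target[1] - com[1]
        return math.degrees(math.atan2(dy, dx)), math.hypot(dx, dy)


class LatticeState:
    """The mutable simulation state: pixel grid plus per-cell bookkeeping.

    Per-cell arrays are indexed by cell index sigma (index 0 unused).  The
    x coordinate sums are unwrapped (see :mod:`combmorph._kernels`).
    """

    def __init__(
        self,
        grid: np.ndarray,
        cell_types: Sequence[int] | np.ndarray,
        params: SimParams,
        adhesion: AdhesionTable,
        eps_type: Mapping[str, float] | None = None,
        r_squared_mode: bool = False,
        strict_unwrap: bool = False,
    ):
        grid = np.ascontiguousarray(grid, dtype=np.int32)
        if grid.shape != (params.n_x, params.n_y):
            raise ValueError(
                f"grid shape {grid.shape} does not match params ({params.n_x}, {params.n_y})"
            )
        self.grid = grid
        self.params = params
        self.adhesion = adhesion
        self.time = 0
        self.tooth_ids: list[int] = []
        self.r_squared_mode = bool(r_squared_mode)
        # when set, refuse cells wider than half the lattice (ambiguous
        # periodic unwrap); enabled for generated simulation configurations
        self.strict_unwrap = bool(strict_unwrap)

        n_cells = int(grid.max())
        ct = np.zeros(n_cells + 1, dtype=np.uint8)
        ct[1:] = np.asarray(cell_types, dtype=np.uint8)[: n_cells]
        self.ctype = ct

        self.eps_type = np.zeros(6, dtype=np.float64)
        if eps_type:
            for name, v in eps_type.items():
                self.eps_type[TYPE_CODE[name]] = v

        self.area = np.zeros(n_cells + 1, dtype=np.int64)
        self.sum_x = np.zeros(n_cells + 1, dtype=np.float64)
        self.sum_y = np.zeros(n_cells + 1, dtype=np.float64)
        self.sum_xx = np.zeros(n_cells + 1, dtype=np.float64)
        self.sum_yy = np.zeros(n_cells + 1, dtype=np.float64)
        self.sum_xy = np.zeros(n_cells + 1, dtype=np.float64)
        self.a_target = np.zeros(n_cells + 1, dtype=np.float64)
        self.l_target = np.zeros(n_cells + 1, dtype=np.float64)
        self.lambda_a = np.zeros(n_cells + 1, dtype=np.float64)
        self.lambda_l = np.zeros(n_cells + 1, dtype=np.float64)
        self.extruded = np.zeros(n_cells + 1, dtype=bool)
        self._ever_alive = np.zeros(n_cells + 1, dtype=bool)
        self._rebuild_sums()
        self._ever_alive[:] = self.area > 0

    # -- bookkeeping -------------------------------------------------------

    def _rebuild_sums(self) -> None:
        """Recompute per-cell area/coordinate sums from the grid."""
        nx, ny = self.grid.shape
        n = self.area.shape[0]
        self.area[:] = 0
        for arr in (self.sum_x, self.sum_y, self.sum_xx, self.sum_yy, self.sum_xy):
            arr[:] = 0.0
        flat = self.grid.ravel()
        self.area[:] = np.bincount(flat, minlength=n)
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        # unwrap x per cell: anchor at each cell's first pixel
        order = np.argsort(flat, kind="stable")
        sig_sorted = flat[order]
        x_sorted = xs.ravel()[order].astype(np.float64)
        y_sorted = ys.ravel()[order].astype(np.float64)
        starts = np.searchsorted(sig_sorted, np.arange(n))
        ends = np.searchsorted(sig_sorted, np.arange(n), side="right")
        for sig in range(1, n):
            lo, hi = starts[sig], ends[sig]
            if lo == hi:
                continue
            x = x_sorted[lo:hi]
            y = y_sorted[lo:hi]
            anchor = x[0]
            xu = anchor + (x - anchor) - nx * np.rint((x - anchor) / nx)
            ext = xu.max() - xu.min()
            if ext >= nx / 2 and self.strict_unwrap:
                raise ValueError(
                    f"cell {sig} x-extent {ext} exceeds half the lattice width; "
                    "periodic unwrap is ambiguous"
                )
            self.sum_x[sig] = xu.sum()
            self.sum_y[sig] = y.sum()
            self.sum_xx[sig] = (xu * xu).sum()
            self.sum_yy[sig] = (y * y).sum()
            self.sum_xy[sig] = (xu * y).sum()

    def check_consistency(self, atol: float = 1e-9) -> None:
        """Assert the incremental bookkeeping matches a recomputation from
        the grid (debug invariant)."""
        saved = {
            name: getattr(self, name).copy()
            for name in ("area", "sum_x", "sum_y", "sum_xx", "sum_yy", "sum_xy")
        }
        self._rebuild_sums()
        try:
            if not np.array_equal(saved["area"], self.area):
                raise AssertionError("per-cell areas inconsistent with grid")
            for name in ("sum_y", "sum_yy"):
                if not np.allclose(saved[name], getattr(self, name), atol=atol):
                    raise AssertionError(f"{name} inconsistent with grid")
            # x sums may differ by a multiple of n_x per pixel (choice of
            # periodic image); compare CoM modulo n_x and central moments
            nx = self.params.n_x
            alive = self.area > 0
            n = np.where(alive, self.area, 1).astype(float)
            for a, b in ((saved["sum_x"], self.sum_x),):
                d = (a - b) / n
                d -= nx * np.rint(d / nx)
                if not np.allclose(d[alive], 0.0, atol=atol):
                    raise AssertionError("CoM x inconsistent with grid")
            var_a = saved["sum_xx"] / n - (saved["sum_x"] / n) ** 2
            var_b = self.sum_xx / n - (self.sum_x / n) ** 2
            if not np.allclose(var_a[alive], var_b[alive], atol=1e-6):
                raise AssertionError("x variance inconsistent with grid")
            cov_a = saved["sum_xy"] / n - (saved["sum_x"] / n) * (saved["sum_y"] / n)
            cov_b = self.sum_xy / n - (self.sum_x / n) * (self.sum_y / n)
            if not np.allclose(cov_a[alive], cov_b[alive], atol=1e-6):
                raise AssertionError("xy covariance inconsistent with grid")
        finally:
            for name, arr in saved.items():
                getattr(self, name)[:] = arr

    # -- views -------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.area.shape[0] - 1

    def alive_sigmas(self) -> np.ndarray:
        return np.nonzero(self.area > 0)[0]

    def cell(self, sigma: int) -> CellState:
        n = self.area[sigma]
        if n > 0:
            com = (float(self.sum_x[sigma] / n) % self.params.n_x, float(self.sum_y[sigma] / n))
            length = float(
                _kernels._length_from_sums(
                    n, self.sum_x[sigma], self.sum_y[sigma],
                    self.sum_xx[sigma], self.sum_yy[sigma], self.sum_xy[sigma],
                )
            )
        else:
            com = (float("nan"), float("nan"))
            length = 0.0
        return CellState(
            sigma=int(sigma),
            type=TYPE_NAME[int(self.ctype[sigma])],
            area=int(n),
            com=com,
            length=length,
            a_target=float(self.a_target[sigma]),
            l_target=float(self.l_target[sigma]),
            lambda_a=float(self.lambda_a[sigma]),
            lambda_l=float(self.lambda_l[sigma]),
            extruded=bool(self.extruded[sigma]),
        )

    @property
    def cells(self) -> dict[int, CellState]:
        return {int(s): self.cell(s) for s in range(1, self.n_cells + 1) if self._ever_alive[s]}

    def copy(self) -> "LatticeState":
        new = object.__new__(LatticeState)
        new.grid = self.grid.copy()
        new.params = self.params
        new.adhesion = self.adhesion.copy()
        new.time = self.time
        new.tooth_ids = list(self.tooth_ids)
        new.r_squared_mode = self.r_squared_mode
        new.strict_unwrap = self.strict_unwrap
        new.eps_type = self.eps_type.copy()
        new.ctype = self.ctype.copy()
        for name in (
            "area", "sum_x", "sum_y", "sum_xx", "sum_yy", "sum_xy",
            "a_target", "l_target", "lambda_a", "lambda_l", "extruded",
            "_ever_alive",
        ):
            setattr(new, name, getattr(self, name).copy())
        return new


# --------------------------------------------------------------------------
# neighbourhoods
# --------------------------------------------------------------------------


def _check_in_lattice(p: tuple[int, int], dims: tuple[int, int]) -> None:
    x, y = p
    nx, ny = dims
    if not (0 <= x < nx and 0 <= y < ny):
        raise ValueError(f"pixel {p} outside lattice {dims}")


def contact_neighbours(p: tuple[int, int], lattice_dims: tuple[int, int]) -> list[tuple[int, int]]:
    """Von Neumann (order-1) neighbours used for the adhesion term; x wraps
    periodically, out-of-range y neighbours are omitted."""
    _check_in_lattice(p, lattice_dims)
    x, y = p
    nx, ny = lattice_dims
    out = [((x - 1) % nx, y), ((x + 1) % nx, y)]
    if y - 1 >= 0:
        out.append((x, y - 1))
    if y + 1 < ny:
        out.append((x, y + 1))
    return out


def flip_neighbours(p: tuple[int, int], lattice_dims: tuple[int, int]) -> list[tuple[int, int]]:
    """Moore (order-2) neighbours from which invading pixels are drawn."""
    _check_in_lattice(p, lattice_dims)
    x, y = p
    nx, ny = lattice_dims
    out = []
    for ox, oy in ((-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)):
        qy = y + oy
        if qy < 0 or qy >= ny:
            continue
        out.append(((x + ox) % nx, qy))
    return out


def cell_length(pixels: Iterable[tuple[int, int]], n_x: int | None = None) -> float:
    """Length of a pixel set along its principal axis.

    sqrt(12 * lambda_max) of the covariance of pixel centres smeared by the
    unit-square term I/12: a filled s x s square has length exactly s and a
    single pixel has length 1.  If ``n_x`` is given, x coordinates are
    unwrapped by minimal image around the first pixel (x-extent must stay
    below n_x/2).
    """
    pts = np.asarray(list(pixels), dtype=np.float64)
    if pts.size == 0:
        raise ValueError("cell has no pixels")
    x = pts[:, 0]
    y = pts[:, 1]
    if n_x is not None:
        anchor = x[0]
        x = anchor + (x - anchor) - n_x * np.rint((x - anchor) / n_x)
        if x.max() - x.min() >= n_x / 2:
            raise ValueError("x-extent exceeds half the lattice width")
    n = len(x)
    return float(
        _kernels._length_from_sums(
            n, x.sum(), y.sum(), (x * x).sum(), (y * y).sum(), (x * y).sum()
        )
    )


# --------------------------------------------------------------------------
# energies
# --------------------------------------------------------------------------


def make_proposal(lattice: LatticeState, target: tuple[int, int], invading: tuple[int, int]) -> FlipProposal:
    """Build a flip proposal, freezing the pre-flip CoMs of the two cells."""
    sig_t = int(lattice.grid[target])
    sig_i = int(lattice.grid[invading])
    if sig_t == sig_i:
        raise ValueError("target and invading pixel belong to the same cell")

    def com(s):
        n = lattice.area[s]
        return (float(lattice.sum_x[s] / n), float(lattice.sum_y[s] / n))

    return FlipProposal(
        target=tuple(map(int, target)),
        invading=tuple(map(int, invading)),
        target_sigma=sig_t,
        invading_sigma=sig_i,
        com_target=com(sig_t),
        com_invading=com(sig_i),
    )


def _axial_weight_py(lattice, sigma, com, flip_ctx):
    eps = float(lattice.eps_type[lattice.ctype[sigma]])
    if eps <= 0.0 or flip_ctx is None:
        return 1.0
    if sigma not in (flip_ctx.target_sigma, flip_ctx.invading_sigma):
        return 1.0
    nx = lattice.params.n_x
    tx, ty = flip_ctx.target
    dx = tx - com[0]
    dx -= nx * round(dx / nx)
    dy = ty - com[1]
    r2 = dx * dx + dy * dy
    if r2 <= 1e-24:
        s2, r = 0.0, 0.5
    else:
        s2 = dy * dy / r2
        r = max(math.sqrt(r2), 0.5)
    denom = r * r if lattice.r_squared_mode else r
    return 1.0 - eps * (1.0 - s2 / denom)


def hamiltonian(lattice: LatticeState, flip_ctx: FlipProposal | None = None, breakdown: bool = False):
    """Full (global) effective energy; the independent oracle for the
    incremental ``delta_h``.

    With ``flip_ctx``, the area term of the two cells named by the proposal
    uses the axially weighted form (when their type has epsilon > 0),
    evaluated at the proposal's frozen pre-flip CoMs so the same geometry
    applies before and after a flip.  Cells retired at area 0 contribute
    their constant lambda_a*a_target^2 + lambda_l*l_target^2.
    """
    g = lattice.grid
    nx, ny = g.shape
    J = lattice.adhesion.matrix
    ct_of = lattice.ctype

    # boundary: each unordered heterocellular contact counted once
    ct_grid = ct_of[g]
    hb = 0.0
    gn = np.roll(g, 1, axis=0)  # x neighbour, periodic
    cn = np.roll(ct_grid, 1, axis=0)
    mask = gn != g
    hb += J[ct_grid[mask], cn[mask]].sum()
    mask = g[:, 1:] != g[:, :-1]  # y neighbour, truncated
    hb += J[ct_grid[:, 1:][mask], ct_grid[:, :-1][mask]].sum()

    ha = 0.0
    hl = 0.0
    for sig in range(1, lattice.n_cells + 1):
        if not lattice._ever_alive[sig]:
            continue
        n = lattice.area[sig]
        lam_a = lattice.lambda_a[sig]
        lam_l = lattice.lambda_l[sig]
        if n == 0:
            ha += lam_a * lattice.a_target[sig] ** 2
            hl += lam_l * lattice.l_target[sig] ** 2
            continue
        com = (lattice.sum_x[sig] / n, lattice.sum_y[sig] / n)
        w = _axial_weight_py(lattice, sig, _ctx_com(lattice, sig, flip_ctx, com), flip_ctx)
        ha += lam_a * w * (n - lattice.a_target[sig]) ** 2
        length = _kernels._length_from_sums(
            n, lattice.sum_x[sig], lattice.sum_y[sig],
            lattice.sum_xx[sig], lattice.sum_yy[sig], lattice.sum_xy[sig],
        )
        hl += lam_l * (length - lattice.l_target[sig]) ** 2
    if breakdown:
        return {"boundary": float(hb), "length": float(hl), "area": float(ha),
                "total": float(hb + hl + ha)}
    return float(hb + hl + ha)


def _ctx_com(lattice, sigma, flip_ctx, default_com):
    if flip_ctx is None:
        return default_com
    if sigma == flip_ctx.target_sigma and flip_ctx.com_target is not None:
        return flip_ctx.com_target
    if sigma == flip_ctx.invading_sigma and flip_ctx.com_invading is not None:
        return flip_ctx.com_invading
    return default_com


def delta_h(lattice: LatticeState, proposal: FlipProposal) -> float:
    """Incremental energy change of the proposed flip (H1 - H0)."""
    if proposal.target_sigma == proposal.invading_sigma:
        raise ValueError("same-cell proposal")
    ct = lattice.ctype
    if ct[proposal.target_sigma] == BA or ct[proposal.invading_sigma] == BA:
        raise ValueError("BA cells are frozen; proposals involving BA are invalid")
    tx, ty = proposal.target
    return float(
        _kernels.delta_h_kernel(
            lattice.grid, lattice.ctype, lattice.area,
            lattice.sum_x, lattice.sum_y, lattice.sum_xx, lattice.sum_yy, lattice.sum_xy,
            lattice.a_target, lattice.l_target, lattice.lambda_a, lattice.lambda_l,
            lattice.eps_type, lattice.adhesion.matrix,
            tx, ty, proposal.target_sigma, proposal.invading_sigma,
            lattice.r_squared_mode,
        )
    )


def apply_flip(lattice: LatticeState, proposal: FlipProposal) -> None:
    """Apply an (accepted) proposal to the lattice in place."""
    tx, ty = proposal.target
    _kernels.apply_flip_kernel(
        lattice.grid, lattice.area,
        lattice.sum_x, lattice.sum_y, lattice.sum_xx, lattice.sum_yy, lattice.sum_xy,
        tx, ty, proposal.target_sigma, proposal.invading_sigma,
    )


def metropolis_decide(dh: float, temperature: float, u: float) -> bool:
    """Metropolis acceptance rule: certain for dh < 0, else accept when the
    uniform draw u < exp(-dh/T)."""
    if dh < 0.0:
        return True
    return u < math.exp(-dh / temperature)


def attempt_flip(lattice: LatticeState, rng: np.random.Generator) -> bool:
    """One Metropolis attempt with an explicit numpy Generator.

    Returns True iff a flip was accepted and applied.  Same-cell pairs,
    out-of-lattice neighbours and BA involvement are rejected no-ops.
    """
    nx, ny = lattice.grid.shape
    tx = int(rng.integers(nx))
    ty = int(rng.integers(ny))
    ox, oy = _kernels._MOORE[int(rng.integers(8))]
    iy = ty + int(oy)
    if iy < 0 or iy >= ny:
        return False
    ix = (tx + int(ox)) % nx
    sig_t = int(lattice.grid[tx, ty])
    sig_i = int(lattice.grid[ix, iy])
    if sig_t == sig_i:
        return False
    if lattice.ctype[sig_t] == BA or lattice.ctype[sig_i] == BA:
        return False
    prop = FlipProposal(
        target=(tx, ty), invading=(ix, iy),
        target_sigma=sig_t, invading_sigma=sig_i,
    )
    dh = delta_h(lattice, prop)
    if not metropolis_decide(dh, lattice.params.temperature, float(rng.random())):
        return False
    apply_flip(lattice, prop)
    return True


def run_mcs(lattice: LatticeState, n_mcs: int = 1) -> LatticeState:
    """Advance the lattice by ``n_mcs`` Monte Carlo steps in place (one mcs =
    ``flips_per_mcs`` attempts).  Uses the in-kernel RNG; call
    :func:`seed_rng` first for reproducibility."""
    for _ in range(n_mcs):
        _kernels.run_attempts_kernel(
            lattice.grid, lattice.ctype, lattice.area,
            lattice.sum_x, lattice.sum_y, lattice.sum_xx, lattice.sum_yy, lattice.sum_xy,
            lattice.a_target, lattice.l_target, lattice.lambda_a, lattice.lambda_l,
            lattice.eps_type, lattice.adhesion.matrix,
            lattice.params.temperature, lattice.params.flips_per_mcs,
            lattice.r_squared_mode,
        )
        lattice.time += 1
    return lattice
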