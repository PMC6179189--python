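"""Numba kernels for the cellular Potts engine.

Everything here operates on the flat array representation held by
:class:`combmorph.cpm_core.LatticeState`:

* ``grid[x, y]`` -- cell index per pixel,
* per-cell bookkeeping arrays indexed by cell index (area, coordinate sums
  for centre of mass and the covariance-based length, target values and
  per-cell stiffnesses).

x-coordinate sums are kept in *unwrapped* form: each pixel is stored at the
periodic image closest to the cell's current mean, so centre of mass and
length are well defined on the cylinder as long as a cell's x-extent stays
below half the lattice width.

The in-kernel RNG is numba's thread-local Mersenne Twister; call
:func:`seed_rng` once at the start of a run for reproducibility.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# cell type codes (also the VTK type field)
EP1, EP2, EP3, SCT, BA = 1, 2, 3, 4, 5

# Moore (order-2) neighbourhood offsets
_MOORE = np.array(
    [(-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1)],
    dtype=np.int64,
)


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _length_from_sums(n, sx, sy, sxx, syy, sxy):
    """Principal-axis length sqrt(12*lambda_max) of the unit-square-smeared
    pixel covariance; exactly the side length for filled squares and 1 for a
    single pixel."""
    if n <= 0:
        return 0.0
    fn = float(n)
    mx = sx / fn
    my = sy / fn
    cxx = sxx / fn - mx * mx + 1.0 / 12.0
    cyy = syy / fn - my * my + 1.0 / 12.0
    cxy = sxy / fn - mx * my
    half_tr = 0.5 * (cxx + cyy)
    det = np.sqrt(0.25 * (cxx - cyy) ** 2 + cxy * cxy)
    lam = half_tr + det
    if lam < 0.0:
        lam = 0.0
    return np.sqrt(12.0 * lam)


@njit(cache=True, inline="always")
def _unwrap_x(x, sum_x, n, nx):
    """Periodic image of column x closest to the cell's unwrapped mean."""
    return x + nx * np.rint((sum_x / n - x) / nx)


@njit(cache=True, inline="always")
def _axial_weight(tx, ty, sum_x, sum_y, n, nx, eps, r_squared_mode):
    """Axial-preference factor 1 - eps*(1 - sin^2(theta)/R) for the vector
    from a cell's (pre-flip) centre of mass to the target pixel.

    R is clamped below at 0.5 pixel; at R == 0 the direction is undefined and
    the isotropic sin^2 = 0 branch is used.  In double-resolution mode R is
    replaced by R^2 to preserve the relative scale.
    """
    comx = sum_x / n
    comy = sum_y / n
    dx = tx - comx
    dx -= nx * np.rint(dx / nx)
    dy = ty - comy
    r2 = dx * dx + dy * dy
    if r2 <= 1e-24:
        s2 = 0.0
        r = 0.5
    else:
        s2 = dy * dy / r2
        r = np.sqrt(r2)
        if r < 0.5:
            r = 0.5
    denom = r * r if r_squared_mode else r
    return 1.0 - eps * (1.0 - s2 / denom)


@njit(cache=True)
def delta_h_kernel(
    grid,
    ctype,
    area,
    sum_x,
    sum_y,
    sum_xx,
    sum_yy,
    sum_xy,
    a_target,
    l_target,
    lambda_a,
    lambda_l,
    eps_type,
    J,
    tx,
    ty,
    sig_t,
    sig_i,
    r_squared_mode,
):
    """Energy change for flipping pixel (tx, ty) from cell sig_t to sig_i.

    Incremental: only the contact links touching the target pixel and the
    area/length terms of the two affected cells are revisited.  Each
    unordered heterocellular contact contributes J once.
    """
    nx, ny = grid.shape
    ct = ctype[sig_t]
    ci = ctype[sig_i]

    # --- boundary term over the 4 contact neighbours -----------------------
    db = 0.0
    for k in range(4):
        if k == 0:
            qx, qy = tx - 1, ty
        elif k == 1:
            qx, qy = tx + 1, ty
        elif k == 2:
            qx, qy = tx, ty - 1
        else:
            qx, qy = tx, ty + 1
        if qy < 0 or qy >= ny:
            continue
        if qx < 0:
            qx += nx
        elif qx >= nx:
            qx -= nx
        sq = grid[qx, qy]
        cq = ctype[sq]
        if sq != sig_t:
            db -= J[ct, cq]
        if sq != sig_i:
            db += J[ci, cq]
    dh = db

    # --- axial weights (pre-flip CoM, used for both H0 and H1) -------------
    wt = 1.0
    et = eps_type[ct]
    if et > 0.0:
        wt = _axial_weight(tx, ty, sum_x[sig_t], sum_y[sig_t], area[sig_t], nx, et, r_squared_mode)
    wi = 1.0
    ei = eps_type[ci]
    if ei > 0.0:
        wi = _axial_weight(tx, ty, sum_x[sig_i], sum_y[sig_i], area[sig_i], nx, ei, r_squared_mode)

    # --- area terms --------------------------------------------------------
    at = float(area[sig_t])
    ai = float(area[sig_i])
    dat = at - a_target[sig_t]
    dai = ai - a_target[sig_i]
    dh += lambda_a[sig_t] * wt * ((dat - 1.0) ** 2 - dat * dat)
    dh += lambda_a[sig_i] * wi * ((dai + 1.0) ** 2 - dai * dai)

    # --- length terms ------------------------------------------------------
    if lambda_l[sig_t] != 0.0:
        n_t = area[sig_t]
        l0 = _length_from_sums(n_t, sum_x[sig_t], sum_y[sig_t], sum_xx[sig_t], sum_yy[sig_t], sum_xy[sig_t])
        xu = _unwrap_x(tx, sum_x[sig_t], n_t, nx)
        l1 = _length_from_sums(
            n_t - 1,
            sum_x[sig_t] - xu,
            sum_y[sig_t] - ty,
            sum_xx[sig_t] - xu * xu,
            sum_yy[sig_t] - ty * ty,
            sum_xy[sig_t] - xu * ty,
        )
        dh += lambda_l[sig_t] * ((l1 - l_target[sig_t]) ** 2 - (l0 - l_target[sig_t]) ** 2)
    if lambda_l[sig_i] != 0.0:
        n_i = area[sig_i]
        l0 = _length_from_sums(n_i, sum_x[sig_i], sum_y[sig_i], sum_xx[sig_i], sum_yy[sig_i], sum_xy[sig_i])
        xu = _unwrap_x(tx, sum_x[sig_i], n_i, nx)
        l1 = _length_from_sums(
            n_i + 1,
            sum_x[sig_i] + xu,
            sum_y[sig_i] + ty,
            sum_xx[sig_i] + xu * xu,
            sum_yy[sig_i] + ty * ty,
            sum_xy[sig_i] + xu * ty,
        )
        dh += lambda_l[sig_i] * ((l1 - l_target[sig_i]) ** 2 - (l0 - l_target[sig_i]) ** 2)
    return dh


@njit(cache=True)
def apply_flip_kernel(
    grid,
    area,
    sum_x,
    sum_y,
    sum_xx,
    sum_yy,
    sum_xy,
    tx,
    ty,
    sig_t,
    sig_i,
):
    """Realize an accepted flip: reassign the pixel and update bookkeeping.
    Returns True if the losing cell was retired (area hit 0)."""
    nx = grid.shape[0]
    xu = _unwrap_x(tx, sum_x[sig_t], area[sig_t], nx)
    sum_x[sig_t] -= xu
    sum_y[sig_t] -= ty
    sum_xx[sig_t] -= xu * xu
    sum_yy[sig_t] -= ty * ty
    sum_xy[sig_t] -= xu * ty
    area[sig_t] -= 1

    xu = _unwrap_x(tx, sum_x[sig_i], area[sig_i], nx)
    sum_x[sig_i] += xu
    sum_y[sig_i] += ty
    sum_xx[sig_i] += xu * xu
    sum_yy[sig_i] += ty * ty
    sum_xy[sig_i] += xu * ty
    area[sig_i] += 1

    grid[tx, ty] = sig_i
    if area[sig_t] == 0:
        sum_x[sig_t] = 0.0
        sum_y[sig_t] = 0.0
        sum_xx[sig_t] = 0.0
        sum_yy[sig_t] = 0.0
        sum_xy[sig_t] = 0.0
        return True
    return False


@njit(cache=True)
def run_attempts_kernel(
    grid,
    ctype,
    area,
    sum_x,
    sum_y,
    sum_xx,
    sum_yy,
    sum_xy,
    a_target,
    l_target,
    lambda_a,
    lambda_l,
    eps_type,
    J,
    temperature,
    n_attempts,
    r_squared_mode,
):
    """Perform a block of Metropolis pixel-flip attempts in place.

    Targets and flip neighbours are drawn uniformly; a neighbour falling
    outside the open top/bottom boundaries, a same-cell pair, or any BA
    involvement is a rejected no-op.  Returns the number of accepted flips.
    """
    nx, ny = grid.shape
    accepted = 0
    for _ in range(n_attempts):
        tx = np.random.randint(0, nx)
        ty = np.random.randint(0, ny)
        k = np.random.randint(0, 8)
        ox = _MOORE[k, 0]
        oy = _MOORE[k, 1]
        iy = ty + oy
        if iy < 0 or iy >= ny:
            continue
        ix = tx + ox
        if ix < 0:
            ix += nx
        elif ix >= nx:
            ix -= nx
        sig_t = grid[tx, ty]
        sig_i = grid[ix, iy]
        if sig_t == sig_i:
            continue
        if ctype[sig_t] == BA or ctype[sig_i] == BA:
            continue
        dh = delta_h_kernel(
            grid, ctype, area, sum_x, sum_y, sum_xx, sum_yy, sum_xy,
            a_target, l_target, lambda_a, lambda_l, eps_type, J,
            tx, ty, sig_t, sig_i, r_squared_mode,
        )
        if dh >= 0.0:
            if np.random.random() >= np.exp(-dh / temperature):
                continue
        apply_flip_kernel(
            grid, area, sum_x, sum_y, sum_xx, sum_yy, sum_xy,
            tx, ty, sig_t, sig_i,
        )
        accepted += 1
    return accepted
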