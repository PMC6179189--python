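import numpy as np
import pytest

from combmorph.cpm_core import AdhesionTable, LatticeState, SimParams


def brute_force_hamiltonian(lattice, flip_ctx=None):
    """Independent slow oracle: enumerate every pixel and every cell
    directly from the grid (single count of unordered contact pairs)."""
    import math

    g = lattice.grid
    nx, ny = g.shape
    J = lattice.adhesion.matrix
    ct = lattice.ctype
    hb = 0.0
    for x in range(nx):
        for y in range(ny):
            s = g[x, y]
            # right neighbour (periodic) and up neighbour (truncated)
            s2 = g[(x + 1) % nx, y]
            if s2 != s:
                hb += J[ct[s], ct[s2]]
            if y + 1 < ny:
                s2 = g[x, y + 1]
                if s2 != s:
                    hb += J[ct[s], ct[s2]]
    ha = 0.0
    hl = 0.0
    for sig in range(1, lattice.n_cells + 1):
        if not lattice._ever_alive[sig]:
            continue
        xs, ys = np.nonzero(g == sig)
        lam_a = lattice.lambda_a[sig]
        lam_l = lattice.lambda_l[sig]
        if len(xs) == 0:
            ha += lam_a * lattice.a_target[sig] ** 2
            hl += lam_l * lattice.l_target[sig] ** 2
            continue
        # unwrap x around first pixel
        xs = xs.astype(float)
        xs = xs[0] + (xs - xs[0]) - nx * np.rint((xs - xs[0]) / nx)
        ys = ys.astype(float)
        n = len(xs)
        w = 1.0
        if flip_ctx is not None and sig in (flip_ctx.target_sigma, flip_ctx.invading_sigma):
            eps = lattice.eps_type[ct[sig]]
            if eps > 0:
                com = (
                    flip_ctx.com_target
                    if sig == flip_ctx.target_sigma
                    else flip_ctx.com_invading
                )
                dx = flip_ctx.target[0] - com[0]
                dx -= nx * round(dx / nx)
                dy = flip_ctx.target[1] - com[1]
                r2 = dx * dx + dy * dy
                if r2 <= 1e-24:
                    s2t, r = 0.0, 0.5
                else:
                    s2t = dy * dy / r2
                    r = max(math.sqrt(r2), 0.5)
                denom = r * r if lattice.r_squared_mode else r
                w = 1.0 - eps * (1.0 - s2t / denom)
        ha += lam_a * w * (n - lattice.a_target[sig]) ** 2
        cxx = xs.var() + 1.0 / 12.0
        cyy = ys.var() + 1.0 / 12.0
        cxy = ((xs - xs.mean()) * (ys - ys.mean())).mean()
        lam = 0.5 * (cxx + cyy) + math.sqrt(0.25 * (cxx - cyy) ** 2 + cxy**2)
        length = math.sqrt(12.0 * max(lam, 0.0))
        hl += lam_l * (length - lattice.l_target[sig]) ** 2
    return hb + ha + hl


def random_lattice(rng, nx=20, ny=20, n_cells=14, with_eps=True, temperature=100.0):
    """Random periodic Voronoi partition with random mechanical parameters;
    cells are kept narrower than half the lattice so the periodic unwrap of
    centre of mass and length is unambiguous."""
    for _ in range(50):
        seeds_x = rng.uniform(0, nx, n_cells)
        seeds_y = rng.uniform(0, ny, n_cells)
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        dx = np.abs(xs[..., None] - seeds_x[None, None, :])
        dx = np.minimum(dx, nx - dx)
        dy = ys[..., None] - seeds_y[None, None, :]
        grid = np.argmin(dx**2 + dy**2, axis=-1) + 1
        types = [int(rng.integers(1, 5)) for _ in range(n_cells)]  # EP1..SCT, no BA
        params = SimParams(
            temperature=temperature, flips_per_mcs=nx * ny, n_x=nx, n_y=ny
        )
        adhesion = AdhesionTable()
        names = ("EP1", "EP2", "EP3", "SCT", "BA")
        for i, c1 in enumerate(names):
            for c2 in names[i:]:
                adhesion.set(c1, c2, float(rng.integers(0, 2000)))
        eps = {"EP1": 0.03, "EP2": 0.05} if with_eps else None
        try:
            lat = LatticeState(
                grid, types, params, adhesion, eps_type=eps, strict_unwrap=True
            )
        except ValueError:
            continue
        alive = lat.area > 0
        k = int(alive.sum())
        lat.a_target[alive] = lat.area[alive] + rng.uniform(-3, 3, k)
        lat.l_target[alive] = rng.uniform(1, 6, k)
        lat.lambda_a[alive] = rng.uniform(0, 50, k)
        lat.lambda_l[alive] = rng.uniform(0, 10, k)
        return lat
    raise RuntimeError("could not build a valid random lattice")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
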