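"""Engine unit tests: neighbourhoods, length, energies, Metropolis."""

import math

import numpy as np
import pytest

from combmorph import _kernels
from combmorph.cpm_core import (
    AdhesionTable,
    LatticeState,
    SimParams,
    apply_flip,
    attempt_flip,
    cell_length,
    contact_neighbours,
    delta_h,
    flip_neighbours,
    hamiltonian,
    make_proposal,
    metropolis_decide,
    run_mcs,
    seed_rng,
)

from conftest import brute_force_hamiltonian, random_lattice

DIMS = (114, 84)


class TestNeighbourhoods:
    def test_periodic_wrap_left_edge(self):
        assert set(contact_neighbours((0, 5), DIMS)) == {(113, 5), (1, 5), (0, 4), (0, 6)}

    def test_top_edge_truncation(self):
        nbs = contact_neighbours((10, 83), DIMS)
        assert len(nbs) == 3 and (10, 84) not in nbs

    def test_interior_von_neumann(self):
        assert len(set(contact_neighbours((50, 40), DIMS))) == 4

    def test_moore_interior_and_wrap(self):
        assert len(flip_neighbours((50, 40), DIMS)) == 8
        right = flip_neighbours((113, 5), DIMS)
        assert {(0, 4), (0, 5), (0, 6)} <= set(right)

    def test_moore_bottom_edge(self):
        assert len(flip_neighbours((5, 0), DIMS)) == 5

    @pytest.mark.parametrize("p", [(-1, 0), (114, 0), (0, 84)])
    def test_out_of_lattice_errors(self, p):
        with pytest.raises(ValueError):
            contact_neighbours(p, DIMS)
        with pytest.raises(ValueError):
            flip_neighbours(p, DIMS)


class TestCellLength:
    def test_square_is_side_length(self):
        pix = [(x, y) for x in range(6) for y in range(6)]
        assert cell_length(pix) == pytest.approx(6.0)

    def test_single_pixel(self):
        assert cell_length([(3, 7)]) == pytest.approx(1.0)

    def test_horizontal_rod(self):
        # unit-square-smeared covariance: a 1 x n rod has length exactly n
        assert cell_length([(x, 0) for x in range(8)]) == pytest.approx(8.0)

    def test_periodic_unwrap(self):
        pix = [((110 + k) % 114, 3) for k in range(8)]
        assert cell_length(pix, n_x=114) == pytest.approx(8.0)

    def test_rotation_between_axes(self):
        diag = [(k, k) for k in range(6)]
        straight = [(k, 0) for k in range(6)]
        assert cell_length(diag) > cell_length(straight)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cell_length([])


def two_cell_lattice(j=1000.0, nx=4, ny=4, lam_a=0.0, lam_l=0.0):
    grid = np.zeros((nx, ny), dtype=int)
    grid[: nx // 2, :] = 1
    grid[nx // 2 :, :] = 2
    adhesion = AdhesionTable({("EP1", "EP2"): j})
    params = SimParams(flips_per_mcs=nx * ny, n_x=nx, n_y=ny)
    lat = LatticeState(grid, [1, 2], params, adhesion)
    lat.a_target[1:] = lat.area[1:]
    lat.lambda_a[1:] = lam_a
    lat.lambda_l[1:] = lam_l
    lat.l_target[1:] = 2.0
    return lat


class TestHamiltonian:
    def test_two_column_cells_boundary_energy(self):
        # 4x4 periodic-x lattice, two 2-column cells: 8 unordered
        # heterocellular contacts, each counted once
        lat = two_cell_lattice(j=1000.0)
        assert hamiltonian(lat) == pytest.approx(8000.0)
        assert brute_force_hamiltonian(lat) == pytest.approx(8000.0)

    def test_single_cell_at_rest_zero(self):
        grid = np.ones((6, 6), dtype=int)
        lat = LatticeState(
            grid, [1], SimParams(flips_per_mcs=36, n_x=6, n_y=6), AdhesionTable()
        )
        lat.a_target[1] = 36.0
        lat.l_target[1] = 6.0
        lat.lambda_a[1] = 1e4
        lat.lambda_l[1] = 1e3
        assert hamiltonian(lat) == pytest.approx(0.0)

    def test_breakdown_sums_to_total(self, rng):
        lat = random_lattice(rng)
        parts = hamiltonian(lat, breakdown=True)
        assert parts["total"] == pytest.approx(
            parts["boundary"] + parts["length"] + parts["area"]
        )

    def test_matches_brute_force_on_random_lattices(self, rng):
        for _ in range(5):
            lat = random_lattice(rng)
            assert hamiltonian(lat) == pytest.approx(
                brute_force_hamiltonian(lat), rel=1e-12
            )

    def test_axial_weight_values(self):
        # epsilon=0.03: factor 0.9775 for theta=90deg at R=4, 0.97 at theta=0
        w = _kernels._axial_weight(0.0, 4.0, 0.0, 0.0, 1, 100, 0.03, False)
        assert w == pytest.approx(1 - 0.03 * (1 - 1.0 / 4.0))  # 0.9775
        w = _kernels._axial_weight(4.0, 0.0, 0.0, 0.0, 1, 100, 0.03, False)
        assert w == pytest.approx(0.97)
        w = _kernels._axial_weight(0.0, 4.0, 0.0, 0.0, 1, 100, 0.0, False)
        assert w == pytest.approx(1.0)

    def test_axial_weight_r_clamp(self):
        # R < 0.5 px is clamped to 0.5 so the factor stays bounded
        w = _kernels._axial_weight(0.0, 0.25, 0.0, 0.0, 1, 100, 0.03, False)
        assert w == pytest.approx(1 - 0.03 * (1 - 1.0 / 0.5))

    def test_eps_zero_flip_ctx_is_noop(self, rng):
        lat = random_lattice(rng, with_eps=False)
        prop = _random_proposal(lat, rng)
        assert hamiltonian(lat, prop) == pytest.approx(hamiltonian(lat))


def _random_proposal(lat, rng):
    nx, ny = lat.grid.shape
    for _ in range(1000):
        tx, ty = int(rng.integers(nx)), int(rng.integers(ny))
        nbs = flip_neighbours((tx, ty), (nx, ny))
        ix, iy = nbs[int(rng.integers(len(nbs)))]
        if lat.grid[tx, ty] != lat.grid[ix, iy]:
            return make_proposal(lat, (tx, ty), (ix, iy))
    raise RuntimeError("no heterocellular pair found")


class TestDeltaH:
    def test_matches_global_difference(self, rng):
        for _ in range(3):
            lat = random_lattice(rng)
            lat.strict_unwrap = False  # evolved cells may sprawl
            for _ in range(60):
                prop = _random_proposal(lat, rng)
                dh = delta_h(lat, prop)
                h0 = hamiltonian(lat, prop)
                after = lat.copy()
                apply_flip(after, prop)
                after._rebuild_sums()
                h1 = hamiltonian(after, prop)
                assert dh == pytest.approx(h1 - h0, rel=1e-9, abs=1e-6)
                if metropolis_decide(dh, 200.0, float(rng.random())):
                    apply_flip(lat, prop)

    def test_reverse_proposal_negates(self, rng):
        # exact for isotropic cells; with an axial preference the weighted
        # area term is evaluated at each attempt's own pre-flip geometry and
        # is only a state function per attempt
        from combmorph.cpm_core import FlipProposal

        lat = random_lattice(rng, with_eps=False)
        for _ in range(30):
            prop = _random_proposal(lat, rng)
            dh = delta_h(lat, prop)
            after = lat.copy()
            apply_flip(after, prop)
            if after.area[prop.target_sigma] == 0:
                continue
            # flip the same pixel back, with the same frozen geometry
            rev = FlipProposal(
                target=prop.target,
                invading=prop.invading,
                target_sigma=prop.invading_sigma,
                invading_sigma=prop.target_sigma,
                com_target=prop.com_invading,
                com_invading=prop.com_target,
            )
            assert delta_h(after, rev) == pytest.approx(-dh, rel=1e-9, abs=1e-6)

    def test_shrinking_below_target_costs_energy(self):
        lat = two_cell_lattice(j=0.0, lam_a=100.0)
        prop = make_proposal(lat, (1, 1), (2, 1))  # cell 2 invades cell 1
        assert delta_h(lat, prop) > 0

    def test_same_cell_proposal_rejected(self):
        lat = two_cell_lattice()
        with pytest.raises(ValueError):
            make_proposal(lat, (0, 0), (0, 1))

    def test_ba_proposals_invalid(self):
        grid = np.zeros((4, 4), dtype=int)
        grid[:, :2] = 1
        grid[:, 2:] = 2
        lat = LatticeState(
            grid, [5, 1], SimParams(flips_per_mcs=16, n_x=4, n_y=4), AdhesionTable()
        )  # cell 1 is BA
        prop = make_proposal(lat, (0, 1), (0, 2))
        with pytest.raises(ValueError):
            delta_h(lat, prop)


class TestMetropolis:
    def test_decide_certain_for_negative(self):
        assert metropolis_decide(-1.0, 100.0, 0.999999)

    def test_decide_dh_zero_always_accepts(self):
        assert metropolis_decide(0.0, 100.0, 0.999999)

    def test_acceptance_frequency_at_dh_equal_t(self, rng):
        u = rng.random(20000)
        freq = np.mean([metropolis_decide(100.0, 100.0, x) for x in u])
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / 20000)
        assert abs(freq - math.exp(-1)) < 4 * se

    def test_attempt_flip_same_cell_noop(self):
        grid = np.ones((4, 4), dtype=int)
        lat = LatticeState(
            grid, [1], SimParams(flips_per_mcs=16, n_x=4, n_y=4), AdhesionTable()
        )
        g = np.random.default_rng(0)
        assert not any(attempt_flip(lat, g) for _ in range(50))
        assert lat.grid.min() == 1

    def test_attempt_flip_updates_bookkeeping(self, rng):
        lat = random_lattice(rng, temperature=2000.0)
        lat.strict_unwrap = False  # hot dynamics may sprawl cells
        g = np.random.default_rng(7)
        accepted = sum(attempt_flip(lat, g) for _ in range(1000))
        assert accepted > 0
        lat.check_consistency()


class TestRunMcs:
    def test_pixel_conservation_and_time(self, rng):
        lat = random_lattice(rng, temperature=500.0)
        lat.strict_unwrap = False  # hot dynamics may sprawl cells
        total = lat.grid.size
        seed_rng(42)
        run_mcs(lat, 5)
        assert lat.time == 5
        assert lat.area.sum() == total
        lat.check_consistency()

    def test_giant_cell_is_static(self):
        grid = np.ones((10, 10), dtype=int)
        lat = LatticeState(
            grid, [1], SimParams(flips_per_mcs=100, n_x=10, n_y=10), AdhesionTable()
        )
        seed_rng(3)
        run_mcs(lat, 10)
        assert np.all(lat.grid == 1)

    def test_seeded_runs_reproducible(self, rng):
        lat1 = random_lattice(rng, temperature=500.0)
        lat2 = lat1.copy()
        seed_rng(99)
        run_mcs(lat1, 3)
        seed_rng(99)
        run_mcs(lat2, 3)
        assert np.array_equal(lat1.grid, lat2.grid)
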