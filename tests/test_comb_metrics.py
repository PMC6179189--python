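"""Morphometrics: rotation angle, inter-tooth angles, intactness."""

import math
import warnings

import numpy as np
import pytest

from combmorph.comb_configs import CombLayoutSpec, generate_initial_lattice
from combmorph.comb_metrics import (
    MetricError,
    MetricsRecord,
    abasct_sd,
    alpha_from_coms,
    betas_from_coms,
    compute_abasct,
    compute_alpha,
    distal_area_summary,
    intact_ratio,
    is_intact,
    measure,
    tooth_coms,
)
from combmorph.cpm_core import AdhesionTable, LatticeState, SimParams


class TestAlpha:
    def test_horizontal_comb_is_zero(self):
        assert alpha_from_coms([(30, 10), (10, 10)]) == pytest.approx(0.0)

    def test_vertical_comb_is_ninety(self):
        assert alpha_from_coms([(20, 10), (20, 30)]) == pytest.approx(90.0)

    def test_diagonal_is_fortyfive(self):
        assert alpha_from_coms([(30, 10), (10, 30)]) == pytest.approx(45.0)

    def test_beyond_vertical(self):
        assert alpha_from_coms([(10, 10), (30, 30)]) == pytest.approx(135.0)

    def test_translation_invariance(self):
        coms = [(30.0, 10.0), (22.0, 14.0), (10.0, 30.0)]
        shifted = [(x + 7.3, y + 2.1) for x, y in coms]
        assert alpha_from_coms(shifted) == pytest.approx(alpha_from_coms(coms))

    def test_coincident_ends_error(self):
        with pytest.raises(MetricError):
            alpha_from_coms([(5, 5), (5, 5)])

    def test_long_comb_across_periodic_seam(self):
        # consecutive short steps unwrap correctly even when the comb spans
        # more than half the lattice
        coms = [((100 + 6 * k) % 114, 10.0) for k in range(11)]
        # tip points toward +x after wrapping around the seam
        assert alpha_from_coms(coms, n_x=114) == pytest.approx(180.0)


class TestAbasct:
    def test_right_angle_fixture(self):
        betas = betas_from_coms([(0, 0), (10, 0), (10, 10)])
        assert betas == pytest.approx([0.0, 90.0])
        assert abasct_sd(betas) == pytest.approx(math.sqrt(2 * 45.0**2), abs=0.01)  # 63.64

    def test_collinear_teeth_zero_sd(self):
        betas = betas_from_coms([(0, 0), (5, 5), (10, 10), (15, 15)])
        assert abasct_sd(betas) == pytest.approx(0.0)

    def test_rigid_rotation_shifts_betas_keeps_sd(self):
        coms = [(0.0, 0.0), (10.0, 0.0), (18.0, 6.0), (24.0, 14.0)]
        th = math.radians(30)
        rot = [
            (x * math.cos(th) - y * math.sin(th), x * math.sin(th) + y * math.cos(th))
            for x, y in coms
        ]
        b0, b1 = betas_from_coms(coms), betas_from_coms(rot)
        np.testing.assert_allclose(np.array(b1) - np.array(b0), 30.0, atol=1e-9)
        assert abasct_sd(b1) == pytest.approx(abasct_sd(b0))

    def test_unwrap_across_branch_cut(self):
        # vectors straddling the +-180 deg branch stay on one branch
        betas = betas_from_coms([(0, 0), (-10, 0.5), (-20, -0.5)])
        assert abasct_sd(betas) < 10.0

    def test_sd_requires_two_angles(self):
        with pytest.raises(MetricError):
            abasct_sd([12.0])


class TestRigidMotionProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    BASE = [(0.0, 0.0), (9.0, 1.0), (17.0, 5.0), (23.0, 12.0), (27.0, 21.0)]

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        theta=st.floats(-170.0, 170.0),
        dx=st.floats(-50.0, 50.0),
        dy=st.floats(-50.0, 50.0),
    )
    def test_sd_invariant_alpha_equivariant_under_rigid_motion(self, theta, dx, dy):
        th = math.radians(theta)
        moved = [
            (
                x * math.cos(th) - y * math.sin(th) + dx,
                x * math.sin(th) + y * math.cos(th) + dy,
            )
            for x, y in self.BASE
        ]
        sd0 = abasct_sd(betas_from_coms(self.BASE))
        sd1 = abasct_sd(betas_from_coms(moved))
        assert sd1 == pytest.approx(sd0, abs=1e-8)
        # alpha rotates with the comb, up to the [0, 180] fold of the
        # unsigned angle definition
        a0 = alpha_from_coms(self.BASE)
        a1 = alpha_from_coms(moved)

        def circ(a, b):
            d = abs((a - b) % 360.0)
            return min(d, 360.0 - d)

        assert any(
            circ(s0 * a0 + theta, s1 * a1) < 1e-6
            for s0 in (1, -1)
            for s1 in (1, -1)
        )


def lattice_from_mask(mask, fill_type=1):
    """SCT mask (True pixels) over a background cell, as a LatticeState."""
    mask = np.asarray(mask, dtype=bool)
    nx, ny = mask.shape
    grid = np.where(mask, 2, 1)
    lat = LatticeState(
        grid,
        [fill_type, 4],
        SimParams(flips_per_mcs=nx * ny, n_x=nx, n_y=ny),
        AdhesionTable(),
        strict_unwrap=False,  # masks may be disconnected and span the seam
    )
    return lat


def bfs_intact(mask, connectivity=8):
    """Flood-fill oracle with periodic x."""
    nx, ny = mask.shape
    pts = {(x, y) for x, y in zip(*np.nonzero(mask))}
    if not pts:
        raise ValueError
    start = next(iter(pts))
    seen = {start}
    stack = [start]
    if connectivity == 8:
        offs = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1) if (dx, dy) != (0, 0)]
    else:
        offs = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    while stack:
        x, y = stack.pop()
        for dx, dy in offs:
            q = ((x + dx) % nx, y + dy)
            if 0 <= q[1] < ny and q in pts and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(pts)


class TestIntact:
    def test_single_blob(self):
        m = np.zeros((10, 8), dtype=bool)
        m[2:5, 2:5] = True
        assert is_intact(lattice_from_mask(m))

    def test_two_separated_clusters(self):
        m = np.zeros((10, 8), dtype=bool)
        m[0:2, 0:2] = True
        m[6:8, 5:7] = True
        assert not is_intact(lattice_from_mask(m))

    def test_diagonal_contact_depends_on_connectivity(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:4, 2:4] = True
        m[4:6, 4:6] = True  # touching only at the corner (4,4)/(3,3)
        lat = lattice_from_mask(m)
        assert is_intact(lat, connectivity=8)
        assert not is_intact(lat, connectivity=4)

    def test_connected_across_periodic_seam(self):
        m = np.zeros((12, 6), dtype=bool)
        m[10:, 2:4] = True
        m[:2, 2:4] = True
        assert is_intact(lattice_from_mask(m))
        # same two blocks without wrap adjacency are separate
        m2 = np.zeros((12, 6), dtype=bool)
        m2[9:11, 2:4] = True
        m2[1:3, 2:4] = True
        assert not is_intact(lattice_from_mask(m2))

    def test_matches_flood_fill_oracle_on_random_masks(self, rng):
        for _ in range(100):
            m = rng.random((9, 7)) < 0.35
            if not m.any():
                m[0, 0] = True
            lat = lattice_from_mask(m)
            assert is_intact(lat, 8) == bfs_intact(m, 8)
            assert is_intact(lat, 4) == bfs_intact(m, 4)

    def test_no_sct_errors(self):
        grid = np.ones((4, 4), dtype=int)
        lat = LatticeState(
            grid, [1], SimParams(flips_per_mcs=16, n_x=4, n_y=4), AdhesionTable()
        )
        with pytest.raises(MetricError):
            is_intact(lat)


class TestIntactRatio:
    def rec(self, intact):
        return MetricsRecord(0, [0, 0], 0, intact, None, None, 0, 5)

    def test_values(self):
        assert intact_ratio([self.rec(True)] * 48) == 1.0
        assert intact_ratio([self.rec(True)] * 24 + [self.rec(False)] * 24) == 0.5
        assert intact_ratio([self.rec(False)] * 10) == 0.0

    def test_empty_errors(self):
        with pytest.raises(MetricError):
            intact_ratio([])


class TestOnGeneratedLattice:
    def test_tooth_coms_order_and_centers(self):
        spec = CombLayoutSpec(n_teeth=5)
        lat = generate_initial_lattice(spec)
        coms = tooth_coms(lat)
        assert [sig for sig, _ in coms] == lat.tooth_ids
        x0, y0 = spec.tooth_origin(0)
        assert coms[0][1] == pytest.approx((x0 + 2.5, y0 + 2.5))

    def test_initial_alpha_near_configured_angle(self):
        lat = generate_initial_lattice(CombLayoutSpec(n_teeth=9))
        assert compute_alpha(lat) == pytest.approx(18.0, abs=3.0)

    def test_initial_comb_intact_and_straightish(self):
        lat = generate_initial_lattice(CombLayoutSpec(n_teeth=9))
        m = measure(lat)
        assert m.intact
        assert len(m.betas) == 8
        assert m.abasct_sd < 10.0

    def test_distal_area_summary_gradient(self):
        lat = generate_initial_lattice(CombLayoutSpec(n_teeth=9))
        ep1, ep2 = distal_area_summary(lat)
        assert ep2 < ep1

    def test_distal_summary_handles_missing_class(self):
        grid = np.ones((6, 6), dtype=int)
        grid[0, 0] = 2
        lat = LatticeState(
            grid, [1, 4], SimParams(flips_per_mcs=36, n_x=6, n_y=6), AdhesionTable()
        )
        ep1, ep2 = distal_area_summary(lat)
        assert ep1 == pytest.approx(35.0)
        assert ep2 is None

    def test_retired_tooth_warns_and_is_omitted(self):
        lat = generate_initial_lattice(CombLayoutSpec(n_teeth=5))
        sig = lat.tooth_ids[2]
        # forcibly retire the middle tooth
        lat.grid[lat.grid == sig] = lat.tooth_ids[1]
        lat._rebuild_sums()
        with pytest.warns(UserWarning, match="retired"):
            coms = tooth_coms(lat)
        assert len(coms) == 4
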