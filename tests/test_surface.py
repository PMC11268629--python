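"""Spline-grid surface reconstruction: alignment, normals, poses, mesh."""

import numpy as np
import pytest

from tomogeom.core_model import validate
from tomogeom.fixtures import MembraneSpec, make_membrane_fixture
from tomogeom.surface import (
    align_strips,
    build_surface_grid,
    strips_from_points,
    surface_mesh,
    surface_poses,
)


def exhaustive_best_shift(a, b):
    """Independent oracle: scan every shift, minimise mean matched distance."""
    best = None
    for d in range(-(len(b) - 2), len(a) - 1):
        lo, hi = max(0, d), min(len(a), len(b) + d)
        if hi - lo < 2:
            continue
        cost = np.linalg.norm(a[lo:hi] - b[lo - d : hi - d], axis=1).mean()
        key = (cost, abs(d), d)
        if best is None or key < best[0]:
            best = (key, d)
    return best[1]


@pytest.fixture
def plane_grid():
    _, strips, normal_at = make_membrane_fixture(MembraneSpec(kind="plane"))
    return build_surface_grid(strips, spacing=3.0), normal_at


class TestAlignStrips:
    def test_identical_strips_no_padding(self):
        strip = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        offsets, rect, mask = align_strips([strip, strip.copy()])
        np.testing.assert_array_equal(offsets, [0, 0])
        assert rect.shape == (2, 5, 3)
        assert not mask.any()

    def test_recovers_unit_shift(self):
        a = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
        b = a[1:].copy()
        b = np.vstack([b, [[6.0, 0, 0]]])  # drop first point, append one
        offsets, rect, mask = align_strips([a, b])
        assert offsets[1] - offsets[0] == 1
        assert rect.shape[1] == 7
        assert mask.sum() == 2  # one padded node per strip

    def test_rectangle_width_and_mask_count(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        b = np.column_stack([np.arange(8.0), np.ones(8), np.zeros(8)])
        offsets, rect, mask = align_strips([a, b])
        assert rect.shape[1] == 8
        assert mask.sum() == 3  # only the shorter strip is padded
        assert mask[0].sum() == 3 and not mask[1].any()

    def test_matches_exhaustive_oracle_on_random_scenarios(self, rng):
        for _ in range(100):
            n = rng.integers(5, 12)
            base = np.cumsum(rng.uniform(1, 2, size=(n, 3)), axis=0)
            true_shift = int(rng.integers(-2, 3))
            m = rng.integers(4, 10)
            start = max(0, -true_shift)
            other = base[0] + np.cumsum(rng.uniform(1, 2, size=(m + start, 3)), axis=0)
            other = other[start:]
            offsets, _, _ = align_strips([base, other])
            assert offsets[1] - offsets[0] == exhaustive_best_shift(base, other)

    def test_padding_extrapolates_edge_segment(self):
        a = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        b = a + [1.0, 0, 0]  # same geometry advanced one x unit -> shift 1
        offsets, rect, mask = align_strips([a, b])
        assert offsets[1] - offsets[0] == 1
        # b's prepended head continues its unit step backwards
        np.testing.assert_allclose(rect[1, 0], [0.0, 0, 0], atol=1e-9)
        assert mask[1, 0] and mask[0, -1]

    def test_too_few_strips(self):
        with pytest.raises(ValueError, match="2 strips"):
            align_strips([np.zeros((3, 3))])


class TestPlaneRecovery:
    def test_normals_within_one_degree(self, plane_grid):
        grid, normal_at = plane_grid
        true = normal_at(None)
        normals = grid.orientations[..., :, 2]
        cos = np.abs(normals @ true)
        assert np.rad2deg(np.arccos(np.clip(cos, -1, 1))).max() < 1.0

    def test_spacing_within_five_percent(self, plane_grid):
        grid, _ = plane_grid
        keep = ~grid.padded_mask
        du = np.linalg.norm(np.diff(grid.grid_points, axis=0), axis=-1)
        dv = np.linalg.norm(np.diff(grid.grid_points, axis=1), axis=-1)
        du = du[keep[:-1] & keep[1:]]
        dv = dv[keep[:, :-1] & keep[:, 1:]]
        assert np.all(np.abs(du - 3.0) / 3.0 < 0.05)
        assert np.all(np.abs(dv - 3.0) / 3.0 < 0.05)

    def test_node_heights_on_plane(self, plane_grid):
        # plane x = z: residual x - z should vanish
        grid, _ = plane_grid
        resid = grid.grid_points[..., 0] - grid.grid_points[..., 2]
        assert np.sqrt((resid**2).mean()) < 1.0

    def test_families_perpendicular_on_plane(self, plane_grid):
        grid, _ = plane_grid
        tan_x = grid.orientations[..., :, 0]
        tan_y = grid.orientations[..., :, 1]
        # frame axes are orthogonal by construction; check raw grid directions
        du = np.diff(grid.grid_points, axis=0)
        dv = np.diff(grid.grid_points, axis=1)
        du = du / np.linalg.norm(du, axis=-1, keepdims=True)
        dv = dv / np.linalg.norm(dv, axis=-1, keepdims=True)
        cos = np.abs(np.einsum("uvk,uvk->uv", du[:, :-1], dv[:-1, :]))
        assert cos.max() < 0.05
        assert tan_x.shape == tan_y.shape

    def test_orientations_orthonormal(self, plane_grid):
        grid, _ = plane_grid
        frames = grid.orientations.reshape(-1, 3, 3)
        np.testing.assert_allclose(np.linalg.det(frames), 1.0, atol=1e-6)
        gram = np.einsum("nij,nik->njk", frames, frames)
        np.testing.assert_allclose(gram, np.broadcast_to(np.eye(3), gram.shape), atol=1e-6)

    def test_normal_perpendicular_to_tangents(self, plane_grid):
        grid, _ = plane_grid
        z = grid.orientations[..., :, 2]
        for col in (0, 1):
            t = grid.orientations[..., :, col]
            assert np.abs(np.einsum("uvk,uvk->uv", z, t)).max() < 1e-3


class TestCylinderRecovery:
    def test_normals_radial_within_two_degrees(self):
        radius, cx, cy = 50.0, 60.0, 60.0
        zs = np.linspace(20, 80, 6)
        phi = np.linspace(-np.pi / 3, np.pi / 3, 9)
        strips = [
            np.column_stack(
                [cx + radius * np.cos(phi), cy + radius * np.sin(phi), np.full_like(phi, z)]
            )
            for z in zs
        ]
        grid = build_surface_grid(strips, spacing=5.0)
        radial = grid.grid_points - [cx, cy, 0]
        radial[..., 2] = 0
        radial /= np.linalg.norm(radial, axis=-1, keepdims=True)
        cos = np.abs(np.einsum("uvk,uvk->uv", grid.orientations[..., :, 2], radial))
        angles = np.rad2deg(np.arccos(np.clip(cos, -1, 1)))
        assert angles[~grid.padded_mask].max() < 2.0


class TestSinusoidalSheet:
    def test_height_recovery_within_one_voxel_rms(self, rng):
        spec = MembraneSpec(kind="sine", jitter=0.2, seed=7)
        _, strips, _ = make_membrane_fixture(spec)
        grid = build_surface_grid(strips, spacing=3.0)
        x0 = (spec.size[2] - 1) / 2
        expected_x = x0 + spec.sine_amplitude * np.sin(
            2 * np.pi * grid.grid_points[..., 1] / spec.sine_period
        )
        resid = (grid.grid_points[..., 0] - expected_x)[~grid.padded_mask]
        assert np.sqrt((resid**2).mean()) < 1.0


class TestSurfacePoses:
    def test_counts(self, plane_grid):
        grid, _ = plane_grid
        u, v = grid.shape
        all_poses = surface_poses(grid, include_padded=True)
        assert len(all_poses) == u * v
        unpadded = surface_poses(grid, include_padded=False)
        assert len(unpadded) == u * v - grid.padded_mask.sum()
        assert validate(unpadded) == []
        assert {"grid_u", "grid_v"} <= set(unpadded.features.columns)

    def test_plane_normals_agree_pairwise(self, plane_grid):
        grid, _ = plane_grid
        z = surface_poses(grid).orientations[:, :, 2]
        cos = z @ z.T
        assert cos.min() > np.cos(np.deg2rad(1.0))


class TestSurfaceMesh:
    def test_two_by_two_gives_two_triangles(self, plane_grid):
        grid, _ = plane_grid
        sub = type(grid)(
            grid_points=grid.grid_points[:2, :2],
            orientations=grid.orientations[:2, :2],
            padded_mask=grid.padded_mask[:2, :2],
            spacing=grid.spacing,
        )
        vertices, faces = surface_mesh(sub)
        assert len(vertices) == 4 and len(faces) == 2

    def test_counting_and_index_range(self, plane_grid):
        grid, _ = plane_grid
        u, v = grid.shape
        vertices, faces = surface_mesh(grid)
        assert len(faces) == 2 * (u - 1) * (v - 1)
        assert faces.min() >= 0 and faces.max() < len(vertices)

    def test_winding_follows_node_normals(self, plane_grid):
        grid, _ = plane_grid
        vertices, faces = surface_mesh(grid)
        node_normals = grid.orientations[..., :, 2].reshape(-1, 3)
        fn = np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        )
        fn /= np.linalg.norm(fn, axis=1, keepdims=True)
        mean_normal = node_normals[faces].mean(axis=1)
        dots = np.einsum("ik,ik->i", fn, mean_normal)
        assert dots.min() > 0.99


class TestDegenerateInput:
    def test_collinear_input_names_failing_step(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="step"):
            build_surface_grid([line, line + [0, 0, 1e-15]], spacing=1.0)

    def test_bad_spacing(self):
        with pytest.raises(ValueError, match="spacing"):
            build_surface_grid([np.zeros((3, 3)), np.ones((3, 3))], spacing=-1)


class TestStripsFromPoints:
    def test_groups_by_z_when_no_group_column(self):
        points = np.array([[0, 0, 5], [1, 0, 5], [0, 0, 9], [1, 0, 9]], dtype=float)
        strips = strips_from_points(points)
        assert len(strips) == 2
        np.testing.assert_array_equal(strips[0][:, 2], [5, 5])

    def test_explicit_groups_preserve_pick_order(self):
        points = np.array([[3, 0, 0], [1, 0, 0], [2, 0, 1]], dtype=float)
        strips = strips_from_points(points, groups=np.array([0, 0, 1]))
        np.testing.assert_array_equal(strips[0][:, 0], [3, 1])
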