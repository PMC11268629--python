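"""Spline-grid surface reconstruction from per-slice point strips.

Membrane-like objects are annotated by clicking a handful of points along
the surface on a few Z-slices.  The reconstruction proceeds in eight steps:

1. group picks into ordered strips, one per annotated slice;
2. fit a spline through each strip (chosen order and smoothing);
3. sample each strip spline equidistantly in Euclidean space;
4. align the sampled strips by integer index shifts minimising index-wise
   distances, and pad them to a common rectangular width;
5. fit a second family of splines through matched columns (the direction
   perpendicular to the strips);
6. resample the column splines equidistantly → a full rectangular grid of
   evenly spaced surface points;
7. fit a third spline family along the rows of the final grid;
8. differentiate families 2 and 3 at every node → two surface-tangent
   vectors; their cross product is the surface normal, completing a full
   orientation frame per node.

Padded nodes (grid positions extrapolated beyond the user's picks) are kept
for spline support but flagged in a mask and excluded from pose output by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tomogeom.core_model import PoseSet
from tomogeom.splines import Spline3D, fit_spline, sample_equidistant

__all__ = [
    "SurfaceGrid",
    "align_strips",
    "build_surface_grid",
    "surface_poses",
    "surface_mesh",
    "strips_from_points",
]


@dataclass
class SurfaceGrid:
    """A U×V lattice of oriented surface points.

    ``orientations[u, v]`` is a proper rotation whose third column is the
    unit surface normal at ``grid_points[u, v]``; the first two columns are
    surface-tangent directions.  ``padded_mask`` is True where a node arises
    from padding rather than from the user's picks.
    """

    grid_points: np.ndarray
    orientations: np.ndarray
    padded_mask: np.ndarray
    spacing: float
    experiment_id: str = ""

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid_points.shape[:2]


def _pair_shift(a: np.ndarray, b: np.ndarray) -> int:
    """Integer shift of strip ``b`` relative to ``a`` minimising the mean
    Euclidean distance between index-matched points.

    Shift ``d`` matches ``a[u]`` with ``b[u - d]``.  All shifts with an
    overlap of at least 2 points are searched exhaustively; ties are broken
    by smaller ``|d|``, then by smaller ``d``.
    """
    la, lb = len(a), len(b)
    best = None
    for d in range(-(lb - 2), la - 1):
        lo = max(0, d)
        hi = min(la, lb + d)
        if hi - lo < 2:
            continue
        cost = float(np.linalg.norm(a[lo:hi] - b[lo - d : hi - d], axis=1).mean())
        key = (cost, abs(d), d)
        if best is None or key < best[0]:
            best = (key, d)
    if best is None:
        raise ValueError("strips too short to overlap by 2 points at any shift")
    return best[1]


def _extrapolate(strip: np.ndarray, n_before: int, n_after: int) -> np.ndarray:
    """Pad a strip on both ends by linear extrapolation of its edge segments."""
    parts = []
    if n_before:
        step = strip[0] - strip[1]
        parts.append(strip[0] + step * np.arange(n_before, 0, -1)[:, None])
    parts.append(strip)
    if n_after:
        step = strip[-1] - strip[-2]
        parts.append(strip[-1] + step * np.arange(1, n_after + 1)[:, None])
    return np.concatenate(parts, axis=0)


def align_strips(
    strips: list[np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align point strips by integer index shifts and pad to a rectangle.

    Each strip is assigned an integer offset minimising the summed
    index-wise distance to its predecessor (exhaustive search over feasible
    shifts).  Strips are then padded on both ends, by linear extrapolation of
    their terminal segments, to a common width.

    Returns
    -------
    offsets : (U,) int array of per-strip column offsets (min is 0)
    rect : (U, V, 3) padded rectangular point array
    padded_mask : (U, V) bool array, True at padded entries
    """
    if len(strips) < 2:
        raise ValueError(f"need at least 2 strips, got {len(strips)}")
    strips = [np.asarray(s, dtype=float).reshape(-1, 3) for s in strips]
    for i, s in enumerate(strips):
        if len(s) < 2:
            raise ValueError(f"strip {i} has fewer than 2 points")
    offsets = np.zeros(len(strips), dtype=int)
    for i in range(1, len(strips)):
        offsets[i] = offsets[i - 1] + _pair_shift(strips[i - 1], strips[i])
    offsets -= offsets.min()
    width = int(max(o + len(s) for o, s in zip(offsets, strips)))
    rect = np.empty((len(strips), width, 3))
    mask = np.zeros((len(strips), width), dtype=bool)
    for i, (o, s) in enumerate(zip(offsets, strips)):
        rect[i] = _extrapolate(s, o, width - o - len(s))
        mask[i, :o] = True
        mask[i, o + len(s) :] = True
    return offsets, rect, mask


def _column_spacing_mask(
    spline: Spline3D, mask_col: np.ndarray, arcs: np.ndarray, tol: float
) -> np.ndarray:
    """Flag resampled nodes lying outside the arc span of real support points."""
    arc_at_control = np.interp(spline.control_params, spline.arc_params, spline.arc_lengths)
    real = np.nonzero(~mask_col)[0]
    if len(real) == 0:
        return np.ones(len(arcs), dtype=bool)
    lo, hi = arc_at_control[real[0]], arc_at_control[real[-1]]
    return (arcs < lo - tol) | (arcs > hi + tol)


def build_surface_grid(
    strips: list[np.ndarray],
    spacing: float,
    order: int = 3,
    smoothing: float = 0.0,
    experiment_id: str = "",
) -> SurfaceGrid:
    """Reconstruct an oriented rectangular surface grid from point strips.

    ``strips`` are ordered point rows, one per annotated slice, ordered by
    slice coordinate with pick order preserved within each strip.
    ``spacing`` is the requested inter-node (and hence inter-particle)
    distance in voxel units.
    """
    if spacing <= 0:
        raise ValueError(f"spacing must be > 0, got {spacing}")
    if len(strips) < 2:
        raise ValueError(f"need at least 2 strips, got {len(strips)}")

    # steps 2-3: strip splines, sampled equidistantly
    try:
        sampled = []
        for s in strips:
            spl = fit_spline(s, order=order, smoothing=smoothing)
            pts, _ = sample_equidistant(spl, spacing)
            sampled.append(pts)
    except ValueError as e:
        raise ValueError(f"step 2-3 (strip splines) failed: {e}") from e

    # step 4: integer alignment + rectangular padding
    offsets, rect, mask = align_strips(sampled)
    n_strips, width = rect.shape[:2]

    # step 5: column splines (perpendicular direction)
    try:
        col_splines = [
            fit_spline(rect[:, v], order=min(order, n_strips - 1), smoothing=smoothing)
            for v in range(width)
        ]
    except ValueError as e:
        raise ValueError(f"step 5 (column splines) failed: {e}") from e

    # step 6: common equidistant resampling of the columns → final grid rows.
    # The row count is shared (the grid must stay rectangular): take the count
    # the longest column needs, so its spacing is the requested one and
    # shorter columns are sampled slightly finer.
    n_rows = max(2, max(int(round(cs.length / spacing)) + 1 for cs in col_splines))
    grid = np.empty((n_rows, width, 3))
    grid_mask = np.zeros((n_rows, width), dtype=bool)
    col_params = np.empty((n_rows, width))
    for v, cs in enumerate(col_splines):
        arcs = np.linspace(0.0, cs.length, n_rows)
        params = cs.arc_to_param(arcs)
        params[0], params[-1] = 0.0, 1.0
        grid[:, v] = cs(params)
        col_params[:, v] = params
        grid_mask[:, v] = _column_spacing_mask(cs, mask[:, v], arcs, tol=spacing / 2)

    # step 7: row splines (same orientation as the strips)
    try:
        row_splines = [
            fit_spline(grid[u], order=min(order, width - 1), smoothing=smoothing)
            for u in range(n_rows)
        ]
    except ValueError as e:
        raise ValueError(f"step 7 (row splines) failed: {e}") from e

    # step 8: tangents from families 2 and 3 → normals → full frames
    tan_u = np.empty_like(grid)
    tan_v = np.empty_like(grid)
    for v, cs in enumerate(col_splines):
        tan_u[:, v] = cs.tangent(col_params[:, v])
    for u, rs in enumerate(row_splines):
        tan_v[u] = rs.tangent(rs.control_params)

    normals = np.cross(tan_u, tan_v)
    norms = np.linalg.norm(normals, axis=-1, keepdims=True)
    if np.any(norms < 1e-9):
        raise ValueError("step 8 (normals) failed: degenerate (parallel) tangents")
    normals /= norms
    _orient_normals(normals, grid_mask)

    orientations = np.empty((n_rows, width, 3, 3))
    for u in range(n_rows):
        for v in range(width):
            z = normals[u, v]
            x = tan_v[u, v] - np.dot(tan_v[u, v], z) * z
            x /= np.linalg.norm(x)
            y = np.cross(z, x)
            orientations[u, v] = np.stack([x, y, z], axis=1)

    return SurfaceGrid(
        grid_points=grid,
        orientations=orientations,
        padded_mask=grid_mask,
        spacing=float(spacing),
        experiment_id=experiment_id,
    )


def _orient_normals(normals: np.ndarray, mask: np.ndarray) -> None:
    """Make normal signs continuous across the grid, in place.

    Seeded by the raw cross product at the first unpadded node; each node is
    flipped if it disagrees with an already-fixed neighbour (left, then up).
    """
    u_dim, v_dim = normals.shape[:2]
    for u in range(u_dim):
        for v in range(v_dim):
            ref = None
            if v > 0:
                ref = normals[u, v - 1]
            elif u > 0:
                ref = normals[u - 1, v]
            if ref is not None and np.dot(normals[u, v], ref) < 0:
                normals[u, v] = -normals[u, v]


def surface_poses(grid: SurfaceGrid, include_padded: bool = False) -> PoseSet:
    """One oriented pose per grid node; padded nodes dropped by default.

    Features carry the ``(u, v)`` grid indices of each pose.
    """
    u_dim, v_dim = grid.shape
    uu, vv = np.meshgrid(np.arange(u_dim), np.arange(v_dim), indexing="ij")
    keep = np.ones((u_dim, v_dim), dtype=bool) if include_padded else ~grid.padded_mask
    return PoseSet(
        positions=grid.grid_points[keep],
        orientations=grid.orientations[keep],
        features=pd.DataFrame({"grid_u": uu[keep], "grid_v": vv[keep]}),
        experiment_id=grid.experiment_id,
        pixel_spacing=0.0,
    )


def surface_mesh(grid: SurfaceGrid) -> tuple[np.ndarray, np.ndarray]:
    """Triangulate the grid for display.

    Vertices are the grid nodes in row-major order; each quad is split into
    two triangles, wound so face normals agree (positive dot) with the stored
    node normals.
    """
    u_dim, v_dim = grid.shape
    if u_dim < 2 or v_dim < 2:
        raise ValueError(f"grid must be at least 2x2, got {u_dim}x{v_dim}")
    vertices = grid.grid_points.reshape(-1, 3)
    node_normals = grid.orientations[..., :, 2].reshape(-1, 3)
    faces = []
    for u in range(u_dim - 1):
        for v in range(v_dim - 1):
            a = u * v_dim + v
            b = a + 1
            c = a + v_dim
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    faces = np.asarray(faces, dtype=int)
    for i, f in enumerate(faces):
        fn = np.cross(vertices[f[1]] - vertices[f[0]], vertices[f[2]] - vertices[f[0]])
        if np.dot(fn, node_normals[f].mean(axis=0)) < 0:
            faces[i] = f[[0, 2, 1]]
    return vertices, faces


def strips_from_points(
    points: np.ndarray, groups: np.ndarray | None = None
) -> list[np.ndarray]:
    """Group manual picks into per-slice strips.

    If ``groups`` is given (e.g. the 4th CSV column), points sharing a group
    value form a strip; otherwise points are grouped by their z coordinate.
    Strips are ordered by group / slice value; pick order is preserved within
    each strip.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    key = np.asarray(groups) if groups is not None else points[:, 2]
    strips = []
    for value in np.unique(key):
        strips.append(points[key == value])
    return strips
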