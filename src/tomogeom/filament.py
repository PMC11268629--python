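"""Helical filament picking: spline → lattice of oriented particle poses.

The five-step procedure: points picked along a filament are fit with a
spline; the spline is sampled equidistantly at the helical *rise*; each
sample is rotated about the local filament axis by an accumulating *twist*;
an optional *radius* shifts particles off-axis along the (twisted) local X
axis, producing the helical point pattern; an optional cyclic symmetry Cn
replicates each pose n times about the filament axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from tomogeom.core_model import PoseSet
from tomogeom.splines import Spline3D, frames_along, sample_equidistant

__all__ = ["HelicalParams", "generate_helical_poses", "filament_polyline"]


def rot_z(degrees: float) -> np.ndarray:
    """Right-handed rotation about +z by the given angle in degrees."""
    c, s = np.cos(np.deg2rad(degrees)), np.sin(np.deg2rad(degrees))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass(frozen=True)
class HelicalParams:
    """Helical lattice parameters.

    rise
        Axial translation between consecutive subunits, voxel units along the
        filament (> 0).
    twist
        Rotation about the filament axis per rise step, degrees.
    radius
        Radial offset of particles from the spline, voxel units (>= 0).
    symmetry
        Cyclic group order n >= 1 (Cn): azimuthal copies per subunit.
    """

    rise: float
    twist: float = 0.0
    radius: float = 0.0
    symmetry: int = 1

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError(f"rise must be > 0, got {self.rise}")
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")
        if self.symmetry < 1 or int(self.symmetry) != self.symmetry:
            raise ValueError(f"symmetry must be an integer >= 1, got {self.symmetry}")


def generate_helical_poses(
    spline: Spline3D,
    params: HelicalParams,
    experiment_id: str = "",
    pixel_spacing: float = 0.0,
    filament_id: int = 0,
) -> PoseSet:
    """Generate a helical lattice of oriented poses along a filament spline.

    Axis samples are Euclidean-equidistant at spacing ``rise``.  Sample ``j``
    carries the frame ``F_j = RMF_j · Rz(j·twist)`` (rotation-minimising frame
    composed with the accumulated twist); its position is the axis point
    shifted by ``radius`` along the frame's local X axis.  Every pose's local
    Z axis is the filament tangent.  With symmetry Cn, each pose is replicated
    n times by a further local-frame rotation ``Rz(360°·m/n)``, rotating both
    the radial offset and the orientation about the axis point.

    A rise longer than the filament still yields the 2-endpoint minimum.
    Features carry ``filament_id``, axis index ``axis_index`` and symmetry
    copy index ``sym_index``.
    """
    axis_points, t_params = sample_equidistant(spline, params.rise)
    base_frames = frames_along(spline, t_params)
    k = len(axis_points)
    n = int(params.symmetry)

    positions = np.empty((n * k, 3))
    orientations = np.empty((n * k, 3, 3))
    axis_idx = np.empty(n * k, dtype=int)
    sym_idx = np.empty(n * k, dtype=int)
    row = 0
    for j in range(k):
        twisted = base_frames[j] @ rot_z(j * params.twist)
        for m in range(n):
            frame = twisted @ rot_z(360.0 * m / n)
            orientations[row] = frame
            positions[row] = axis_points[j] + params.radius * frame[:, 0]
            axis_idx[row], sym_idx[row] = j, m
            row += 1

    features = pd.DataFrame(
        {
            "filament_id": np.full(n * k, filament_id),
            "axis_index": axis_idx,
            "sym_index": sym_idx,
        }
    )
    return PoseSet(
        positions=positions,
        orientations=orientations,
        features=features,
        experiment_id=experiment_id,
        pixel_spacing=float(pixel_spacing),
    )


def filament_polyline(spline: Spline3D, spacing: float) -> np.ndarray:
    """Ordered equidistant polyline along the filament, for display/export."""
    points, _ = sample_equidistant(spline, spacing)
    return points
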