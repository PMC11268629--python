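"""Shared, validated data structures: particle poses, images, label volumes.

Conventions (fixed package-wide):

* Particle positions are stored in **voxel units** of the source tomogram with
  axis order ``(x, y, z)``.
* Image arrays are stored in native index order ``(z, y, x)``; conversion
  between the two happens only at module boundaries (resampling, I/O).
* An orientation matrix ``R`` maps **reference-frame** basis vectors onto
  **particle** basis vectors: the particle's local z axis in the tomogram is
  ``R @ [0, 0, 1]`` (i.e. the third column of ``R``).  Use
  :func:`particle_to_reference` for the inverse view.
* ``pixel_spacing`` is in Å/voxel; ``0`` means *unknown* and is propagated as
  such, never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PoseSet",
    "ImageVolume",
    "LabeledVolume",
    "poses_from_points",
    "select_poses",
    "validate",
    "particle_to_reference",
    "read_points_csv",
]

#: tolerance for orthonormality / unit-determinant checks on rotations
ROTATION_ATOL = 1e-6


@dataclass
class PoseSet:
    """A set of particle poses with per-particle features.

    Parameters
    ----------
    positions
        ``(N, 3)`` array, voxel units, axis order ``(x, y, z)``.
    orientations
        ``(N, 3, 3)`` array of proper rotation matrices (reference→particle).
    features
        DataFrame with ``N`` rows of arbitrary scalar/string columns.
    experiment_id
        Identifier tying the poses to their source tomogram.
    pixel_spacing
        Å per voxel; ``0`` if unknown.
    """

    positions: np.ndarray
    orientations: np.ndarray
    features: pd.DataFrame = field(default_factory=pd.DataFrame)
    experiment_id: str = ""
    pixel_spacing: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3, 3)
        n = len(self.positions)
        if len(self.orientations) != n:
            raise ValueError(
                f"positions ({n}) and orientations ({len(self.orientations)}) disagree"
            )
        if self.features is None or len(self.features.columns) == 0 and len(self.features) == 0:
            self.features = pd.DataFrame(index=range(n))
        if len(self.features) != n:
            raise ValueError(f"features has {len(self.features)} rows, expected {n}")
        self.features = self.features.reset_index(drop=True)
        violations = validate(self)
        if violations:
            raise ValueError("invalid PoseSet: " + "; ".join(violations[:5]))

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ImageVolume:
    """A 2D/3D intensity array (or stack) with pixel spacing metadata.

    ``data`` uses axis order ``(z, y, x)`` (or ``(y, x)`` for 2D).  Lazily
    loaded data (e.g. a memory map) is accepted; finiteness is only enforced
    for in-memory arrays so metadata stays available without touching voxels.
    """

    data: np.ndarray
    pixel_spacing: float = 0.0
    experiment_id: str = ""

    def __post_init__(self) -> None:
        if self.pixel_spacing < 0:
            raise ValueError("pixel_spacing must be >= 0")
        if isinstance(self.data, np.ndarray) and not isinstance(self.data, np.memmap):
            if not np.all(np.isfinite(self.data)):
                raise ValueError("image data contains non-finite values")

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class LabeledVolume:
    """An n-D integer label array; ``0`` is background."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"label dtype must be integer, got {self.data.dtype}")
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be non-negative")


def _check_rotations(rotations: np.ndarray, atol: float = ROTATION_ATOL) -> list[str]:
    """Return one message per rotation violating det=+1 / orthonormality."""
    out: list[str] = []
    if len(rotations) == 0:
        return out
    dets = np.linalg.det(rotations)
    gram = np.einsum("nij,nik->njk", rotations, rotations)
    ortho = np.abs(gram - np.eye(3)).max(axis=(1, 2))
    for i in np.nonzero(np.abs(dets - 1.0) >= atol)[0]:
        out.append(f"orientations: det(R)={dets[i]:.6g} != 1 at row {i}")
    for i in np.nonzero(ortho >= atol)[0]:
        out.append(f"orientations: R^T R deviates from I by {ortho[i]:.3g} at row {i}")
    return out


def validate(poses: PoseSet) -> list[str]:
    """Check every :class:`PoseSet` invariant; return human-readable violations.

    An empty list means the pose set is valid.  Each violation names the field
    and the offending row.
    """
    out: list[str] = []
    pos = np.asarray(poses.positions, dtype=float)
    if pos.ndim != 2 or pos.shape[1] != 3:
        return [f"positions: expected (N, 3), got {pos.shape}"]
    bad = np.nonzero(~np.isfinite(pos).all(axis=1))[0]
    for i in bad:
        out.append(f"positions: non-finite coordinate at row {i}")
    rot = np.asarray(poses.orientations, dtype=float)
    if rot.shape != (len(pos), 3, 3):
        out.append(f"orientations: expected ({len(pos)}, 3, 3), got {rot.shape}")
    else:
        out.extend(_check_rotations(rot))
    if len(poses.features) != len(pos):
        out.append(f"features: {len(poses.features)} rows for {len(pos)} poses")
    if poses.pixel_spacing < 0:
        out.append(f"pixel_spacing: negative ({poses.pixel_spacing})")
    return out


def poses_from_points(
    points: np.ndarray, experiment_id: str = "", pixel_spacing: float = 0.0
) -> PoseSet:
    """Turn manually clicked points into identity-oriented particle poses.

    Every orientation is the identity; the feature table carries only a
    ``particle_index`` column.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if points.size and not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite coordinates")
    n = len(points)
    return PoseSet(
        positions=points,
        orientations=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        features=pd.DataFrame({"particle_index": np.arange(n)}),
        experiment_id=experiment_id,
        pixel_spacing=float(pixel_spacing),
    )


def select_poses(poses: PoseSet, feature: str, lo: float, hi: float) -> PoseSet:
    """Select the sub-PoseSet whose ``feature`` value lies in ``[lo, hi]``.

    Order is preserved; the feature table is subset row-wise.  This is the
    library form of picking a band on a per-particle feature plot.
    """
    if feature not in poses.features.columns:
        raise KeyError(f"no feature column named {feature!r}")
    if lo > hi:
        raise ValueError(f"lo ({lo}) > hi ({hi})")
    values = pd.to_numeric(poses.features[feature])
    keep = np.asarray((values >= lo) & (values <= hi))
    return PoseSet(
        positions=poses.positions[keep],
        orientations=poses.orientations[keep],
        features=poses.features.loc[keep].reset_index(drop=True),
        experiment_id=poses.experiment_id,
        pixel_spacing=poses.pixel_spacing,
    )


def particle_to_reference(poses: PoseSet) -> np.ndarray:
    """The inverse orientation view: matrices mapping particle→reference."""
    return np.transpose(poses.orientations, (0, 2, 1))


def read_points_csv(path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read a plain-text point list of manual picks.

    Accepts CSV/TSV/whitespace tables with 3 or 4 numeric columns
    (``x, y, z[, group]``), with or without a header row.  Returns
    ``(points, groups)``; ``groups`` is ``None`` when absent.
    """
    df = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    # drop a header row if the first row is non-numeric
    first = pd.to_numeric(df.iloc[0], errors="coerce")
    if first.isna().any():
        df = df.iloc[1:].reset_index(drop=True)
    df = df.apply(pd.to_numeric)
    if df.shape[1] not in (3, 4):
        raise ValueError(f"expected 3 or 4 columns (x,y,z[,group]), got {df.shape[1]}")
    points = df.iloc[:, :3].to_numpy(dtype=float)
    if not np.all(np.isfinite(points)):
        raise ValueError("point list contains non-finite coordinates")
    groups = df.iloc[:, 3].to_numpy() if df.shape[1] == 4 else None
    return points, groups
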