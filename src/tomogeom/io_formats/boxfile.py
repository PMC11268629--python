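"""EMAN BOX and CrYOLO CBOX particle coordinate files.

A ``.box`` line is ``x y w h`` (or ``x y z w h d`` for 3D picks), giving the
lower corner and extent of a box; the particle sits at the box centre.  A
``.cbox`` file is CrYOLO's STAR dialect (``data_cryolo_coordinates`` block
with ``_CoordinateX/Y/Z``, ``_Width/Height/Depth`` and ``_Confidence``
columns); coordinates are again box corners and the confidence is kept as a
feature.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tomogeom.core_model import PoseSet
from tomogeom.io_formats.errors import FormatError
from tomogeom.io_formats.starparse import parse_star

__all__ = ["read_boxfile", "write_boxfile"]


def _read_box(path) -> PoseSet:
    centers = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                vals = [float(tok) for tok in line.split()]
            except ValueError as e:
                raise FormatError(f"non-numeric value on line {lineno}: {e}") from e
            if len(vals) == 4:
                x, y, w, h = vals
                centers.append((x + w / 2, y + h / 2, 0.0))
            elif len(vals) == 6:
                x, y, z, w, h, d = vals
                centers.append((x + w / 2, y + h / 2, z + d / 2))
            else:
                raise FormatError(
                    f"line {lineno}: expected 4 (2D) or 6 (3D) fields, got {len(vals)}"
                )
    n = len(centers)
    return PoseSet(
        positions=np.asarray(centers, dtype=float).reshape(n, 3),
        orientations=np.broadcast_to(np.eye(3), (n, 3, 3)).copy(),
        features=pd.DataFrame(index=range(n)),
    )


def _read_cbox(path) -> PoseSet:
    blocks = parse_star(path)
    df = next(
        (b for name, b in blocks.items() if "CoordinateX" in b.columns), None
    )
    if df is None:
        raise FormatError("no block with _CoordinateX found in CBOX file")
    pos = np.zeros((len(df), 3))
    for i, (coord, size) in enumerate(
        zip(("CoordinateX", "CoordinateY", "CoordinateZ"), ("Width", "Height", "Depth"))
    ):
        if coord in df.columns:
            pos[:, i] = pd.to_numeric(df[coord], errors="coerce").fillna(0.0)
            if size in df.columns:
                extent = pd.to_numeric(df[size], errors="coerce").fillna(0.0)
                pos[:, i] += extent / 2
    features = pd.DataFrame(index=range(len(df)))
    if "Confidence" in df.columns:
        features["confidence"] = pd.to_numeric(df["Confidence"]).to_numpy()
    return PoseSet(
        positions=pos,
        orientations=np.broadcast_to(np.eye(3), (len(df), 3, 3)).copy(),
        features=features,
    )


def read_boxfile(path, dialect: str | None = None) -> PoseSet:
    """Read an EMAN ``.box`` or CrYOLO ``.cbox`` file.

    ``dialect`` is guessed from the extension when not given.
    """
    if dialect is None:
        dialect = "cbox" if str(path).lower().endswith(".cbox") else "box"
    if dialect == "box":
        return _read_box(path)
    if dialect == "cbox":
        return _read_cbox(path)
    raise ValueError(f"unknown box dialect {dialect!r}")


def write_boxfile(poses: PoseSet, path, box_size: float = 0.0) -> None:
    """Write particle centres as a 2D/3D EMAN box file.

    Boxes of extent ``box_size`` are placed so their centres are the pose
    positions.  3D lines are written when any z coordinate is nonzero.
    """
    three_d = bool(np.any(poses.positions[:, 2] != 0))
    with open(path, "w") as fh:
        for p in poses.positions:
            if three_d:
                corner = p - box_size / 2
                fh.write(
                    f"{corner[0]:.4f} {corner[1]:.4f} {corner[2]:.4f} "
                    f"{box_size:.4f} {box_size:.4f} {box_size:.4f}\n"
                )
            else:
                corner = p[:2] - box_size / 2
                fh.write(
                    f"{corner[0]:.4f} {corner[1]:.4f} {box_size:.4f} {box_size:.4f}\n"
                )
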