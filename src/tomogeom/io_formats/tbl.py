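"""Dynamo TBL particle tables.

A TBL file is a whitespace-separated numeric table with one row per
particle.  The 1-indexed column layout used here (the documented Dynamo
convention):

* 1 — tag (particle id)
* 4, 5, 6 — shifts dx, dy, dz (pixels)
* 7, 8, 9 — Euler angles tdrot, tilt, narot (degrees, ZXZ)
* 20 — volume id (grouping)
* 24, 25, 26 — x, y, z coordinates (pixels)

Positions are ``coordinates + shifts``.  Tables with fewer than 26 columns
are padded with zeros on read if they reach the coordinate columns of a
shorter accepted dialect; on write, all unused columns are zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tomogeom.core_model import PoseSet
from tomogeom.io_formats.errors import FormatError
from tomogeom.io_formats.euler import eulers_to_matrices, matrices_to_eulers

__all__ = ["read_tbl", "write_tbl"]

N_COLS = 26


def _load_table(path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as e:
                raise FormatError(f"non-numeric value on line {lineno}: {e}") from e
    if not rows:
        return np.empty((0, N_COLS))
    width = max(len(r) for r in rows)
    if width < N_COLS:
        # shorter dialect: right-pad with zeros
        width = N_COLS
    table = np.zeros((len(rows), width))
    for i, r in enumerate(rows):
        table[i, : len(r)] = r
    return table


def read_tbl(path) -> list[PoseSet]:
    """Read a Dynamo TBL file into one PoseSet per volume id."""
    table = _load_table(path)
    positions = table[:, 23:26] + table[:, 3:6]
    orientations = eulers_to_matrices(table[:, 6:9], "dynamo_zxz")
    tags = table[:, 0]
    volumes = table[:, 19]
    out = []
    for vol in pd.unique(volumes):
        idx = np.nonzero(volumes == vol)[0]
        out.append(
            PoseSet(
                positions=positions[idx],
                orientations=orientations[idx],
                features=pd.DataFrame({"tag": tags[idx]}),
                experiment_id=str(int(vol)) if float(vol).is_integer() else str(vol),
                pixel_spacing=0.0,
            )
        )
    return out


def write_tbl(posesets: list[PoseSet] | PoseSet, path) -> None:
    """Write PoseSets as a Dynamo TBL (coordinates in cols 24-26, zero shifts).

    Volume id (column 20) enumerates the pose sets (1-based) unless an
    experiment_id is itself an integer string, which is then used directly.
    Values are written with 6 decimals so orientation matrices survive a
    round trip to better than 1e-6.
    """
    if isinstance(posesets, PoseSet):
        posesets = [posesets]
    blocks = []
    tag0 = 1
    for i, ps in enumerate(posesets, start=1):
        n = len(ps)
        table = np.zeros((n, N_COLS))
        tags = (
            ps.features["tag"].to_numpy(dtype=float)
            if "tag" in ps.features.columns
            else np.arange(tag0, tag0 + n, dtype=float)
        )
        tag0 += n
        table[:, 0] = tags
        table[:, 1] = 1.0  # aligned flag, Dynamo convention
        table[:, 6:9] = matrices_to_eulers(ps.orientations, "dynamo_zxz")
        try:
            vol = int(ps.experiment_id)
        except (TypeError, ValueError):
            vol = i
        table[:, 19] = vol
        table[:, 23:26] = ps.positions
        blocks.append(table)
    full = np.concatenate(blocks, axis=0) if blocks else np.empty((0, N_COLS))
    np.savetxt(path, full, fmt="%.6f")
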