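"""Relion STAR particle tables (Relion >= 3.0).

Positions are reconstructed as ``rlnCoordinate{X,Y,Z} - origin``, where the
origin shift comes from ``rlnOrigin{X,Y,Z}Angst / pixel size`` (Relion 3.1
dialect, preferred) or ``rlnOrigin{X,Y,Z}`` in pixels (3.0 dialect).  The
pixel size is taken from a ``data_optics`` block (``rlnImagePixelSize``)
when present.  One :class:`PoseSet` is produced per distinct
``rlnMicrographName`` / ``rlnTomoName``; unrecognised columns ride along as
features and are written back.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from tomogeom.core_model import PoseSet
from tomogeom.io_formats.errors import FormatError
from tomogeom.io_formats.euler import eulers_to_matrices, matrices_to_eulers
from tomogeom.io_formats.starparse import parse_star, write_star_blocks

__all__ = ["read_star", "write_star"]

COORD_COLS = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")
ANGLE_COLS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
ORIGIN_ANGST_COLS = ("rlnOriginXAngst", "rlnOriginYAngst", "rlnOriginZAngst")
ORIGIN_PX_COLS = ("rlnOriginX", "rlnOriginY", "rlnOriginZ")
GROUP_COLS = ("rlnMicrographName", "rlnTomoName")
_HANDLED = set(COORD_COLS + ANGLE_COLS + ORIGIN_ANGST_COLS + ORIGIN_PX_COLS + GROUP_COLS)


def _particle_block(blocks: dict[str, pd.DataFrame]) -> pd.DataFrame:
    for key in ("particles", ""):
        if key in blocks:
            return blocks[key]
    # fall back to the first block with coordinate columns
    for df in blocks.values():
        if COORD_COLS[0] in df.columns:
            return df
    raise FormatError(f"no particle table with {COORD_COLS[0]} found")


def _pixel_size(blocks: dict[str, pd.DataFrame]) -> float:
    optics = blocks.get("optics")
    if optics is not None and "rlnImagePixelSize" in optics.columns:
        return float(optics["rlnImagePixelSize"].iloc[0])
    return 0.0


def read_star(path) -> list[PoseSet]:
    """Read a Relion STAR particle file into one PoseSet per tomogram."""
    blocks = parse_star(path)
    df = _particle_block(blocks)
    for col in COORD_COLS[:2]:
        if col not in df.columns:
            raise FormatError(f"missing coordinate column {col}")
    pixel = _pixel_size(blocks)

    coords = np.column_stack(
        [
            pd.to_numeric(df[c]) if c in df.columns else np.zeros(len(df))
            for c in COORD_COLS
        ]
    ).astype(float)
    if all(c in df.columns for c in ORIGIN_ANGST_COLS[:2]):
        if pixel <= 0:
            raise FormatError(
                "rlnOriginXAngst present but no optics pixel size to convert it"
            )
        origin = np.column_stack(
            [
                pd.to_numeric(df[c]) if c in df.columns else np.zeros(len(df))
                for c in ORIGIN_ANGST_COLS
            ]
        ).astype(float) / pixel
    elif all(c in df.columns for c in ORIGIN_PX_COLS[:2]):
        origin = np.column_stack(
            [
                pd.to_numeric(df[c]) if c in df.columns else np.zeros(len(df))
                for c in ORIGIN_PX_COLS
            ]
        ).astype(float)
    else:
        origin = np.zeros_like(coords)
    positions = coords - origin

    if all(c in df.columns for c in ANGLE_COLS):
        angles = df[list(ANGLE_COLS)].to_numpy(dtype=float)
        orientations = eulers_to_matrices(angles, "relion_zyz")
    else:
        orientations = np.broadcast_to(np.eye(3), (len(df), 3, 3)).copy()

    group_col = next((c for c in GROUP_COLS if c in df.columns), None)
    extra = [c for c in df.columns if c not in _HANDLED]

    out = []
    groups = df.groupby(group_col, sort=False).indices if group_col else {"": np.arange(len(df))}
    for exp_id, idx in groups.items():
        idx = np.asarray(idx)
        out.append(
            PoseSet(
                positions=positions[idx],
                orientations=orientations[idx],
                features=df.iloc[idx][extra].reset_index(drop=True),
                experiment_id=str(exp_id),
                pixel_spacing=pixel,
            )
        )
    return out


def write_star(posesets: list[PoseSet] | PoseSet, path) -> None:
    """Write PoseSets as a Relion 3.1-style STAR file.

    Orientations are stored as rot/tilt/psi ZYZ Euler angles; positions go
    to the coordinate columns with zero origins.  A ``data_optics`` block
    with the pixel size is emitted when the spacing is known (> 0).
    """
    if isinstance(posesets, PoseSet):
        posesets = [posesets]
    frames = []
    for ps in posesets:
        angles = matrices_to_eulers(ps.orientations, "relion_zyz")
        df = pd.DataFrame(
            {
                "rlnCoordinateX": ps.positions[:, 0],
                "rlnCoordinateY": ps.positions[:, 1],
                "rlnCoordinateZ": ps.positions[:, 2],
                "rlnAngleRot": angles[:, 0],
                "rlnAngleTilt": angles[:, 1],
                "rlnAnglePsi": angles[:, 2],
                "rlnMicrographName": ps.experiment_id or "unknown",
            }
        )
        for col in ps.features.columns:
            df[col] = ps.features[col].to_numpy()
        frames.append(df)
    particles = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=list(COORD_COLS + ANGLE_COLS) + ["rlnMicrographName"]
    )
    blocks: dict[str, pd.DataFrame] = {}
    pixel = max((ps.pixel_spacing for ps in posesets), default=0.0)
    if pixel > 0:
        blocks["optics"] = pd.DataFrame(
            {"rlnOpticsGroup": [1], "rlnImagePixelSize": [float(pixel)]}
        )
    blocks["particles"] = particles
    write_star_blocks(blocks, path, float_format="%.6f")
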