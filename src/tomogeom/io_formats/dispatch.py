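"""Format guessing: one `read_any` entry point over all readers.

Dispatch is by file extension.  An optional ``name_regex`` extracts a shared
experiment id from each file stem (e.g. ``r"tomo_\\d+"`` makes
``tomo_01.mrc`` and ``tomo_01.star`` both carry id ``tomo_01``), which is
how images and particle sets from the same tomogram are associated.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import tifffile

from tomogeom.core_model import ImageVolume, PoseSet
from tomogeom.io_formats.boxfile import read_boxfile
from tomogeom.io_formats.em import read_em
from tomogeom.io_formats.errors import DispatchError
from tomogeom.io_formats.mrc import MRC_EXTENSIONS, read_mrc, write_mrc
from tomogeom.io_formats.star import read_star, write_star
from tomogeom.io_formats.tbl import read_tbl, write_tbl

__all__ = ["read_image", "write_image", "read_any", "write_poses"]

TIFF_EXTENSIONS = (".tif", ".tiff")
POSE_EXTENSIONS = (".star", ".tbl", ".box", ".cbox")
IMAGE_EXTENSIONS = MRC_EXTENSIONS + TIFF_EXTENSIONS + (".em",)
SUPPORTED = POSE_EXTENSIONS + IMAGE_EXTENSIONS


def read_image(path, lazy: bool = False) -> ImageVolume:
    """Read an MRC/TIFF/EM image into an ImageVolume ((z, y, x) order)."""
    ext = Path(path).suffix.lower()
    if ext in MRC_EXTENSIONS:
        return read_mrc(path, lazy=lazy)
    if ext in TIFF_EXTENSIONS:
        return ImageVolume(
            data=np.asarray(tifffile.imread(path)), pixel_spacing=0.0
        )
    if ext == ".em":
        return read_em(path)
    raise DispatchError(
        f"unsupported image extension {ext!r}; supported: {IMAGE_EXTENSIONS}"
    )


def write_image(volume: ImageVolume, path) -> None:
    """Write an ImageVolume as MRC (with voxel size) or TIFF (no spacing)."""
    ext = Path(path).suffix.lower()
    if ext in MRC_EXTENSIONS:
        write_mrc(volume, path)
    elif ext in TIFF_EXTENSIONS:
        tifffile.imwrite(path, np.asarray(volume.data))
    else:
        raise DispatchError(
            f"unsupported image extension {ext!r} for writing; "
            f"supported: {MRC_EXTENSIONS + TIFF_EXTENSIONS}"
        )


def write_poses(posesets, path) -> None:
    """Write pose sets to STAR or TBL, chosen by extension."""
    ext = Path(path).suffix.lower()
    if ext == ".star":
        write_star(posesets, path)
    elif ext == ".tbl":
        write_tbl(posesets, path)
    else:
        raise DispatchError(
            f"unsupported particle extension {ext!r} for writing; "
            "supported: ('.star', '.tbl')"
        )


def _read_one(path: Path, lazy: bool) -> list:
    ext = path.suffix.lower()
    if ext == ".star":
        return read_star(path)
    if ext == ".tbl":
        return read_tbl(path)
    if ext in (".box", ".cbox"):
        return [read_boxfile(path)]
    if ext in IMAGE_EXTENSIONS:
        return [read_image(path, lazy=lazy)]
    raise DispatchError(f"unknown extension {ext!r}; supported: {SUPPORTED}")


def read_any(
    paths, name_regex: str | None = None, lazy: bool = False
) -> list[PoseSet | ImageVolume]:
    """Read any mix of particle and image files, guessing formats.

    ``paths`` may be a single path, a list of paths, or directories (scanned
    non-recursively for supported extensions).  ``lazy=True`` memory-maps
    image voxel data so larger-than-memory volumes open instantly.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    files: list[Path] = []
    for p in map(Path, paths):
        if p.is_dir():
            files.extend(
                sorted(
                    f for f in p.iterdir() if f.suffix.lower() in SUPPORTED
                )
            )
        else:
            files.append(p)
    pattern = re.compile(name_regex) if name_regex else None
    out: list[PoseSet | ImageVolume] = []
    for f in files:
        objs = _read_one(f, lazy)
        if pattern is not None:
            match = pattern.search(f.stem)
            if match:
                for obj in objs:
                    obj.experiment_id = match.group(0)
        out.extend(objs)
    return out
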