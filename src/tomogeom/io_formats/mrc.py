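"""MRC2014 volume reader/writer (modes 0/1/2/6 read, mode 2 write).

The MRC2014 layout: a 1024-byte header of 32-bit words (dimensions, mode,
sampling grid, cell size in Å, statistics, ``MAP `` stamp, machine stamp),
an optional extended header of ``nsymbt`` bytes, then the voxel data with x
fastest — i.e. a C-ordered ``(nz, ny, nx)`` array.  The voxel size is
``cella / (mx, my, mz)`` and is stored per axis; a single scalar spacing is
reported when the three agree (0 when absent).
"""

from __future__ import annotations

import numpy as np

from tomogeom.core_model import ImageVolume
from tomogeom.io_formats.errors import FormatError

__all__ = ["read_mrc", "write_mrc", "MRC_EXTENSIONS"]

MRC_EXTENSIONS = (".mrc", ".mrcs", ".st", ".map", ".rec")

_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}

_HEADER = np.dtype(
    [
        ("nx", "i4"), ("ny", "i4"), ("nz", "i4"),
        ("mode", "i4"),
        ("nxstart", "i4"), ("nystart", "i4"), ("nzstart", "i4"),
        ("mx", "i4"), ("my", "i4"), ("mz", "i4"),
        ("cella", "f4", 3),
        ("cellb", "f4", 3),
        ("mapc", "i4"), ("mapr", "i4"), ("maps", "i4"),
        ("dmin", "f4"), ("dmax", "f4"), ("dmean", "f4"),
        ("ispg", "i4"),
        ("nsymbt", "i4"),
        ("extra1", "V8"),
        ("exttyp", "S4"),
        ("nversion", "i4"),
        ("extra2", "V84"),
        ("origin", "f4", 3),
        ("map", "S4"),
        ("machst", "u1", 4),
        ("rms", "f4"),
        ("nlabl", "i4"),
        ("labels", "S80", 10),
    ]
)
assert _HEADER.itemsize == 1024


def _read_header(fh) -> np.void:
    raw = fh.read(1024)
    if len(raw) < 1024:
        raise FormatError("truncated MRC file: header shorter than 1024 bytes")
    header = np.frombuffer(raw, dtype=_HEADER.newbyteorder("<"))[0]
    if header["machst"][0] == 0x11:  # big-endian machine stamp
        header = np.frombuffer(raw, dtype=_HEADER.newbyteorder(">"))[0]
    if int(header["mode"]) not in _MODE_DTYPES:
        raise FormatError(f"unsupported MRC mode {int(header['mode'])}")
    return header


def read_mrc(path, lazy: bool = False) -> ImageVolume:
    """Read an MRC2014 file into an ImageVolume (data order (z, y, x)).

    With ``lazy=True`` the voxel data is memory-mapped: header metadata is
    available immediately and voxels are read from disk on first access.
    """
    with open(path, "rb") as fh:
        header = _read_header(fh)
    nx, ny, nz = int(header["nx"]), int(header["ny"]), int(header["nz"])
    mode = int(header["mode"])
    dtype = np.dtype(_MODE_DTYPES[mode])
    if header["machst"][0] == 0x11:
        dtype = dtype.newbyteorder(">")
    offset = 1024 + int(header["nsymbt"])
    shape = (nz, ny, nx) if nz > 1 else ((ny, nx) if nz == 1 else (nz, ny, nx))

    spacing = 0.0
    m = np.array([header["mx"], header["my"], header["mz"]], dtype=float)
    cella = np.asarray(header["cella"], dtype=float)
    if np.all(m > 0) and np.all(cella > 0):
        per_axis = cella / m
        if np.allclose(per_axis, per_axis[0], rtol=1e-4):
            spacing = float(per_axis[0])

    if lazy:
        data = np.memmap(path, dtype=dtype, mode="r", offset=offset, shape=shape)
    else:
        with open(path, "rb") as fh:
            fh.seek(offset)
            count = int(np.prod(shape))
            data = np.fromfile(fh, dtype=dtype, count=count)
            if data.size < count:
                raise FormatError(
                    f"truncated MRC data: expected {count} voxels, got {data.size}"
                )
            data = data.reshape(shape)
    return ImageVolume(data=data, pixel_spacing=spacing, experiment_id="")


def write_mrc(volume: ImageVolume, path) -> None:
    """Write an ImageVolume as MRC2014 mode 2 (32-bit float), voxel size set."""
    data = np.asarray(volume.data, dtype=np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise ValueError(f"MRC writer expects 2D or 3D data, got {data.ndim}D")
    nz, ny, nx = data.shape
    spacing = float(volume.pixel_spacing) if volume.pixel_spacing > 0 else 1.0
    header = np.zeros((), dtype=_HEADER.newbyteorder("<"))
    header["nx"], header["ny"], header["nz"] = nx, ny, nz
    header["mode"] = 2
    header["mx"], header["my"], header["mz"] = nx, ny, nz
    header["cella"] = (nx * spacing, ny * spacing, nz * spacing)
    header["cellb"] = (90.0, 90.0, 90.0)
    header["mapc"], header["mapr"], header["maps"] = 1, 2, 3
    header["dmin"], header["dmax"], header["dmean"] = (
        float(data.min()) if data.size else 0.0,
        float(data.max()) if data.size else 0.0,
        float(data.mean()) if data.size else 0.0,
    )
    header["ispg"] = 1
    header["nversion"] = 20140
    header["map"] = b"MAP "
    header["machst"] = (0x44, 0x44, 0, 0)
    header["rms"] = float(data.std()) if data.size else 0.0
    with open(path, "wb") as fh:
        fh.write(header.tobytes())
        fh.write(np.ascontiguousarray(data).tobytes())
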