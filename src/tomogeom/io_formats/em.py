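"""Dynamo/TOM EM image format (read-only).

An EM file has a 512-byte header: four leading bytes (machine code, two
reserved bytes, a data-type code), three little-endian int32 dimensions
(x, y, z), and padding/comment fields; voxel data follows with x fastest,
i.e. a C-ordered ``(nz, ny, nx)`` array.  No pixel spacing is stored.
"""

from __future__ import annotations

import numpy as np

from tomogeom.core_model import ImageVolume
from tomogeom.io_formats.errors import FormatError

__all__ = ["read_em"]

# data-type codes: 1 int8, 2 int16, 4 int32, 5 float32, 9 float64
_EM_DTYPES = {1: np.int8, 2: np.int16, 4: np.int32, 5: np.float32, 9: np.float64}


def read_em(path) -> ImageVolume:
    with open(path, "rb") as fh:
        raw = fh.read(512)
        if len(raw) < 512:
            raise FormatError("truncated EM file: header shorter than 512 bytes")
        machine = raw[0]
        # machine code 6 = PC (little-endian); 0/3/5 are big-endian platforms
        order = "<" if machine in (6, 2, 4) else ">"
        type_code = raw[3]
        if type_code not in _EM_DTYPES:
            raise FormatError(f"unsupported EM data type code {type_code}")
        dims = np.frombuffer(raw, dtype=f"{order}i4", count=3, offset=4)
        nx, ny, nz = (int(d) for d in dims)
        dtype = np.dtype(_EM_DTYPES[type_code]).newbyteorder(order)
        count = nx * ny * nz
        data = np.fromfile(fh, dtype=dtype, count=count)
        if data.size < count:
            raise FormatError(f"truncated EM data: expected {count} voxels")
    shape = (nz, ny, nx) if nz > 1 else (ny, nx)
    return ImageVolume(
        data=data.reshape(shape).astype(np.float32), pixel_spacing=0.0
    )
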