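"""Minimal MRC/MRCS container support (mode 2, 32-bit real).

Implements the 1024-byte MRC2014 header with the fields this package
needs: dimensions, mode, cell size (pixel size), axis order, statistics,
the MAP magic and little-endian machine stamp.  Image stacks are stored
with nz = number of images.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 1024


def write_mrcs(images: np.ndarray, pixel_size_A: float, path) -> None:
    """Write an (N, P, P) stack (or a 3D volume) as MRC mode 2."""
    images = np.ascontiguousarray(images, dtype="<f4")
    if images.ndim != 3:
        raise ValueError("expected a 3D array (stack or volume)")
    nz, ny, nx = images.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)
    struct.pack_into("<i", header, 12, 2)                       # mode 2: float32
    struct.pack_into("<3i", header, 28, nx, ny, nz)             # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * pixel_size_A,
                     ny * pixel_size_A, nz * pixel_size_A)      # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)       # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)                # mapc, mapr, maps
    struct.pack_into("<3f", header, 76, float(images.min()),
                     float(images.max()), float(images.mean()))
    struct.pack_into("<i", header, 92, 0)                       # ispg
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0x00, 0x00])           # little-endian stamp
    struct.pack_into("<f", header, 216, float(images.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(images.tobytes())


def read_mrcs(path):
    """Read an MRC mode-2 file; returns (images (nz, ny, nx) float32,
    pixel_size_A)."""
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise ValueError(f"{path}: truncated header ({len(raw)} < {_HEADER_SIZE} bytes)")
    nx, ny, nz = struct.unpack_from("<3i", raw, 0)
    mode, = struct.unpack_from("<i", raw, 12)
    if mode != 2:
        raise ValueError(f"{path}: unsupported MRC mode {mode} (only mode 2 supported)")
    mx, = struct.unpack_from("<i", raw, 28)
    cella_x, = struct.unpack_from("<f", raw, 40)
    expected = _HEADER_SIZE + 4 * nx * ny * nz
    if len(raw) < expected:
        raise ValueError(f"{path}: truncated data: expected {expected} bytes, "
                         f"found {len(raw)}")
    data = np.frombuffer(raw[_HEADER_SIZE:expected], dtype="<f4").reshape(nz, ny, nx)
    pixel = cella_x / mx if mx else 1.0
    return data.copy(), float(pixel)
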