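"""Minimal NRRD reader/writer for 3D label volumes (raw and gzip encodings).

Covers the subset of NRRD used for plain label volumes exported from
segmentation tools: attached-header files, C-ordered data with the fastest
axis first in ``sizes`` (x y z, i.e. the mirror of this package's (z, y, x)
array order), spacing from ``spacings`` or diagonal ``space directions``.
"""

from __future__ import annotations

import gzip

import numpy as np

_TYPE_MAP = {
    "signed char": np.int8, "int8": np.int8, "int8_t": np.int8,
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8, "uint8_t": np.uint8,
    "short": np.int16, "int16": np.int16, "int16_t": np.int16,
    "ushort": np.uint16, "unsigned short": np.uint16, "uint16": np.uint16, "uint16_t": np.uint16,
    "int": np.int32, "int32": np.int32, "int32_t": np.int32,
    "uint": np.uint32, "unsigned int": np.uint32, "uint32": np.uint32, "uint32_t": np.uint32,
    "long long": np.int64, "int64": np.int64, "int64_t": np.int64,
    "unsigned long long": np.uint64, "uint64": np.uint64, "uint64_t": np.uint64,
    "float": np.float32, "double": np.float64,
}


def read(path):
    """Return ``(grid, spacing)`` with grid in (z, y, x) order; spacing may be None."""
    from .volumes import VoxelSpacing

    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise ValueError(f"{path}: not an NRRD file")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", errors="replace").strip()
            if not text or text.startswith("#"):
                continue
            if ":=" in text:
                key, _, val = text.partition(":=")
            else:
                key, _, val = text.partition(":")
            fields[key.strip().lower()] = val.strip()
        data = fh.read()

    if int(fields.get("dimension", "0")) != 3:
        raise ValueError(f"{path}: expected a 3D NRRD (dimension: 3)")
    dtype = _TYPE_MAP.get(fields.get("type", ""))
    if dtype is None:
        raise ValueError(f"{path}: unsupported NRRD type {fields.get('type')!r}")
    sizes = [int(s) for s in fields["sizes"].split()]  # fastest first: x y z
    encoding = fields.get("encoding", "raw").lower()
    if encoding in ("gzip", "gz"):
        data = gzip.decompress(data)
    elif encoding != "raw":
        raise ValueError(f"{path}: unsupported NRRD encoding {encoding!r}")
    endian = fields.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    grid = np.frombuffer(data, dtype=dt, count=int(np.prod(sizes)))
    # NRRD's first axis is fastest-varying; a C-ordered (z, y, x) array has x
    # fastest, so sizes (x, y, z) reshape to shape (z, y, x) directly.
    grid = grid.reshape(sizes[::-1]).astype(dtype)

    spacing = None
    if "spacings" in fields:
        sx, sy, sz = [float(s) for s in fields["spacings"].split()]
        spacing = VoxelSpacing(sz, sy, sx)
    elif "space directions" in fields:
        vecs = []
        for token in fields["space directions"].split(") ("):
            token = token.strip().strip("()")
            vecs.append([float(v) for v in token.replace(",", " ").split()])
        if len(vecs) == 3:
            sx, sy, sz = (float(np.linalg.norm(v)) for v in vecs)
            spacing = VoxelSpacing(sz, sy, sx)
    return grid, spacing


_INV_TYPE = {
    np.dtype(np.uint8): "uint8", np.dtype(np.int8): "int8",
    np.dtype(np.uint16): "uint16", np.dtype(np.int16): "int16",
    np.dtype(np.uint32): "uint32", np.dtype(np.int32): "int32",
    np.dtype(np.uint64): "uint64", np.dtype(np.int64): "int64",
    np.dtype(np.float32): "float", np.dtype(np.float64): "double",
}


def write(path, grid: np.ndarray, spacing, encoding: str = "gzip") -> None:
    grid = np.ascontiguousarray(grid)
    if grid.ndim != 3:
        raise ValueError("only 3D volumes are written")
    tname = _INV_TYPE.get(grid.dtype)
    if tname is None:
        grid = grid.astype(np.int64)
        tname = "int64"
    nz, ny, nx = grid.shape
    header = [
        "NRRD0004",
        f"type: {tname}",
        "dimension: 3",
        f"sizes: {nx} {ny} {nz}",
        f"spacings: {spacing.dx:.17g} {spacing.dy:.17g} {spacing.dz:.17g}",
        "endian: little",
        f"encoding: {encoding}",
    ]
    payload = grid.astype(grid.dtype.newbyteorder("<")).tobytes(order="C")
    if encoding == "gzip":
        payload = gzip.compress(payload)
    elif encoding != "raw":
        raise ValueError(f"unsupported encoding {encoding!r}")
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n\n").encode("ascii"))
        fh.write(payload)
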