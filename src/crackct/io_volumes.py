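"""Volume and table I/O for tooth micro-CT data.

All volumes are rank-3 arrays in ``(z, y, x)`` order with *z* the vertical
tooth axis, 0-based indices, and an isotropic voxel pitch in micrometres.
Greyscale attenuation volumes are stored as unsigned 16-bit, label volumes
as unsigned 8-bit with the fixed code set ``{0: air, 1: enamel, 2: dentin,
3: crack}``.

Supported on-disk formats: multi-page TIFF stacks (one page per z-slice,
via :mod:`tifffile`, pitch carried in the image description as JSON) and
NRRD (raw encoding, pitch in the ``spacings`` header field; a minimal
reader/writer is included). Component tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

#: Label codes, fixed package-wide.
AIR = 0
ENAMEL = 1
DENTIN = 2
CRACK = 3
LABEL_NAMES = {AIR: "air", ENAMEL: "enamel", DENTIN: "dentin", CRACK: "crack"}
N_CLASSES = 4

_FORMATS = ("tiff-stack", "nrrd")


@dataclass
class GreyVolume:
    """A 3D attenuation volume with isotropic voxel pitch.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative attenuation values; stored as ``uint16``.
    voxel_pitch_um : float
        Isotropic voxel edge length in micrometres (> 0).
    """

    data: np.ndarray
    voxel_pitch_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"volume must be rank 3, got rank {arr.ndim}")
        if not np.issubdtype(arr.dtype, np.integer) or arr.dtype != np.uint16:
            if arr.size and (arr.min() < 0 or arr.max() > 65535):
                raise ValueError("grey values must lie in [0, 65535]")
            arr = np.rint(arr).astype(np.uint16)
        if not self.voxel_pitch_um > 0:
            raise ValueError("voxel_pitch_um must be positive")
        self.data = arr
        self.voxel_pitch_um = float(self.voxel_pitch_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class LabelVolume:
    """A 3D categorical volume over {air, enamel, dentin, crack}."""

    data: np.ndarray
    voxel_pitch_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"label volume must be rank 3, got rank {arr.ndim}")
        if arr.size and not np.isin(np.unique(arr), [AIR, ENAMEL, DENTIN, CRACK]).all():
            raise ValueError("label codes must be in {0, 1, 2, 3}")
        if not self.voxel_pitch_um > 0:
            raise ValueError("voxel_pitch_um must be positive")
        self.data = arr.astype(np.uint8)
        self.voxel_pitch_um = float(self.voxel_pitch_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "tiff-stack"
    if suffix == ".nrrd":
        return "nrrd"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


# ---------------------------------------------------------------------------
# Minimal NRRD (raw encoding only, the subset this package writes)

def _write_nrrd(path: Path, data: np.ndarray, pitch_um: float) -> None:
    type_name = {np.dtype(np.uint16): "uint16", np.dtype(np.uint8): "uint8"}[data.dtype]
    nz, ny, nx = data.shape
    header = (
        "NRRD0004\n"
        f"type: {type_name}\n"
        "dimension: 3\n"
        f"sizes: {nx} {ny} {nz}\n"  # NRRD lists sizes fastest axis first
        f"spacings: {pitch_um!r} {pitch_um!r} {pitch_um!r}\n"
        "endian: little\n"
        "encoding: raw\n"
        "\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data).astype(data.dtype.newbyteorder("<")).tobytes())


def _read_nrrd(path: Path) -> tuple[np.ndarray, float | None]:
    fields: dict[str, str] = {}
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if not magic.startswith(b"NRRD"):
            raise OSError(f"{path}: not an NRRD file")
        while True:
            line = fh.readline()
            if not line:
                raise OSError(f"{path}: truncated NRRD header")
            line = line.strip()
            if line == b"":
                break
            if line.startswith(b"#"):
                continue
            key, _, value = line.decode("ascii").partition(":")
            fields[key.strip().lower()] = value.strip()
        raw = fh.read()

    if fields.get("encoding", "raw") != "raw":
        raise OSError(f"{path}: only raw NRRD encoding is supported")
    if int(fields["dimension"]) != 3:
        raise ValueError(f"{path}: expected 3D data, got dimension {fields['dimension']}")
    dtype = {"uint16": np.uint16, "uint8": np.uint8, "ushort": np.uint16,
             "uchar": np.uint8}.get(fields["type"])
    if dtype is None:
        raise OSError(f"{path}: unsupported NRRD type {fields['type']!r}")
    nx, ny, nz = (int(s) for s in fields["sizes"].split())
    endian = fields.get("endian", "little")
    dt = np.dtype(dtype).newbyteorder("<" if endian == "little" else ">")
    data = np.frombuffer(raw, dtype=dt, count=nx * ny * nz).reshape(nz, ny, nx)

    pitch: float | None = None
    if "spacings" in fields:
        sp = [float(s) for s in fields["spacings"].split()]
        if not np.allclose(sp, sp[0]):
            raise ValueError(f"{path}: anisotropic spacings {sp}; only isotropic pitch is supported")
        pitch = sp[0]
    return np.array(data), pitch


# ---------------------------------------------------------------------------
# TIFF stacks

def _write_tiff(path: Path, data: np.ndarray, pitch_um: float) -> None:
    desc = json.dumps({"voxel_pitch_um": pitch_um, "axis_order": "zyx"})
    tifffile.imwrite(path, data, description=desc, photometric="minisblack")


def _read_tiff(path: Path) -> tuple[np.ndarray, float | None]:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        pitch = None
        desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
                pitch = float(meta["voxel_pitch_um"])
            except (ValueError, KeyError, TypeError):
                pitch = None
    if data.ndim == 2:
        data = data[None, ...]
    return data, pitch


# ---------------------------------------------------------------------------
# Public API

def read_volume(path, format: str | None = None, *, kind: str = "grey",
                voxel_pitch_um: float | None = None):
    """Read a volume from disk.

    Parameters
    ----------
    path : path-like
    format : {"tiff-stack", "nrrd"}, optional
        Inferred from the file suffix when omitted.
    kind : {"grey", "labels"}
        Container type to return.
    voxel_pitch_um : float, optional
        Override / supply the pitch when the file carries none.

    Returns
    -------
    GreyVolume or LabelVolume
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    data, pitch = (_read_tiff if fmt == "tiff-stack" else _read_nrrd)(path)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    if voxel_pitch_um is not None:
        pitch = float(voxel_pitch_um)
    if pitch is None:
        raise ValueError(f"{path}: no voxel pitch in metadata; pass voxel_pitch_um=")
    cls = GreyVolume if kind == "grey" else LabelVolume
    return cls(data=data, voxel_pitch_um=pitch)


def write_volume(volume, path, format: str | None = None):
    """Write a :class:`GreyVolume` or :class:`LabelVolume`; round-trips bit-exactly."""
    path = Path(path)
    fmt = _infer_format(path, format)
    path.parent.mkdir(parents=True, exist_ok=True)
    writer = _write_tiff if fmt == "tiff-stack" else _write_nrrd
    writer(path, volume.data, volume.voxel_pitch_um)
    return path


COMPONENT_COLUMNS = [
    "component_id", "voxel_count",
    "bbox_z0", "bbox_y0", "bbox_x0", "bbox_z1", "bbox_y1", "bbox_x1",
    "centroid_z", "centroid_y", "centroid_x",
    "lambda1", "lambda2", "lambda3", "planarity",
    "normal_z", "normal_y", "normal_x",
]


def write_component_table(table: pd.DataFrame, path) -> Path:
    """Write a crack-component table as CSV (header always present)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COMPONENT_COLUMNS if c in table.columns] + \
        [c for c in table.columns if c not in COMPONENT_COLUMNS]
    table.loc[:, cols].to_csv(path, index=False)
    return path


def read_component_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
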