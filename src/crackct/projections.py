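"""2D visual summaries: projected density maps and depth-shaded views."""

from __future__ import annotations

import numpy as np

from .morphometry import distance_to_crack_projection
from .segmentation import _AXIS_INDEX


def projected_density(volume_or_mask, axis, scale: str = "sqrt") -> np.ndarray:
    """Sum along ``axis``, optionally square-root scaled for enhancement,
    normalised to [0, 1]."""
    ax = _AXIS_INDEX.get(axis)
    if ax is None:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    if scale not in ("linear", "sqrt"):
        raise ValueError("scale must be 'linear' or 'sqrt'")
    data = volume_or_mask.data if hasattr(volume_or_mask, "voxel_pitch_um") \
        else np.asarray(volume_or_mask)
    if data.size == 0:
        raise ValueError("empty volume")
    proj = data.astype(np.float64).sum(axis=ax)
    if scale == "sqrt":
        proj = np.sqrt(proj)
    peak = proj.max()
    return proj / peak if peak > 0 else proj


def shade_transfer(depth: np.ndarray, axis_length: int) -> np.ndarray:
    """Map first-hit depth to intensity: 1 at the viewer face, ~0 at the far
    face; lines that hit nothing (NaN depth) shade to 0."""
    shade = (axis_length - np.asarray(depth, dtype=np.float64)) / axis_length
    return np.nan_to_num(shade, nan=0.0)


def depth_shaded_projection(mask: np.ndarray, axis) -> np.ndarray:
    """First-hit view of a mask along ``axis``: nearer surfaces lighter,
    farther darker, misses zero."""
    ax = _AXIS_INDEX.get(axis)
    if ax is None:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    depth = distance_to_crack_projection(mask, axis)
    return shade_transfer(depth, np.asarray(mask).shape[ax])


def to_png_u8(image: np.ndarray) -> np.ndarray:
    """Scale a [0, 1] float image to uint8 for PNG export."""
    return np.clip(np.rint(np.asarray(image, dtype=np.float64) * 255), 0, 255
                   ).astype(np.uint8)
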