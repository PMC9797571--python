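"""Three-axis consensus voting and the crack-free fill-in.

The data-cube is segmented three times (slices perpendicular to x, y, z).
A voxel is crack iff at least two of the three per-axis labellings call it
crack; remaining voxels take the majority class among their three non-crack
votes (ties broken by the z-axis label, then y, then x). The fill-in then
reassigns crack voxels (and their dilated neighbourhood) the label of the
nearest non-masked enamel/dentin pixel, slice by slice, restoring the tooth
as if it had no cracks.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .io_volumes import AIR, CRACK, DENTIN, ENAMEL, LabelVolume


def _data(v) -> np.ndarray:
    return v.data if hasattr(v, "voxel_pitch_um") else np.asarray(v)


def _check_shapes(*arrays):
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch between label volumes: {shapes}")


def vote_crack(labels_x, labels_y, labels_z) -> np.ndarray:
    """Boolean mask: crack where at least two of the three labellings agree."""
    lx, ly, lz = _data(labels_x), _data(labels_y), _data(labels_z)
    _check_shapes(lx, ly, lz)
    votes = (lx == CRACK).astype(np.uint8) + (ly == CRACK) + (lz == CRACK)
    return votes >= 2


def resolve_noncrack(labels_x, labels_y, labels_z, crack_mask) -> LabelVolume:
    """Fuse the three labellings into one: crack on the mask; elsewhere the
    majority among {air, enamel, dentin} votes with crack votes discarded,
    ties broken by the z-axis label, then y, then x.

    A non-mask voxel whose three votes are all crack (possible only with an
    externally supplied mask) degenerates to dentin.
    """
    lx, ly, lz = _data(labels_x), _data(labels_y), _data(labels_z)
    mask = np.asarray(crack_mask, dtype=bool)
    _check_shapes(lx, ly, lz, mask)

    counts = np.zeros((3,) + lx.shape, dtype=np.uint8)
    for lab in (lx, ly, lz):
        for code in (AIR, ENAMEL, DENTIN):
            counts[code] += lab == code
    best = counts.max(axis=0)
    out = counts.argmax(axis=0).astype(np.uint8)  # lowest code wins ties here...

    # ...but the contract says ties go to the z label, then y, then x:
    tied = (counts == best[None]).sum(axis=0) > 1
    undecided = tied | (best == 0)
    for lab in (lz, ly, lx):  # first non-crack in z, y, x order
        take = undecided & (lab != CRACK)
        out[take] = lab[take]
        undecided &= ~take
    out[undecided] = DENTIN  # all three votes crack, off-mask: degenerate
    out[mask] = CRACK
    pitch = getattr(labels_z, "voxel_pitch_um", getattr(labels_x, "voxel_pitch_um", 1.0))
    return LabelVolume(data=out, voxel_pitch_um=pitch)


def fill_in(final_labels, crack_mask=None, dilation_radius: int = 1) -> LabelVolume:
    """Restore enamel/dentin under the (dilated) crack mask, slice by slice.

    Per z-slice the crack mask is dilated by ``dilation_radius`` (square
    structuring element, 3x3 at radius 1); every masked pixel currently
    labelled enamel, dentin, or crack is reassigned the code of its nearest
    (Euclidean) non-masked enamel/dentin pixel. Masked air pixels and
    everything outside the dilated mask are untouched, so air is never
    fabricated into tissue. The output contains no crack voxels.

    When ``crack_mask`` is omitted it defaults to ``final_labels == crack``.
    """
    if dilation_radius < 0:
        raise ValueError("dilation_radius must be >= 0")
    lab = _data(final_labels).copy()
    mask = lab == CRACK if crack_mask is None else np.asarray(crack_mask, dtype=bool)
    _check_shapes(lab, mask)
    if not mask.any():
        return LabelVolume(data=lab, voxel_pitch_um=final_labels.voxel_pitch_um)

    size = 2 * dilation_radius + 1
    for z in range(lab.shape[0]):
        m = mask[z]
        if not m.any():
            continue
        if dilation_radius > 0:
            m = ndimage.binary_dilation(m, structure=np.ones((size, size), bool))
        sl = lab[z]
        targets = m & (sl != AIR)
        if not targets.any():
            continue
        sources = ~m & ((sl == ENAMEL) | (sl == DENTIN))
        if not sources.any():
            raise ValueError(f"slice z={z}: tooth region entirely masked; cannot fill in")
        idx = ndimage.distance_transform_edt(~sources, return_distances=False,
                                             return_indices=True)
        sl[targets] = sl[tuple(i[targets] for i in idx)]
    return LabelVolume(data=lab, voxel_pitch_um=final_labels.voxel_pitch_um)
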