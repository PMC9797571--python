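"""Volume resampling, axis alignment, and the 3-slab x 4-sector tooth partition.

The tooth is split into three horizontal slabs of equal height (cervical,
middle, occlusal thirds; remainder slices assigned bottom-up) and, per slab,
four angular sectors (buccal, contact right, palatal, contact left). Sector
boundaries follow the transitions from convex (buccal/palatal) to flatter
(contact) surfaces: on the middle slice of each slab, the boundary curvature
of the tooth cross-section is scanned for the four convex-to-flat transition
points, and the two chords connecting opposite transition points split the
slice into four sectors that are propagated through the slab. When fewer
than four robust transitions exist (e.g. a circular cross-section) the
partition falls back to centroid-anchored +/-45 degree quadrants and flags it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .io_volumes import GreyVolume

SECTOR_NAMES = {1: "buccal", 2: "contact_right", 3: "palatal", 4: "contact_left"}


@dataclass
class SlabSectorPartition:
    """Assignment of tooth voxels to 3 slabs x 4 sectors.

    ``slab`` and ``sector`` are uint8 volumes (0 outside the tooth, slabs
    1-3 bottom-up, sectors 1-4); ``region`` combines them as
    ``(slab - 1) * 4 + sector`` in 1..12. ``fallback_slabs`` lists slabs
    where quadrant fallback replaced curvature-based sector detection.
    """

    slab: np.ndarray
    sector: np.ndarray
    region: np.ndarray
    fallback_slabs: list[int]

    def region_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.region[self.region > 0], return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))


# ---------------------------------------------------------------------------

def resample(volume: GreyVolume, target_pitch_um: float) -> GreyVolume:
    """Block-mean downsample to a coarser pitch (integer ratio only).

    Conserves mean grey value up to output rounding; trailing voxels that do
    not fill a complete block are cropped. Identity when the pitch is
    unchanged. Non-integer pitch ratios raise (no silent interpolation).
    """
    ratio = target_pitch_um / volume.voxel_pitch_um
    if ratio < 1.0 - 1e-9:
        raise ValueError("target pitch must be >= source pitch")
    k = int(round(ratio))
    if abs(ratio - k) > 1e-6:
        raise ValueError(f"pitch ratio {ratio} is not an integer; refusing to interpolate")
    if k == 1:
        return GreyVolume(data=volume.data.copy(), voxel_pitch_um=volume.voxel_pitch_um)
    nz, ny, nx = (s // k for s in volume.shape)
    if min(nz, ny, nx) == 0:
        raise ValueError("volume smaller than one output block")
    d = volume.data[: nz * k, : ny * k, : nx * k].astype(np.float64)
    d = d.reshape(nz, k, ny, k, nx, k).mean(axis=(1, 3, 5))
    return GreyVolume(data=np.rint(d).astype(np.uint16), voxel_pitch_um=target_pitch_um)


def principal_rotation(tooth_mask: np.ndarray) -> np.ndarray:
    """Rotation (3x3, acting on (z, y, x) offsets from the mask centroid)
    mapping the mask's largest principal-moment axis to z and the second to x.

    Eigenvector signs are chosen so each mapped axis keeps a positive
    component along its target, giving the rotation closest to identity.
    """
    coords = np.argwhere(tooth_mask)
    if coords.shape[0] < 4:
        raise ValueError("mask too small for principal-axis alignment")
    c = coords.mean(axis=0)
    cov = np.cov((coords - c).T)
    w, v = np.linalg.eigh(cov)  # ascending eigenvalues
    if w[1] <= 1e-9 * max(w[2], 1.0):
        raise ValueError("degenerate mask: collinear voxel distribution")
    v_major = v[:, 2]   # -> z (index 0)
    v_second = v[:, 1]  # -> x (index 2)
    if v_major[0] < 0:
        v_major = -v_major
    if v_second[2] < 0:
        v_second = -v_second
    v_third = np.cross(v_major, v_second)  # -> y, right-handed in (z, y, x)? see below
    # rows map (z, y, x) target axes to source directions
    R = np.stack([v_major, v_third, v_second])
    if np.linalg.det(R) < 0:
        R[1] = -R[1]
    return R


def _rotate_volume(data: np.ndarray, R: np.ndarray, order: int) -> np.ndarray:
    c = (np.asarray(data.shape, dtype=float) - 1) / 2
    # output[o] = input[R.T @ (o - c) + c]: R maps source offsets to target
    M = R.T
    offset = c - M @ c
    return ndimage.affine_transform(data, M, offset=offset, order=order,
                                    mode="constant", cval=0, prefilter=order > 1)


def align_axes(volume: GreyVolume, tooth_mask: np.ndarray):
    """Rotate the volume so the tooth's long axis lies along z and its second
    principal axis along x. Returns the aligned volume and the applied 3x3
    rotation (in (z, y, x) coordinates, about the mask centroid-centred grid).
    """
    if tooth_mask.shape != volume.shape:
        raise ValueError("mask shape must match volume shape")
    R = principal_rotation(tooth_mask)
    rotated = _rotate_volume(volume.data.astype(np.float32), R, order=1)
    return (GreyVolume(data=np.clip(np.rint(rotated), 0, 65535).astype(np.uint16),
                       voxel_pitch_um=volume.voxel_pitch_um), R)


def rotation_angle_deg(R: np.ndarray) -> float:
    """Rotation angle of a 3x3 rotation matrix, in degrees."""
    return float(np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# slabs

def partition_slabs(tooth_mask: np.ndarray) -> np.ndarray:
    """Split the tooth's vertical extent into three equal-height, half-open
    z-intervals; remainder slices go to the lower slabs first (cervical up).

    Returns a uint8 volume: 0 outside the mask, 1/2/3 for the cervical,
    middle, and occlusal thirds.
    """
    zs = np.nonzero(tooth_mask.any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("empty tooth mask")
    z0, z1 = int(zs[0]), int(zs[-1]) + 1
    extent = z1 - z0
    if extent < 3:
        raise ValueError(f"tooth spans only {extent} slices; need at least 3")
    base, rem = divmod(extent, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = np.zeros(tooth_mask.shape, dtype=np.uint8)
    lo = z0
    for i, s in enumerate(sizes):
        out[lo:lo + s][tooth_mask[lo:lo + s]] = i + 1
        lo += s
    return out


def slab_intervals(tooth_mask: np.ndarray) -> list[tuple[int, int]]:
    """The three half-open z-intervals of :func:`partition_slabs`."""
    zs = np.nonzero(tooth_mask.any(axis=(1, 2)))[0]
    if zs.size == 0:
        raise ValueError("empty tooth mask")
    z0, z1 = int(zs[0]), int(zs[-1]) + 1
    extent = z1 - z0
    if extent < 3:
        raise ValueError(f"tooth spans only {extent} slices; need at least 3")
    base, rem = divmod(extent, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    bounds = np.cumsum([z0] + sizes)
    return [(int(bounds[i]), int(bounds[i + 1])) for i in range(3)]


# ---------------------------------------------------------------------------
# sectors

def _boundary_transitions(slice_mask: np.ndarray):
    """Locate the four convex-to-flat transition points on a cross-section
    boundary, via curvature of the smoothed largest contour.

    Returns (points (4, 2) in (row, col) order along the contour, centroid)
    or None when fewer than four robust transitions are found.
    """
    contours = measure.find_contours(slice_mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    n = len(contour)
    if n < 40:
        return None
    centroid = np.asarray(np.nonzero(slice_mask)).mean(axis=1)

    # periodic smoothing of the closed contour
    win = max(int(n * 0.05) | 1, 5)
    kernel = np.ones(win) / win
    sm = np.empty_like(contour)
    for d in range(2):
        sm[:, d] = np.convolve(np.concatenate([contour[-win:, d], contour[:, d],
                                               contour[:win, d]]),
                               kernel, mode="same")[win:win + n]
    dr = np.gradient(sm, axis=0)
    ddr = np.gradient(dr, axis=0)
    speed = np.hypot(dr[:, 0], dr[:, 1])
    curv = np.abs(dr[:, 0] * ddr[:, 1] - dr[:, 1] * ddr[:, 0]) / np.maximum(speed, 1e-9) ** 3
    # heavy periodic smoothing of the curvature signal itself
    kwin = max(int(n * 0.08) | 1, 5)
    kk = np.ones(kwin) / kwin
    curv = np.convolve(np.concatenate([curv[-kwin:], curv, curv[:kwin]]),
                       kk, mode="same")[kwin:kwin + n]

    lo, hi = np.percentile(curv, [5, 95])
    if hi - lo < 0.15 * hi:  # near-constant curvature: circle-like, no transitions
        return None
    mid = (lo + hi) / 2
    above = curv > mid
    # circular majority filter removes threshold chatter inside each zone
    mwin = max(int(n * 0.06) | 1, 5)
    mk = np.ones(mwin) / mwin
    above = np.convolve(np.concatenate([above[-mwin:], above, above[:mwin]]),
                        mk, mode="same")[mwin:mwin + n] > 0.5
    runs = np.nonzero(np.diff(above.astype(int)) != 0)[0]
    if len(runs) != 4:
        return None
    pts = sm[runs + 1]
    return pts, centroid


def _sector_from_chords(shape, pts, centroid):
    """Split a slice into 4 sectors with the two chords joining opposite
    transition points; name sectors by which cardinal extreme they contain
    (+x -> palatal, -x -> buccal, +y -> contact_right, -y -> contact_left)."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    p = [pts[i] for i in range(4)]  # ordered along the contour

    def side(a, b, r, c):
        return (b[0] - a[0]) * (c - a[1]) - (b[1] - a[1]) * (r - a[0]) > 0

    def quad_code(r, c):
        return side(p[0], p[2], r, c).astype(np.uint8) * 2 + \
            side(p[1], p[3], r, c).astype(np.uint8)

    cr, ccol = centroid
    cardinals = {3: (cr, ccol + 1e3), 1: (cr, ccol - 1e3),
                 2: (cr + 1e3, ccol), 4: (cr - 1e3, ccol)}
    code_of_quad = {}
    for name_code, (pr, pc) in cardinals.items():
        code_of_quad[int(quad_code(np.float64(pr), np.float64(pc)))] = name_code
    if len(code_of_quad) != 4:
        return None  # chords failed to separate the cardinals; caller falls back

    quad = quad_code(rr, cc)
    sector = np.zeros(shape, dtype=np.uint8)
    for q, name_code in code_of_quad.items():
        sector[quad == q] = name_code
    return sector


def _quadrant_sectors(shape, centroid) -> np.ndarray:
    """Centroid-anchored +/-45 degree quadrant fallback."""
    rr, cc = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    theta = np.degrees(np.arctan2(rr - centroid[0], cc - centroid[1]))  # (y, x)
    sector = np.zeros(shape, dtype=np.uint8)
    sector[(theta > -45) & (theta <= 45)] = 3   # +x palatal
    sector[(theta > 45) & (theta <= 135)] = 2   # +y contact_right
    sector[(theta > 135) | (theta <= -135)] = 1  # -x buccal
    sector[(theta > -135) & (theta <= -45)] = 4  # -y contact_left
    return sector


def partition_sectors(tooth_mask: np.ndarray):
    """Assign each tooth voxel one of four angular sectors.

    Sector chords are detected once per slab on its middle slice and
    propagated through the slab. Returns ``(sector volume, fallback_slabs)``.
    """
    intervals = slab_intervals(tooth_mask)
    sector = np.zeros(tooth_mask.shape, dtype=np.uint8)
    fallback: list[int] = []
    for i, (lo, hi) in enumerate(intervals):
        for z in range(lo, hi):
            if not tooth_mask[z].any():
                raise ValueError(f"empty slice z={z} inside the tooth extent")
        mid = tooth_mask[(lo + hi) // 2]
        found = _boundary_transitions(mid)
        plane = None
        if found is not None:
            pts, centroid = found
            plane = _sector_from_chords(mid.shape, pts, centroid)
        if plane is None:
            centroid = np.asarray(np.nonzero(mid)).mean(axis=1)
            plane = _quadrant_sectors(mid.shape, centroid)
            fallback.append(i + 1)
        sector[lo:hi] = np.where(tooth_mask[lo:hi], plane[None], 0)
    return sector, fallback


def slab_sector_regions(tooth_mask: np.ndarray) -> SlabSectorPartition:
    """Compose slab and sector partitions into the 12 slab-sector regions."""
    slab = partition_slabs(tooth_mask)
    sector, fallback = partition_sectors(tooth_mask)
    region = np.where(tooth_mask, (slab.astype(np.int16) - 1) * 4 + sector, 0)
    return SlabSectorPartition(slab=slab, sector=sector,
                               region=region.astype(np.uint8),
                               fallback_slabs=fallback)
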