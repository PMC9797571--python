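"""Crack-network isolation and morphometry.

Connected crack groups are extracted under 26-connectivity (cracks are thin
oblique sheets; 6-connectivity fragments them), filtered by size, and
described by eigenvalue shape descriptors: for a component's voxel-coordinate
covariance with eigenvalues lambda1 >= lambda2 >= lambda3, the planarity
(lambda2 - lambda3) / lambda1 approaches 1 for a sheet and 0 for a thread,
and the dominant plane normal is the eigenvector of lambda3.

Crack width uses the local-thickness convention: twice the Euclidean distance
transform sampled on the mask's medial surface, propagated to every mask
voxel and scaled to micrometres; widths at or below one voxel are flagged as
sub-resolution. Plane orientations come from the structure tensor of the
smoothed mask; normals are folded to a hemisphere, histogrammed, and the two
dominant modes with their mutual angle reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import morphology

from .io_volumes import COMPONENT_COLUMNS, CRACK, DENTIN, ENAMEL


@dataclass
class CrackComponent:
    """One connected group of crack voxels."""

    component_id: int
    coords: np.ndarray  # (n, 3) voxel coordinates, (z, y, x)
    voxel_count: int
    bbox: tuple  # (z0, y0, x0, z1, y1, x1), half-open
    centroid: np.ndarray
    eigenvalues: np.ndarray  # lambda1 >= lambda2 >= lambda3 >= 0
    planarity: float
    normal: np.ndarray  # unit, (z, y, x)


@dataclass
class OrientationModes:
    """Hemisphere histogram of local plane normals and its top-2 modes."""

    histogram: np.ndarray  # (n_polar, n_azimuth) voxel counts
    mode_directions: list[np.ndarray]  # up to 2 unit vectors, (z, y, x)
    inter_mode_angle_deg: float | None  # in [0, 90]; None with a single mode


# ---------------------------------------------------------------------------
# components

def _describe(comp_id: int, coords: np.ndarray) -> CrackComponent:
    n = coords.shape[0]
    centroid = coords.mean(axis=0)
    if n > 1:
        cov = np.cov((coords - centroid).T)
        w, v = np.linalg.eigh(cov)  # ascending
        eigenvalues = w[::-1].clip(min=0.0)
        normal = v[:, 0]
    else:
        eigenvalues = np.zeros(3)
        normal = np.array([1.0, 0.0, 0.0])  # undefined; +z by convention
    lam1 = eigenvalues[0]
    planarity = float((eigenvalues[1] - eigenvalues[2]) / lam1) if lam1 > 0 else 0.0
    if normal[0] < 0 or (normal[0] == 0 and (normal[1] < 0 or
                                             (normal[1] == 0 and normal[2] < 0))):
        normal = -normal  # hemisphere convention
    lo = coords.min(axis=0)
    hi = coords.max(axis=0) + 1
    return CrackComponent(
        component_id=comp_id, coords=coords, voxel_count=n,
        bbox=(int(lo[0]), int(lo[1]), int(lo[2]), int(hi[0]), int(hi[1]), int(hi[2])),
        centroid=centroid, eigenvalues=eigenvalues, planarity=planarity,
        normal=normal / np.linalg.norm(normal))


def connected_components(crack_mask: np.ndarray, connectivity: int = 26
                         ) -> list[CrackComponent]:
    """Maximal connected crack groups, ordered by decreasing size then by
    lexicographically smallest voxel; ids are 1-based in that order."""
    if connectivity not in (6, 18, 26):
        raise ValueError("connectivity must be 6, 18 or 26")
    rank = {6: 1, 18: 2, 26: 3}[connectivity]
    structure = ndimage.generate_binary_structure(3, rank)
    lab, n = ndimage.label(np.asarray(crack_mask, dtype=bool), structure=structure)
    if n == 0:
        return []
    order = np.argsort(lab[lab > 0], kind="stable")
    coords_all = np.argwhere(lab > 0)
    # group coordinates by label (argwhere is already in lexicographic order)
    flat_labels = lab[lab > 0]
    groups: list[np.ndarray] = []
    for lid in range(1, n + 1):
        groups.append(coords_all[flat_labels == lid])
    del order
    # order: decreasing size, tie-break by smallest first voxel (lexicographic)
    keys = sorted(range(n), key=lambda i: (-groups[i].shape[0],
                                           tuple(groups[i][0].tolist())))
    return [_describe(rank_i + 1, groups[i]) for rank_i, i in enumerate(keys)]


def filter_by_size(components, min_voxels: int = 27):
    """Keep components with at least ``min_voxels`` voxels (default one 3^3
    noise blob at working scale)."""
    if min_voxels < 1:
        raise ValueError("min_voxels must be >= 1")
    return [c for c in components if c.voxel_count >= min_voxels]


def largest_k(components, k: int = 3):
    """Top-k components by voxel count (stable in the incoming id order)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return sorted(components, key=lambda c: (-c.voxel_count, c.component_id))[:k]


def volume_fraction(component, tooth_mask: np.ndarray) -> float:
    """Component voxels as a fraction of the tooth volume (hard tissue +
    crack; the pulp cavity is excluded from the denominator)."""
    n_tooth = int(np.asarray(tooth_mask, dtype=bool).sum())
    if n_tooth == 0:
        raise ValueError("empty tooth mask")
    if component is None:
        return 0.0
    count = component.voxel_count if hasattr(component, "voxel_count") else int(component)
    return count / n_tooth


def tooth_mask_from_labels(labels) -> np.ndarray:
    """Tooth support: enamel + dentin + crack voxels."""
    lab = labels.data if hasattr(labels, "voxel_pitch_um") else np.asarray(labels)
    return (lab == ENAMEL) | (lab == DENTIN) | (lab == CRACK)


def component_table(components) -> pd.DataFrame:
    rows = []
    for c in components:
        rows.append({
            "component_id": c.component_id, "voxel_count": c.voxel_count,
            "bbox_z0": c.bbox[0], "bbox_y0": c.bbox[1], "bbox_x0": c.bbox[2],
            "bbox_z1": c.bbox[3], "bbox_y1": c.bbox[4], "bbox_x1": c.bbox[5],
            "centroid_z": c.centroid[0], "centroid_y": c.centroid[1],
            "centroid_x": c.centroid[2],
            "lambda1": c.eigenvalues[0], "lambda2": c.eigenvalues[1],
            "lambda3": c.eigenvalues[2], "planarity": c.planarity,
            "normal_z": c.normal[0], "normal_y": c.normal[1],
            "normal_x": c.normal[2],
        })
    return pd.DataFrame(rows, columns=COMPONENT_COLUMNS)


# ---------------------------------------------------------------------------
# width

def local_width(crack_mask: np.ndarray, voxel_pitch_um: float):
    """Local crack width in micrometres via the local-thickness convention.

    Width at a medial-surface voxel is twice its distance to the nearest
    background voxel centre minus one voxel (i.e. the distance to the
    material boundary), and is propagated to every mask voxel from its
    nearest medial voxel. Returns ``(width_um, subresolution)``: width is NaN
    outside the mask; ``subresolution`` flags mask voxels whose width is at
    or below one voxel pitch, where the estimate is resolution-limited.
    """
    mask = np.asarray(crack_mask, dtype=bool)
    width = np.full(mask.shape, np.nan, dtype=np.float32)
    sub = np.zeros(mask.shape, dtype=bool)
    if not mask.any():
        return width, sub
    edt = ndimage.distance_transform_edt(mask)
    medial = morphology.skeletonize(mask)
    medial &= mask
    if not medial.any():
        medial = mask & (edt >= edt.max())
    thickness_vox = 2.0 * edt - 1.0  # centre-to-boundary doubling
    idx = ndimage.distance_transform_edt(~medial, return_distances=False,
                                         return_indices=True)
    propagated = thickness_vox[tuple(i[mask] for i in idx)]
    width[mask] = np.maximum(propagated, 1.0) * voxel_pitch_um
    sub[mask] = propagated <= 1.0
    return width, sub


# ---------------------------------------------------------------------------
# orientation

N_POLAR_BINS = 18   # 5 degree steps in inclination (0..90)
N_AZIMUTH_BINS = 36  # 10 degree steps in azimuth -> 648 hemisphere bins


def _fold_hemisphere(vecs: np.ndarray) -> np.ndarray:
    """Flip sign-ambiguous normals into the z >= 0 hemisphere."""
    v = vecs.copy()
    flip = (v[:, 0] < 0) | ((v[:, 0] == 0) & (v[:, 1] < 0)) \
        | ((v[:, 0] == 0) & (v[:, 1] == 0) & (v[:, 2] < 0))
    v[flip] *= -1
    return v


def orientation_modes(crack_mask: np.ndarray, sigma: float = 2.0,
                      min_voxels: int = 100,
                      min_mode_separation_deg: float = 25.0) -> OrientationModes:
    """Dominant crack-plane orientations from the structure tensor.

    The binary mask is Gaussian-smoothed (``sigma`` voxels); per crack voxel
    the local plane normal is the principal eigenvector of the smoothed
    structure tensor (the direction of steepest intensity variation across
    the thin sheet). Normals are folded to a hemisphere and binned on an
    inclination x azimuth grid; the two strongest well-separated modes are
    refined by averaging member normals, and their mutual angle (folded to
    [0, 90] degrees) reported.
    """
    mask = np.asarray(crack_mask, dtype=bool)
    n_vox = int(mask.sum())
    if n_vox < min_voxels:
        raise ValueError(f"need at least {min_voxels} crack voxels, got {n_vox}")

    smooth = ndimage.gaussian_filter(mask.astype(np.float32), sigma)
    grads = np.gradient(smooth)
    J = np.empty((3, 3) + mask.shape, dtype=np.float32)
    for a in range(3):
        for b in range(a, 3):
            J[a, b] = ndimage.gaussian_filter(grads[a] * grads[b], sigma)
            J[b, a] = J[a, b]
    Jv = np.moveaxis(J[:, :, mask], -1, 0)  # (n, 3, 3)
    w, v = np.linalg.eigh(Jv)
    normals = _fold_hemisphere(v[:, :, 2])  # principal eigenvector per voxel

    # hemisphere histogram: inclination from +z, azimuth in the (y, x) plane
    incl = np.degrees(np.arccos(np.clip(normals[:, 0], -1, 1)))
    azim = np.degrees(np.arctan2(normals[:, 1], normals[:, 2])) % 360.0
    hist, _, _ = np.histogram2d(
        incl, azim, bins=[N_POLAR_BINS, N_AZIMUTH_BINS],
        range=[[0, 90.0000001], [0, 360]])

    def bin_direction(bi, bj):
        th = np.deg2rad((bi + 0.5) * 90.0 / N_POLAR_BINS)
        ph = np.deg2rad((bj + 0.5) * 360.0 / N_AZIMUTH_BINS)
        return np.array([np.cos(th), np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph)])

    def refine(direction):
        cosang = np.abs(normals @ direction)
        member = cosang >= np.cos(np.deg2rad(15.0))
        if not member.any():
            return direction
        aligned = normals[member] * np.sign(normals[member] @ direction)[:, None]
        m = aligned.mean(axis=0)
        return m / np.linalg.norm(m)

    order = np.argsort(hist, axis=None)[::-1]
    modes: list[np.ndarray] = []
    for flat in order:
        bi, bj = np.unravel_index(flat, hist.shape)
        if hist[bi, bj] == 0:
            break
        d = refine(bin_direction(bi, bj))
        if modes:
            ang = np.degrees(np.arccos(np.clip(abs(modes[0] @ d), 0, 1)))
            if ang < min_mode_separation_deg:
                continue
        modes.append(d)
        if len(modes) == 2:
            break

    angle = None
    if len(modes) == 2:
        angle = float(np.degrees(np.arccos(np.clip(abs(modes[0] @ modes[1]), 0, 1))))
    return OrientationModes(histogram=hist, mode_directions=modes,
                            inter_mode_angle_deg=angle)


# ---------------------------------------------------------------------------
# distance projections

def distance_to_crack_projection(crack_mask: np.ndarray, axis) -> np.ndarray:
    """Per line of sight along ``axis``, the distance (in voxels) from the
    viewer-side face (index 0) to the first crack voxel; NaN where the line
    meets no crack."""
    from .segmentation import _AXIS_INDEX

    ax = _AXIS_INDEX.get(axis)
    if ax is None:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    mask = np.asarray(crack_mask, dtype=bool)
    hit = mask.any(axis=ax)
    first = mask.argmax(axis=ax).astype(np.float64)
    first[~hit] = np.nan
    return first
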