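import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from crackct.geometry import (align_axes, partition_sectors, partition_slabs,
                              principal_rotation, resample, rotation_angle_deg,
                              slab_intervals, slab_sector_regions)
from crackct.io_volumes import GreyVolume


# ---------------------------------------------------------------------------
# resample

def test_resample_constant_halves_extent():
    vol = GreyVolume(np.full((8, 8, 8), 1000, np.uint16), 5.0)
    out = resample(vol, 10.0)
    assert out.shape == (4, 4, 4)
    assert out.voxel_pitch_um == 10.0
    assert (out.data == 1000).all()


def test_resample_block_mean_oracle():
    """2x2x2 block of {0..7} averages to 3.5, rounded half-to-even to 4."""
    vol = GreyVolume(np.arange(8, dtype=np.uint16).reshape(2, 2, 2), 5.0)
    out = resample(vol, 10.0)
    assert out.shape == (1, 1, 1)
    assert out.data[0, 0, 0] == 4


def test_resample_identity_and_errors():
    vol = GreyVolume(np.arange(27, dtype=np.uint16).reshape(3, 3, 3), 5.0)
    np.testing.assert_array_equal(resample(vol, 5.0).data, vol.data)
    with pytest.raises(ValueError, match="integer"):
        resample(vol, 7.5)
    with pytest.raises(ValueError, match=">= source"):
        resample(vol, 2.0)


def test_resample_conserves_mean(rng):
    data = rng.integers(0, 60000, size=(12, 12, 12), dtype=np.uint16)
    out = resample(GreyVolume(data, 5.0), 15.0)
    assert out.data.mean() == pytest.approx(data.mean(), abs=0.5)


# ---------------------------------------------------------------------------
# alignment

def _ellipsoid_mask(shape=(96, 96, 96), semi=(36.0, 14.0, 22.0)):
    z, y, x = np.ogrid[:shape[0], :shape[1], :shape[2]]
    c = [(s - 1) / 2 for s in shape]
    return (((z - c[0]) / semi[0]) ** 2 + ((y - c[1]) / semi[1]) ** 2
            + ((x - c[2]) / semi[2]) ** 2) <= 1.0


def test_aligned_mask_gives_near_identity_rotation():
    mask = _ellipsoid_mask()
    vol = GreyVolume((mask * 30000).astype(np.uint16), 10.0)
    _, R = align_axes(vol, mask)
    assert rotation_angle_deg(R) < 1.0


def test_recovers_known_rotation_about_z():
    mask = _ellipsoid_mask()
    rotated = ndimage.rotate(mask.astype(float), 30.0, axes=(1, 2),
                             reshape=False, order=1) > 0.5
    vol = GreyVolume((rotated * 30000).astype(np.uint16), 10.0)
    _, R = align_axes(vol, rotated)
    assert rotation_angle_deg(R) == pytest.approx(30.0, abs=2.0)
    # the recovered rotation undoes the applied one (sign convention free):
    a = np.deg2rad(30.0)
    applied = np.array([[1, 0, 0],
                        [0, np.cos(a), -np.sin(a)],
                        [0, np.sin(a), np.cos(a)]])  # about z in (z, y, x)
    residual = min(rotation_angle_deg(R @ applied),
                   rotation_angle_deg(R @ applied.T))
    assert residual < 2.0


def test_alignment_idempotent():
    mask = _ellipsoid_mask()
    rotated = ndimage.rotate(mask.astype(float), 20.0, axes=(1, 2),
                             reshape=False, order=1) > 0.5
    vol = GreyVolume((rotated * 30000).astype(np.uint16), 10.0)
    aligned, _ = align_axes(vol, rotated)
    mask2 = aligned.data > 15000
    _, R2 = align_axes(aligned, mask2)
    assert rotation_angle_deg(R2) < 1.0


def test_degenerate_mask_rejected():
    mask = np.zeros((16, 16, 16), bool)
    mask[2:14, 8, 8] = True  # collinear voxels
    with pytest.raises(ValueError):
        principal_rotation(mask)
    with pytest.raises(ValueError, match="too small"):
        principal_rotation(np.zeros((8, 8, 8), bool))


# ---------------------------------------------------------------------------
# slabs

def _box_mask(z0, z1, shape=(110, 20, 20)):
    m = np.zeros(shape, bool)
    m[z0:z1, 5:15, 5:15] = True
    return m


def test_slab_intervals_equal_thirds():
    m = _box_mask(0, 99)
    assert slab_intervals(m) == [(0, 33), (33, 66), (66, 99)]


def test_slab_remainder_assigned_bottom_up():
    m = _box_mask(4, 14)  # extent 10 -> sizes (4, 3, 3)
    assert slab_intervals(m) == [(4, 8), (8, 11), (11, 14)]


@settings(max_examples=40, derandomize=True, deadline=None)
@given(extent=st.integers(3, 100))
def test_slabs_tile_the_extent(extent):
    m = _box_mask(2, 2 + extent, shape=(extent + 4, 20, 20))
    slab = partition_slabs(m)
    assert set(np.unique(slab[m])) == {1, 2, 3}
    assert (slab[~m] == 0).all()
    iv = slab_intervals(m)
    sizes = [b - a for a, b in iv]
    assert sum(sizes) == extent and max(sizes) - min(sizes) <= 1


def test_too_thin_tooth_rejected():
    with pytest.raises(ValueError, match="at least 3"):
        partition_slabs(_box_mask(5, 7))
    with pytest.raises(ValueError, match="empty"):
        partition_slabs(np.zeros((10, 10, 10), bool))


# ---------------------------------------------------------------------------
# sectors

def _elliptic_cylinder(shape=(30, 96, 96), semi=(28.0, 42.0)):
    """Elliptical cross-section, x semi-axis > y semi-axis."""
    m = np.zeros(shape, bool)
    yy, xx = np.ogrid[:shape[1], :shape[2]]
    cy, cx = (shape[1] - 1) / 2, (shape[2] - 1) / 2
    ell = ((yy - cy) / semi[0]) ** 2 + ((xx - cx) / semi[1]) ** 2 <= 1.0
    m[:] = ell
    return m


def test_elliptical_sectors_contain_cardinal_extremes():
    """Oracle: the four extreme boundary points (+/-x, +/-y) must land in
    their own sectors (palatal, buccal, contact right/left)."""
    m = _elliptic_cylinder()
    sector, fallback = partition_sectors(m)
    z = 15
    cy, cx = 47.5, 47.5
    ys, xs = np.nonzero(m[z])
    px = (ys[np.argmax(xs)], xs.max())   # +x extreme
    mx = (ys[np.argmin(xs)], xs.min())   # -x extreme
    py = (ys.max(), xs[np.argmax(ys)])   # +y extreme
    my = (ys.min(), xs[np.argmin(ys)])   # -y extreme
    codes = {sector[z][px], sector[z][mx], sector[z][py], sector[z][my]}
    assert codes == {1, 2, 3, 4}
    assert sector[z][px] == 3  # +x -> palatal
    assert sector[z][mx] == 1  # -x -> buccal


def test_circular_section_falls_back_to_quadrants():
    m = _elliptic_cylinder(semi=(35.0, 35.0))
    sector, fallback = partition_sectors(m)
    assert fallback  # circle has no curvature transitions
    counts = np.bincount(sector[m], minlength=5)[1:]
    assert counts.sum() == m.sum()
    assert counts.max() <= counts.mean() * 1.05


def test_sector_assignment_is_a_partition(default_phantom):
    _, _, truth = default_phantom
    from crackct.morphometry import tooth_mask_from_labels
    tooth = tooth_mask_from_labels(truth.labels)
    sector, _ = partition_sectors(tooth)
    assert (sector[tooth] > 0).all() and (sector[tooth] <= 4).all()
    assert (sector[~tooth] == 0).all()


# ---------------------------------------------------------------------------
# slab x sector regions

def test_twelve_nonempty_regions(default_phantom):
    _, _, truth = default_phantom
    from crackct.morphometry import tooth_mask_from_labels
    tooth = tooth_mask_from_labels(truth.labels)
    part = slab_sector_regions(tooth)
    counts = part.region_counts()
    assert sorted(counts) == list(range(1, 13))
    assert all(v > 0 for v in counts.values())
    assert sum(counts.values()) == int(tooth.sum())
    # region id is consistent with the slab and sector maps voxelwise
    recomputed = (part.slab[tooth].astype(int) - 1) * 4 + part.sector[tooth]
    np.testing.assert_array_equal(part.region[tooth], recomputed)
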