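import numpy as np
import pytest
from scipy import ndimage

from crackct.io_volumes import AIR, CRACK, DENTIN, ENAMEL
from crackct.phantom import (CrackNetworkSpec, PhantomSpec, _slab_occupancy,
                             generate_phantom, generate_training_tiles,
                             nocrack_spec)


def _spec(**kw):
    net_kw = {k: kw.pop(k) for k in list(kw)
              if k in CrackNetworkSpec.__dataclass_fields__}
    return PhantomSpec(crack_network=CrackNetworkSpec(**net_kw), **kw)


def test_no_cracks_when_network_disabled():
    spec = _spec(rng_seed=1, n_primary_planes=0, n_isolated_cracks=0,
                 target_volume_fraction=None)
    _, truth = generate_phantom(spec)
    assert (truth.labels.data == CRACK).sum() == 0
    assert truth.connected_network_voxel_fraction == 0.0


def test_explicit_perpendicular_normals_passthrough():
    normals = [[0.0, 0.0, 1.0], [0.0, 1.0, 0.0]]
    spec = _spec(rng_seed=1, plane_normals=normals, n_isolated_cracks=0,
                 target_volume_fraction=0.02)
    _, truth = generate_phantom(spec)
    n1, n2 = truth.crack_plane_normals
    angle = np.degrees(np.arccos(abs(np.dot(n1, n2))))
    assert angle == pytest.approx(90.0, abs=1e-9)


def test_network_fraction_hits_target(default_phantom):
    """Oracle: direct voxel count of the truth network against hard tissue."""
    spec, _, truth = default_phantom
    target = spec.crack_network.target_volume_fraction
    lab = truth.labels.data
    n_tooth = int(np.isin(lab, [ENAMEL, DENTIN, CRACK]).sum())
    counted = truth.network_mask.sum() / n_tooth
    assert counted == pytest.approx(truth.connected_network_voxel_fraction, rel=1e-9)
    assert abs(counted / target - 1.0) <= 0.10


def test_generation_bit_reproducible():
    spec = PhantomSpec(rng_seed=5, grid_shape=(64, 96, 96),
                       crown_height_mm=1.0, crown_radii_mm=(0.8, 0.65),
                       enamel_thickness_mm=(0.3, 0.4))
    g1, t1 = generate_phantom(spec)
    g2, t2 = generate_phantom(spec)
    np.testing.assert_array_equal(g1.data, g2.data)
    np.testing.assert_array_equal(t1.labels.data, t2.labels.data)


def test_shells_nested(default_phantom):
    """Nested supports: pulp enclosed in dentin, dentin laterally wrapped by
    enamel on every slice above the (cut) crown base."""
    _, _, truth = default_phantom
    lab = truth.labels_nocrack.data
    tissue = (lab == ENAMEL) | (lab == DENTIN)
    enclosed_air = ndimage.binary_fill_holes(tissue) & ~tissue  # the pulp
    assert enclosed_air.sum() > 0
    pulp_dilated = ndimage.binary_dilation(enclosed_air,
                                           ndimage.generate_binary_structure(3, 1))
    assert np.isin(lab[pulp_dilated], [AIR, DENTIN]).all()  # pulp only meets dentin
    dentin_z = np.nonzero((lab == DENTIN).any(axis=(1, 2)))[0]
    for z in dentin_z[1:]:  # base slice exposes dentin toward the root: skip it
        sl = lab[z]
        dd = ndimage.binary_dilation(sl == DENTIN)
        outside = (sl == AIR) & ~(enclosed_air[z])
        assert not (dd & outside).any(), f"dentin meets outside air at z={z}"


def test_more_planes_never_fewer_crack_voxels():
    base = [[0.0, 0.0, 1.0]]
    more = base + [[0.0, 1.0, 0.0], [0.0, 0.7071, 0.7071]]
    counts = []
    for normals in (base, more):
        spec = _spec(rng_seed=9, plane_normals=normals, n_isolated_cracks=0,
                     target_volume_fraction=None)
        _, truth = generate_phantom(spec)
        counts.append(int((truth.labels.data == CRACK).sum()))
    assert counts[1] >= counts[0] > 0


def test_unreachable_target_fraction_raises():
    spec = _spec(rng_seed=2, n_primary_planes=1, n_isolated_cracks=0,
                 target_volume_fraction=0.6)
    with pytest.raises(RuntimeError, match="target volume fraction"):
        generate_phantom(spec)


def test_render_two_plateaus_without_noise():
    spec = _spec(rng_seed=3, noise_sd=0.0, n_primary_planes=0,
                 n_isolated_cracks=0, target_volume_fraction=None)
    grey, truth = generate_phantom(spec)
    values = np.unique(grey.data)
    assert values[0] == 0  # background/pulp
    assert len(values) == 3  # air, dentin, enamel plateaus
    lab = truth.labels.data
    enamel_grey = grey.data[lab == ENAMEL]
    dentin_grey = grey.data[lab == DENTIN]
    assert enamel_grey.min() == enamel_grey.max()
    assert dentin_grey.min() == dentin_grey.max()
    assert enamel_grey[0] > dentin_grey[0] > 0


def test_halfwidth_crack_gives_half_grey():
    """Partial volume: a crack of width pitch/2 dims its voxel to half the
    host grey (oracle: analytic occupancy fraction)."""
    assert _slab_occupancy(np.array(0.0), 0.5) == 0.5
    # odd in-plane grid puts voxel centres exactly on the crack mid-plane
    spec = _spec(rng_seed=4, grid_shape=(128, 129, 129), noise_sd=0.0,
                 plane_normals=[[0.0, 0.0, 1.0]],
                 n_isolated_cracks=0, target_volume_fraction=None)
    spec.crack_network.primary_width_vox = 0.5
    grey, truth = generate_phantom(spec)
    nc_grey, _ = generate_phantom(nocrack_spec(spec))
    crack = truth.labels.data == CRACK
    assert crack.sum() > 0
    ratio = grey.data[crack].astype(float) / nc_grey.data[crack].astype(float)
    np.testing.assert_allclose(ratio, 0.5, atol=0.01)


def test_cylinder_void_artifact():
    spec = _spec(rng_seed=6, noise_sd=0.0, n_primary_planes=0,
                 n_isolated_cracks=0, target_volume_fraction=None)
    grey_plain, _ = generate_phantom(spec)
    spec_void = PhantomSpec(**{**spec.__dict__, "cylinder_void": True})
    grey_void, _ = generate_phantom(spec_void)
    zeroed = (grey_plain.data > 0) & (grey_void.data == 0)
    assert zeroed.sum() > 0
    # the void is a vertical cylinder of radius 6: all zeroed voxels share one
    # in-plane disk regardless of z
    ys, xs = np.nonzero(zeroed.any(axis=0))
    cy, cx = ys.mean(), xs.mean()
    assert np.hypot(ys - cy, xs - cx).max() <= 6.5


def test_training_tiles_contract(default_phantom):
    _, grey, truth = default_phantom
    tiles_a = generate_training_tiles(grey, truth, 10, 64, seed=77)
    tiles_b = generate_training_tiles(grey, truth, 10, 64, seed=77)
    assert len(tiles_a) == 10
    for (ga, la), (gb, lb) in zip(tiles_a, tiles_b):
        assert ga.shape == la.shape == (64, 64)
        np.testing.assert_array_equal(ga, gb)
        np.testing.assert_array_equal(la, lb)

    census = np.zeros(4, dtype=int)
    for _, lab in generate_training_tiles(grey, truth, 120, 64, seed=5):
        census += np.bincount(lab.ravel(), minlength=4)
    assert (census > 0).all(), f"missing classes in tile census: {census}"

    with pytest.raises(ValueError):
        generate_training_tiles(grey, truth, 0, 64, seed=1)
    with pytest.raises(ValueError):
        generate_training_tiles(grey, truth, 1, 4096, seed=1)


def test_spec_validation():
    with pytest.raises(ValueError, match="enamel thickness"):
        PhantomSpec(enamel_thickness_mm=(0.1, 0.5))
    with pytest.raises(ValueError, match="fit the grid"):
        PhantomSpec(grid_shape=(32, 32, 32))
    with pytest.raises(ValueError):
        CrackNetworkSpec(target_volume_fraction=1.5)
    with pytest.raises(ValueError):
        CrackNetworkSpec(widths_um=(0.0, 30.0))
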