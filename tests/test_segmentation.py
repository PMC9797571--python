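import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crackct.io_volumes import AIR, CRACK, DENTIN, ENAMEL, GreyVolume
from crackct.segmentation import (CNNBackend, RuleBasedBackend, TrainConfig,
                                  make_tile_grid, pixel_accuracy,
                                  rule_based_oracle, segment_axis,
                                  segment_slice, to_three_channel,
                                  train_classifier)


# ---------------------------------------------------------------------------
# tiling

def test_tile_grid_oracle_1000px():
    """ceil((1000-512)/244)+1 = 3 origins per dim -> 9 tiles, last at 488."""
    grid = make_tile_grid((1000, 1000), tile_size=512, stride=244)
    per_dim = int(np.ceil((1000 - 512) / 244)) + 1
    assert len(grid.origins) == per_dim**2 == 9
    assert max(r for r, _ in grid.origins) == 488


def test_tile_grid_exact_fit():
    grid = make_tile_grid((512, 512), tile_size=512)
    assert grid.origins == [(0, 0)]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(h=st.integers(40, 300), w=st.integers(40, 300),
       tile=st.integers(16, 40), stride_frac=st.floats(0.1, 1.0))
def test_tile_grid_covers_every_pixel(h, w, tile, stride_frac):
    stride = max(1, int(tile * stride_frac))
    grid = make_tile_grid((h, w), tile_size=tile, stride=stride)
    cover = np.zeros((h, w), bool)
    for r, c in grid.origins:
        assert r + tile <= h and c + tile <= w
        cover[r:r + tile, c:c + tile] = True
    assert cover.all()


def test_tile_grid_rejects_oversized_tile():
    with pytest.raises(ValueError):
        make_tile_grid((100, 100), tile_size=128)


def test_to_three_channel():
    tile = np.arange(12, dtype=np.uint16).reshape(3, 4)
    out = to_three_channel(tile)
    assert out.shape == (3, 4, 3)
    for c in range(3):
        np.testing.assert_array_equal(out[:, :, c], tile)
    np.testing.assert_array_equal(to_three_channel(np.zeros((2, 2))), 0)


# ---------------------------------------------------------------------------
# pixel accuracy

def test_pixel_accuracy_values(rng):
    a = rng.integers(0, 4, size=(10, 10)).astype(np.uint8)
    assert pixel_accuracy(a, a) == 1.0
    b = a.copy().ravel()
    b[37] = (b[37] + 1) % 4
    assert pixel_accuracy(a, b.reshape(10, 10)) == pytest.approx(0.99)
    with pytest.raises(ValueError):
        pixel_accuracy(a, a[:5])


def test_pixel_accuracy_confusion_trace_oracle(rng):
    for _ in range(5):
        p = rng.integers(0, 4, size=(8, 9, 10))
        t = rng.integers(0, 4, size=(8, 9, 10))
        conf = np.zeros((4, 4), int)
        np.add.at(conf, (p.ravel(), t.ravel()), 1)
        assert pixel_accuracy(p, t) == pytest.approx(np.trace(conf) / p.size)


# ---------------------------------------------------------------------------
# rule-based oracle

def test_oracle_noisefree_slice_accuracy(noisefree_phantom):
    _, grey, truth = noisefree_phantom
    backend = rule_based_oracle(grey)
    z = grey.shape[0] // 2
    pred = backend.label_tile(grey.data[z])
    assert (pred == truth.labels.data[z]).mean() >= 0.98


def test_oracle_degenerate_slices():
    backend = RuleBasedBackend((1000.0, 30000.0))
    assert (backend.label_tile(np.zeros((32, 32), np.uint16)) == AIR).all()
    # solid enamel disk: no enclosed holes, hence no crack pixels
    yy, xx = np.ogrid[:64, :64]
    disk = ((yy - 31.5) ** 2 + (xx - 31.5) ** 2 <= 20**2)
    tile = (disk * 40000).astype(np.uint16)
    lab = backend.label_tile(tile)
    assert (lab == CRACK).sum() == 0
    assert (lab[disk] == ENAMEL).all()


def test_oracle_threshold_order_enforced():
    with pytest.raises(ValueError, match="ordered"):
        RuleBasedBackend((30000.0, 1000.0))


def test_oracle_probabilities_are_simplex(noisefree_phantom):
    _, grey, _ = noisefree_phantom
    backend = rule_based_oracle(grey)
    probs = backend.predict(grey.data[40])
    assert probs.shape == grey.data[40].shape + (4,)
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)


# ---------------------------------------------------------------------------
# slice/axis assembly

class ConstantBackend:
    """Predicts one class everywhere (pure per-pixel function)."""

    def __init__(self, code):
        self.code = code

    def predict(self, tile):
        probs = np.zeros(tile.shape + (4,), np.float32)
        probs[..., self.code] = 1.0
        return probs


class ThresholdBackend:
    """Pure per-pixel threshold classifier (for tiling-losslessness checks)."""

    def predict(self, tile):
        lab = np.where(tile > 20000, ENAMEL, AIR).astype(np.uint8)
        return np.eye(4, dtype=np.float32)[lab]


def test_constant_backend_gives_constant_volume():
    vol = GreyVolume(np.zeros((6, 20, 20), np.uint16), 10.0)
    out = segment_axis(vol, ConstantBackend(DENTIN), "y")
    assert (out.data == DENTIN).all()
    assert out.shape == vol.shape


@pytest.mark.parametrize("stride", [7, 10, 16])
def test_tiling_lossless_for_per_pixel_backend(stride, rng):
    slice2d = rng.integers(0, 65535, size=(40, 40)).astype(np.uint16)
    backend = ThresholdBackend()
    whole = segment_slice(slice2d, backend)
    tiled = segment_slice(slice2d, backend, tile_size=16, stride=stride)
    np.testing.assert_array_equal(whole, tiled)


def test_single_tile_equals_full_slice(rng):
    slice2d = rng.integers(0, 65535, size=(32, 32)).astype(np.uint16)
    backend = ThresholdBackend()
    np.testing.assert_array_equal(
        segment_slice(slice2d, backend, tile_size=32),
        segment_slice(slice2d, backend))


def test_segment_axis_counts_match_truth(noisefree_phantom):
    """Rule oracle on a noise-free phantom: per-class voxel counts within 2%
    of the truth census (oracle = truth label census)."""
    _, grey, truth = noisefree_phantom
    backend = rule_based_oracle(grey)
    out = segment_axis(grey, backend, "z")
    assert set(np.unique(out.data)) <= {AIR, ENAMEL, DENTIN, CRACK}
    truth_counts = np.bincount(truth.labels.data.ravel(), minlength=4)
    pred_counts = np.bincount(out.data.ravel(), minlength=4)
    for code in (AIR, ENAMEL, DENTIN):
        assert abs(pred_counts[code] / truth_counts[code] - 1.0) <= 0.02


def test_segment_axis_validates_axis(noisefree_phantom):
    _, grey, _ = noisefree_phantom
    with pytest.raises(ValueError, match="axis"):
        segment_axis(grey, ConstantBackend(AIR), "w")


# ---------------------------------------------------------------------------
# CNN training (small smoke configs; the full-scale accuracy check lives in
# the acceptance suite)

def _tiny_tiles(rng, n=8, size=16, constant=None):
    tiles, labels = [], []
    for _ in range(n):
        g = rng.integers(0, 65535, size=(size, size)).astype(np.uint16)
        if constant is None:
            l = (g > 32768).astype(np.uint8) * ENAMEL
        else:
            l = np.full((size, size), constant, np.uint8)
        tiles.append(g)
        labels.append(l)
    return tiles, labels


def test_constant_label_dataset_degenerate_fit(rng):
    tiles, labels = _tiny_tiles(rng, constant=DENTIN)
    cfg = TrainConfig(epochs=8, learning_rate=1e-2, seed=0, channels=4)
    backend = train_classifier(tiles, labels, cfg)
    pred = backend.predict(tiles[0]).argmax(-1)
    assert (pred == DENTIN).all()


def test_training_deterministic_and_loss_decreases(rng):
    tiles, labels = _tiny_tiles(rng)
    cfg = TrainConfig(epochs=4, learning_rate=1e-3, seed=7, channels=4)
    b1 = train_classifier(tiles, labels, cfg)
    b2 = train_classifier(tiles, labels, cfg)
    assert b1.history == b2.history
    assert b1.history[-1] < b1.history[0]
    acc1 = pixel_accuracy(b1.predict(tiles[0]).argmax(-1), labels[0])
    acc2 = pixel_accuracy(b2.predict(tiles[0]).argmax(-1), labels[0])
    assert round(acc1, 3) == round(acc2, 3)


def test_training_rejects_bad_labels(rng):
    tiles, labels = _tiny_tiles(rng, n=2)
    labels[0][0, 0] = 7
    with pytest.raises(ValueError, match="outside"):
        train_classifier(tiles, labels, TrainConfig(epochs=1, channels=4,
                                                    learning_rate=1e-3))


def test_cnn_probabilities_simplex_and_roundtrip(tmp_path, rng):
    tiles, labels = _tiny_tiles(rng, n=4)
    cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=1, channels=4)
    backend = train_classifier(tiles, labels, cfg)
    probs = backend.predict(tiles[0])
    np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
    path = backend.save(tmp_path / "model.npz")
    loaded = CNNBackend.load(path)
    np.testing.assert_allclose(loaded.predict(tiles[0]), probs, atol=1e-7)
    assert loaded.config.epochs == 2


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.0)
    with pytest.raises(ValueError):
        TrainConfig(optimizer="sgd")
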