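"""Tile-based 4-class slice segmentation with pluggable backends.

Each slice perpendicular to a chosen axis is covered by overlapping tiles,
each tile is classified per pixel into {air, enamel, dentin, crack} by a
backend, and the per-tile class-probability maps are assembled back to the
slice (overlaps resolved by averaging probabilities, then argmax).

Two backends are provided:

* :class:`CNNBackend` — a small fully-convolutional encoder-decoder trained
  from labelled tiles (Adam, categorical cross-entropy, random
  contrast/flip/rotation augmentation).
* :class:`RuleBasedBackend` — a deterministic greylevel-threshold classifier
  with a morphological enclosed-dark-region rule for cracks, used as an
  independent oracle.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

from ._nn import SegNet, cross_entropy
from .io_volumes import AIR, CRACK, DENTIN, ENAMEL, N_CLASSES, GreyVolume, LabelVolume

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2, 0: 0, 1: 1, 2: 2}


# ---------------------------------------------------------------------------
# tiling

@dataclass
class TileGrid:
    """Overlapping tile cover of one slice: origins of tile upper-left corners."""

    slice_shape: tuple[int, int]
    tile_size: int
    stride: int
    origins: list[tuple[int, int]]


def _starts(dim: int, tile: int, stride: int) -> list[int]:
    s = list(range(0, dim - tile + 1, stride))
    if s[-1] != dim - tile:
        s.append(dim - tile)  # final tile flush with the edge
    return s


def make_tile_grid(slice_shape, tile_size: int = 512, stride: int | None = None) -> TileGrid:
    """Minimal covering grid of ``tile_size`` tiles with the given stride.

    The last tile per dimension is clamped so it ends at the slice edge.
    """
    h, w = slice_shape
    if tile_size > h or tile_size > w:
        raise ValueError(f"tile_size {tile_size} exceeds slice shape {slice_shape}")
    if stride is None:
        stride = max(tile_size // 2, 1)
    if stride > tile_size:
        raise ValueError("stride must not exceed tile_size")
    origins = [(r, c) for r in _starts(h, tile_size, stride)
               for c in _starts(w, tile_size, stride)]
    return TileGrid(slice_shape=(h, w), tile_size=tile_size, stride=stride,
                    origins=origins)


def to_three_channel(tile: np.ndarray) -> np.ndarray:
    """Replicate a 2D greyscale tile into three identical channels (h, w, 3)."""
    if tile.ndim != 2:
        raise ValueError("expected a 2D tile")
    return np.repeat(tile[:, :, None], 3, axis=2)


# ---------------------------------------------------------------------------
# backends

@dataclass
class TrainConfig:
    """Training configuration for the reference CNN."""

    epochs: int = 50
    optimizer: str = "adam"
    learning_rate: float = 1e-5
    batch_size: int = 5
    augmentations: tuple[str, ...] = ("contrast", "flip", "rotation")
    loss: str = "categorical_cross_entropy"
    seed: int = 0
    channels: int = 12          # width of the reference net
    contrast_range: float = 0.2  # random contrast scale in [1-r, 1+r]
    lr_schedule: str = "constant"  # or "cosine" (anneal to 0 over the run)

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be positive")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")


class CNNBackend:
    """Trained CNN classifier backend (probability maps per tile)."""

    name = "cnn"

    def __init__(self, net: SegNet, config: TrainConfig | None = None,
                 history: list[float] | None = None):
        self.net = net
        self.config = config
        self.history = history or []

    def predict(self, tile: np.ndarray) -> np.ndarray:
        """Grey tile (h, w) -> per-pixel probabilities (h, w, 4)."""
        return self.predict_batch(tile[None])[0]

    def predict_batch(self, tiles: np.ndarray) -> np.ndarray:
        x = tiles.astype(np.float32) / 65535.0
        x3 = np.repeat(x[:, None, :, :], 3, axis=1)
        return self.net.predict_probs(x3)

    def save(self, path):
        """Single portable weights file plus a JSON config sidecar."""
        path = Path(path)
        self.net.save(path)
        meta = {"name": self.name, "history": self.history}
        if self.config is not None:
            cfg = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.config.__dict__.items()}
            meta["train_config"] = cfg
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        return path

    @classmethod
    def load(cls, path):
        path = Path(path)
        net = SegNet.load(path)
        backend = cls(net)
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            backend.history = meta.get("history", [])
            if "train_config" in meta:
                cfg = dict(meta["train_config"])
                cfg["augmentations"] = tuple(cfg.get("augmentations", ()))
                backend.config = TrainConfig(**cfg)
        return backend


def _augment(grey, lab, rng, config: TrainConfig):
    if "rotation" in config.augmentations:
        k = int(rng.integers(4))
        grey, lab = np.rot90(grey, k), np.rot90(lab, k)
    if "flip" in config.augmentations:
        if rng.random() < 0.5:
            grey, lab = grey[::-1], lab[::-1]
        if rng.random() < 0.5:
            grey, lab = grey[:, ::-1], lab[:, ::-1]
    grey = grey.astype(np.float32)
    if "contrast" in config.augmentations:
        scale = 1.0 + config.contrast_range * (2 * rng.random() - 1)
        m = grey.mean()
        grey = np.clip(m + (grey - m) * scale, 0, 65535)
    return np.ascontiguousarray(grey), np.ascontiguousarray(lab)


def train_classifier(tiles, label_tiles, config: TrainConfig | None = None,
                     verbose: bool = False) -> CNNBackend:
    """Train the reference CNN on aligned (grey, label) tile pairs.

    Tiles are greyscale 2D arrays; label tiles carry codes {0..3}. Training
    is deterministic for a fixed ``config.seed``.
    """
    config = config or TrainConfig()
    if len(tiles) == 0 or len(tiles) != len(label_tiles):
        raise ValueError("need equal, nonzero numbers of grey and label tiles")
    for lt in label_tiles:
        u = np.unique(lt)
        if u.min() < 0 or u.max() >= N_CLASSES:
            raise ValueError(f"label tile contains codes outside 0..3: {u}")

    rng = np.random.default_rng(config.seed)
    net = SegNet(channels=config.channels, seed=int(rng.integers(2**31)))
    n = len(tiles)
    history: list[float] = []
    eye = np.eye(N_CLASSES, dtype=np.float32)
    for epoch in range(config.epochs):
        lr = config.learning_rate
        if config.lr_schedule == "cosine":
            lr *= 0.5 * (1 + np.cos(np.pi * epoch / config.epochs))
        order = rng.permutation(n)
        losses = []
        for b0 in range(0, n, config.batch_size):
            idx = order[b0:b0 + config.batch_size]
            gs, ls = [], []
            for i in idx:
                g, l = _augment(np.asarray(tiles[i]), np.asarray(label_tiles[i]),
                                rng, config)
                gs.append(g)
                ls.append(l)
            x = np.stack(gs)[:, None, :, :] / 65535.0
            x = np.repeat(x, 3, axis=1)
            onehot = np.moveaxis(eye[np.stack(ls)], -1, 1)
            probs, cache = net.forward(x)
            loss, dlogits = cross_entropy(probs, onehot)
            grads = net.backward(dlogits, cache)
            net.adam_step(grads, lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if verbose:
            print(f"epoch {epoch + 1}/{config.epochs}  loss {history[-1]:.4f}",
                  flush=True)
    return CNNBackend(net, config=config, history=history)


class RuleBasedBackend:
    """Deterministic greylevel classifier used as an independent oracle.

    Two ordered thresholds split pixels into air (< t1), dentin ([t1, t2)),
    and enamel (>= t2). Cracks are recovered by local contrast: tooth tissue
    is morphologically closed (sealing thin dark channels that break the
    outer surface) and its holes filled; within the filled region, the
    greylevel closing of the image estimates the *host* tissue grey across
    any thin dark structure, and a pixel darker than ``crack_contrast``
    (default one half) of its host is a crack candidate — a crack occupying
    at least half a voxel dims it below half the host grey, so this matches
    the partial-volume rendering of sub-voxel cracks in both enamel and
    dentin. Wide dark regions (the pulp cavity, scan-artifact voids) are
    excluded pixelwise: candidates within ``max_inscribed_radius_px`` of a
    dark core whose 2D inscribed radius exceeds that limit are classed air,
    so thin crack arms stay crack even where they join the pulp.
    """

    name = "rule_based"

    def __init__(self, thresholds: tuple[float, float],
                 max_inscribed_radius_px: float = 5.0,
                 closing_radius_px: int = 3,
                 crack_contrast: float = 0.5):
        t1, t2 = thresholds
        if not t1 < t2:
            raise ValueError(f"thresholds must be ordered, got {thresholds}")
        self.thresholds = (float(t1), float(t2))
        self.max_inscribed_radius_px = float(max_inscribed_radius_px)
        self.closing_radius_px = int(closing_radius_px)
        self.crack_contrast = float(crack_contrast)

    def label_tile(self, tile: np.ndarray) -> np.ndarray:
        t1, t2 = self.thresholds
        g = tile.astype(np.float32)
        lab = np.full(g.shape, AIR, dtype=np.uint8)
        lab[g >= t2] = ENAMEL
        lab[(g >= t1) & (g < t2)] = DENTIN
        tissue = g >= t1
        if not tissue.any():
            return lab
        footprint = morphology.disk(self.closing_radius_px)
        closed = ndimage.binary_erosion(
            ndimage.binary_dilation(tissue, structure=footprint),
            structure=footprint, border_value=1)
        filled = ndimage.binary_fill_holes(closed)
        host = ndimage.grey_closing(g, footprint=footprint)
        # partial-volume lift: a pixel dimmed by a sub-voxel crack but still
        # at least crack_contrast of its host grey belongs to the host class
        dimmed = filled & (g >= self.crack_contrast * host)
        lab[dimmed & (host >= t2) & (g < t2)] = ENAMEL
        lab[dimmed & (host >= t1) & (host < t2) & (g < t1)] = DENTIN
        candidates = filled & (host >= t1) & (g < self.crack_contrast * host)
        if not candidates.any():
            return lab
        r_max = self.max_inscribed_radius_px
        dark = filled & (g < t1)
        core = ndimage.distance_transform_edt(dark) > r_max
        if core.any():
            blobby = candidates & (ndimage.distance_transform_edt(~core) <= r_max)
        else:
            blobby = np.zeros_like(candidates)
        lab[candidates & ~blobby] = CRACK
        return lab

    def predict(self, tile: np.ndarray) -> np.ndarray:
        lab = self.label_tile(tile)
        return np.eye(N_CLASSES, dtype=np.float32)[lab]


def rule_based_oracle(grey_volume: GreyVolume | None = None,
                      thresholds: tuple[float, float] | None = None,
                      **kwargs) -> RuleBasedBackend:
    """Build the rule-based oracle backend.

    Thresholds may be given explicitly (air/dentin, dentin/enamel) or derived
    from the volume's grey histogram with multi-Otsu (3 classes).
    """
    if thresholds is None:
        if grey_volume is None:
            raise ValueError("need either thresholds or a volume to derive them from")
        # 256-bin histogram keeps the multi-Otsu search tractable on 16-bit data
        counts, edges = np.histogram(grey_volume.data, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        t1, t2 = filters.threshold_multiotsu(hist=(counts, centers), classes=3)
        thresholds = (float(t1), float(t2))
    return RuleBasedBackend(thresholds, **kwargs)


# ---------------------------------------------------------------------------
# slice assembly

def _slice_view(data: np.ndarray, axis: int, i: int) -> np.ndarray:
    if axis == 0:
        return data[i]
    if axis == 1:
        return data[:, i, :]
    return data[:, :, i]


def segment_slice(slice2d: np.ndarray, backend, tile_size: int | None = None,
                  stride: int | None = None) -> np.ndarray:
    """Classify one slice: tile, predict, average probabilities, argmax."""
    h, w = slice2d.shape
    if tile_size is None or tile_size >= min(h, w):
        probs = backend.predict(slice2d)
        return probs.argmax(axis=-1).astype(np.uint8)
    grid = make_tile_grid((h, w), tile_size=tile_size, stride=stride)
    acc = np.zeros((h, w, N_CLASSES), dtype=np.float32)
    cnt = np.zeros((h, w, 1), dtype=np.float32)
    for (r, c) in grid.origins:
        probs = backend.predict(slice2d[r:r + tile_size, c:c + tile_size])
        acc[r:r + tile_size, c:c + tile_size] += probs
        cnt[r:r + tile_size, c:c + tile_size] += 1.0
    return (acc / cnt).argmax(axis=-1).astype(np.uint8)


def segment_axis(volume: GreyVolume, backend, axis,
                 tile_size: int | None = None, stride: int | None = None,
                 verbose: bool = False) -> LabelVolume:
    """Segment every slice perpendicular to ``axis`` and reassemble a label
    volume of the same shape. ``axis`` is one of {"z", "y", "x"} (or 0..2).

    Without an explicit ``tile_size`` the full slice is classified in one
    tile (all backends here are fully convolutional / morphological); with
    one, overlapping tiles are averaged in probability space.
    """
    ax = _AXIS_INDEX.get(axis)
    if ax is None:
        raise ValueError(f"axis must be one of z/y/x, got {axis!r}")
    data = volume.data
    out = np.empty(data.shape, dtype=np.uint8)
    t0 = time.time()
    for i in range(data.shape[ax]):
        sl = segment_slice(np.ascontiguousarray(_slice_view(data, ax, i)),
                           backend, tile_size=tile_size, stride=stride)
        _slice_view(out, ax, i)[...] = sl
        if verbose and (i + 1) % 32 == 0:
            print(f"  axis {axis}: {i + 1}/{data.shape[ax]} slices "
                  f"({time.time() - t0:.1f}s)", flush=True)
    return LabelVolume(data=out, voxel_pitch_um=volume.voxel_pitch_um)


def pixel_accuracy(pred, truth) -> float:
    """Fraction of voxels with identical class codes."""
    a = pred.data if hasattr(pred, "voxel_pitch_um") else np.asarray(pred)
    b = truth.data if hasattr(truth, "voxel_pitch_um") else np.asarray(truth)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(a == b))
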