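"""Minimal numpy neural-network engine for the reference segmentation CNN.

Implements exactly what the reference model needs: 2D convolution (with
dilation), ReLU, 2x2 average pooling, nearest-neighbour upsampling, a skip
concatenation, softmax cross-entropy, and Adam. Everything is vectorised
over the batch via per-kernel-offset strided views, runs single-threaded on
CPU, and is bit-deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np


def conv2d_forward(x, W, b, dilation=1):
    """x: (N, C, H, Wd); W: (O, C, k, k); 'same' padding. Returns (out, xp)."""
    N, C, H, Wd = x.shape
    k = W.shape[2]
    pad = dilation * (k // 2)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    out = np.broadcast_to(b[None, :, None, None], (N, W.shape[0], H, Wd)).copy()
    for i in range(k):
        for j in range(k):
            xs = xp[:, :, i * dilation:i * dilation + H, j * dilation:j * dilation + Wd]
            out += np.einsum("oc,nchw->nohw", W[:, :, i, j], xs, optimize=True)
    return out, xp


def conv2d_backward(dout, xp, W, dilation=1):
    """Returns (dx, dW, db) for conv2d_forward."""
    N, O, H, Wd = dout.shape
    k = W.shape[2]
    pad = dilation * (k // 2)
    dW = np.zeros_like(W)
    db = dout.sum(axis=(0, 2, 3))
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            sl = (slice(None), slice(None),
                  slice(i * dilation, i * dilation + H),
                  slice(j * dilation, j * dilation + Wd))
            dW[:, :, i, j] = np.einsum("nohw,nchw->oc", dout, xp[sl], optimize=True)
            dxp[sl] += np.einsum("oc,nohw->nchw", W[:, :, i, j], dout, optimize=True)
    if pad:
        return dxp[:, :, pad:-pad, pad:-pad], dW, db
    return dxp, dW, db


def avgpool2(x):
    N, C, H, W = x.shape
    return x.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))


def avgpool2_backward(dout):
    return np.repeat(np.repeat(dout, 2, axis=2), 2, axis=3) / 4.0


def upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def upsample2_backward(dout):
    N, C, H, W = dout.shape
    return dout.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


def softmax(logits):
    """logits: (N, K, H, W) -> probabilities along axis 1."""
    m = logits.max(axis=1, keepdims=True)
    e = np.exp(logits - m)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs, onehot):
    """Mean categorical cross-entropy; gradient w.r.t. logits is
    (probs - onehot) / n_pixels."""
    eps = 1e-12
    n = probs.shape[0] * probs.shape[2] * probs.shape[3]
    loss = -np.sum(onehot * np.log(probs + eps)) / n
    return loss, (probs - onehot) / n


class SegNet:
    """Small fully-convolutional encoder-decoder for 4-class tile segmentation.

    Encoder: two 3x3 convs at full resolution, 2x average pool, a 3x3 conv and
    a dilated (rate-2) 3x3 conv for multi-scale context. Decoder: nearest
    upsampling, skip concatenation with the full-resolution features, a 3x3
    conv, and a 1x1 classifier head that also sees the raw input (an input
    skip keeps class boundaries pixel-accurate while the deeper features
    provide the context that separates cracks from the pulp cavity and
    background). Input is a 3-channel tile (the greyscale slice replicated to
    three channels) scaled to [0, 1]; output is a 4-class softmax per pixel.
    Tiles must have even height and width (one pooling stage); arbitrary even
    sizes work as the net is fully convolutional.
    """

    N_CLASSES = 4

    def __init__(self, channels: int = 12, seed: int = 0):
        self.channels = channels
        rng = np.random.default_rng(seed)
        c = channels

        def he(o, ci, k):
            w = rng.normal(0, np.sqrt(2.0 / (ci * k * k)), size=(o, ci, k, k))
            return w.astype(np.float32)

        self.params = {
            "W1": he(c, 3, 3), "b1": np.zeros(c, np.float32),
            "W2": he(c, c, 3), "b2": np.zeros(c, np.float32),
            "W3": he(2 * c, c, 3), "b3": np.zeros(2 * c, np.float32),
            "W4": he(2 * c, 2 * c, 3), "b4": np.zeros(2 * c, np.float32),
            "W5": he(2 * c, 3 * c, 3), "b5": np.zeros(2 * c, np.float32),
            "W6": he(self.N_CLASSES, 2 * c + 3, 1), "b6": np.zeros(self.N_CLASSES, np.float32),
        }
        self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t = 0

    # -- forward / backward -------------------------------------------------

    def forward(self, x):
        """x: (N, 3, H, W) float in [0, 1], H and W even. Returns (probs, cache)."""
        p = self.params
        z1, xp1 = conv2d_forward(x, p["W1"], p["b1"])
        h1 = np.maximum(z1, 0)
        z2, xp2 = conv2d_forward(h1, p["W2"], p["b2"])
        h2 = np.maximum(z2, 0)
        pl = avgpool2(h2)
        z3, xp3 = conv2d_forward(pl, p["W3"], p["b3"])
        h3 = np.maximum(z3, 0)
        z4, xp4 = conv2d_forward(h3, p["W4"], p["b4"], dilation=2)
        h4 = np.maximum(z4, 0)
        up = upsample2(h4)
        cat = np.concatenate([up, h2], axis=1)
        z5, xp5 = conv2d_forward(cat, p["W5"], p["b5"])
        h5 = np.maximum(z5, 0)
        head_in = np.concatenate([h5, x], axis=1)  # input skip into the head
        logits, xp6 = conv2d_forward(head_in, p["W6"], p["b6"])
        probs = softmax(logits)
        cache = (z1, xp1, z2, xp2, xp3, z3, z4, xp4, xp5, z5, xp6, h4)
        return probs, cache

    def backward(self, dlogits, cache):
        p = self.params
        z1, xp1, z2, xp2, xp3, z3, z4, xp4, xp5, z5, xp6, h4 = cache
        g = {}
        dhead, g["W6"], g["b6"] = conv2d_backward(dlogits, xp6, p["W6"])
        dh5 = dhead[:, :-3]  # gradient into the raw-input skip is discarded
        dz5 = dh5 * (z5 > 0)
        dcat, g["W5"], g["b5"] = conv2d_backward(dz5, xp5, p["W5"])
        c2 = h4.shape[1]
        dup, dh2_skip = dcat[:, :c2], dcat[:, c2:]
        dh4 = upsample2_backward(dup)
        dz4 = dh4 * (z4 > 0)
        dh3, g["W4"], g["b4"] = conv2d_backward(dz4, xp4, p["W4"], dilation=2)
        dz3 = dh3 * (z3 > 0)
        dpl, g["W3"], g["b3"] = conv2d_backward(dz3, xp3, p["W3"])
        dh2 = avgpool2_backward(dpl) + dh2_skip
        dz2 = dh2 * (z2 > 0)
        dh1, g["W2"], g["b2"] = conv2d_backward(dz2, xp2, p["W2"])
        dz1 = dh1 * (z1 > 0)
        _, g["W1"], g["b1"] = conv2d_backward(dz1, xp1, p["W1"])
        return g

    def adam_step(self, grads, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self._adam_t += 1
        t = self._adam_t
        for k, gk in grads.items():
            m = self._adam_m[k] = beta1 * self._adam_m[k] + (1 - beta1) * gk
            v = self._adam_v[k] = beta2 * self._adam_v[k] + (1 - beta2) * gk * gk
            mhat = m / (1 - beta1**t)
            vhat = v / (1 - beta2**t)
            self.params[k] -= lr * mhat / (np.sqrt(vhat) + eps)

    # -- inference ----------------------------------------------------------

    def predict_probs(self, batch3c):
        """batch3c: (N, 3, H, W) in [0, 1]; pads odd H/W to even and crops back.
        Returns (N, H, W, 4) probabilities."""
        N, _, H, W = batch3c.shape
        ph, pw = H % 2, W % 2
        if ph or pw:
            batch3c = np.pad(batch3c, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="edge")
        probs, _ = self.forward(batch3c)
        probs = probs[:, :, :H, :W]
        return np.moveaxis(probs, 1, -1)

    # -- persistence ---------------------------------------------------------

    def save(self, path):
        np.savez(path, channels=np.array(self.channels), **self.params)

    @classmethod
    def load(cls, path):
        data = np.load(path)
        net = cls(channels=int(data["channels"]), seed=0)
        for k in net.params:
            net.params[k] = data[k]
        return net
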