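"""Minimal convolutional network with explicit forward/backward passes.

A compact NHWC conv-net implemented directly on numpy: 3x3 same-padding
convolutions (computed as nine shifted matmuls), ReLU, 2x2 max pooling,
global average pooling and a dense softmax head, trained with Adam.  Because
the backward pass is explicit, the gradient of any class logit with respect
to any convolutional layer's activations — the quantity Grad-CAM needs — is
available without an autodiff framework.

Inputs are float32 arrays in [0, 1], shape (N, H, W, 3).
"""

from __future__ import annotations

import numpy as np

__all__ = ["SmallCNN", "Adam", "softmax", "soft_cross_entropy"]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def soft_cross_entropy(
    probs: np.ndarray, targets: np.ndarray, eps: float = 1e-12
) -> np.ndarray:
    """Per-sample cross-entropy -sum(t * log p); accepts soft targets."""
    return -np.sum(targets * np.log(np.clip(probs, eps, None)), axis=-1)


def _conv3x3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    n, h, w, _ = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    out = np.broadcast_to(b, (n, h, w, W.shape[-1])).copy()
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + h, dj : dj + w, :].reshape(-1, x.shape[-1])
            out += (patch @ W[di, dj]).reshape(n, h, w, -1)
    return out


def _conv3x3_backward(
    x: np.ndarray, W: np.ndarray, dout: np.ndarray, need_dx: bool
) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    n, h, w, cin = x.shape
    cout = W.shape[-1]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    dW = np.empty_like(W)
    dflat = dout.reshape(-1, cout)
    dxp = np.zeros_like(xp) if need_dx else None
    for di in range(3):
        for dj in range(3):
            patch = xp[:, di : di + h, dj : dj + w, :].reshape(-1, cin)
            dW[di, dj] = patch.T @ dflat
            if need_dx:
                dxp[:, di : di + h, dj : dj + w, :] += (dflat @ W[di, dj].T).reshape(
                    n, h, w, cin
                )
    db = dflat.sum(axis=0)
    dx = dxp[:, 1 : h + 1, 1 : w + 1, :] if need_dx else None
    return dx, dW, db


def _maxpool(a: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    """2x2/stride-2 max pool; odd trailing rows/cols are dropped."""
    n, h, w, c = a.shape
    h2, w2 = h // 2, w // 2
    a = a[:, : h2 * 2, : w2 * 2, :]
    windows = a.reshape(n, h2, 2, w2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    windows = windows.reshape(n, h2, w2, c, 4)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]
    return out, idx, (h, w)


def _maxpool_backward(
    dout: np.ndarray, idx: np.ndarray, in_shape: tuple
) -> np.ndarray:
    h, w = in_shape
    n, h2, w2, c = dout.shape
    dwin = np.zeros((n, h2, w2, c, 4), dtype=dout.dtype)
    np.put_along_axis(dwin, idx[..., None], dout[..., None], axis=-1)
    da = dwin.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
    da = da.reshape(n, h2 * 2, w2 * 2, c)
    if (h, w) != (h2 * 2, w2 * 2):
        da = np.pad(da, ((0, 0), (0, h - h2 * 2), (0, w - w2 * 2), (0, 0)))
    return da


class SmallCNN:
    """Small conv-net: [conv3x3-ReLU-pool] x (L-1), conv3x3-ReLU, GAP, dense.

    Parameters
    ----------
    image_size:
        Input side length in pixels.
    n_classes:
        Number of output classes.
    channels:
        Output channels of the successive conv layers; pooling follows every
        conv except the last, so the final feature map has side
        ``image_size / 2**(len(channels)-1)`` (floor at each pool).
    seed:
        Seed of the weight initialisation (He-normal).
    """

    def __init__(
        self,
        image_size: int,
        n_classes: int,
        channels: tuple[int, ...] = (8, 16, 32, 32),
        seed: int = 0,
    ) -> None:
        self.image_size = int(image_size)
        self.n_classes = int(n_classes)
        self.channels = tuple(channels)
        self.seed = int(seed)
        self.initialize(seed)

    # -- parameters -------------------------------------------------------

    def initialize(self, seed: int) -> None:
        """(Re-)initialize all weights from ``seed`` (the 'base' weights)."""
        rng = np.random.default_rng(seed)
        cins = (3,) + self.channels[:-1]
        self.conv_W = [
            (rng.standard_normal((3, 3, cin, cout)) * np.sqrt(2.0 / (9 * cin))).astype(
                np.float32
            )
            for cin, cout in zip(cins, self.channels)
        ]
        self.conv_b = [np.zeros(c, dtype=np.float32) for c in self.channels]
        self.dense_W = (
            rng.standard_normal((self.channels[-1], self.n_classes))
            * np.sqrt(1.0 / self.channels[-1])
        ).astype(np.float32)
        self.dense_b = np.zeros(self.n_classes, dtype=np.float32)

    def parameters(self, head_only: bool = False) -> list[np.ndarray]:
        if head_only:
            return [self.dense_W, self.dense_b]
        return [*self.conv_W, *self.conv_b, self.dense_W, self.dense_b]

    def state_dict(self) -> dict:
        return {
            "conv_W": [w.copy() for w in self.conv_W],
            "conv_b": [b.copy() for b in self.conv_b],
            "dense_W": self.dense_W.copy(),
            "dense_b": self.dense_b.copy(),
        }

    def load_state_dict(self, state: dict) -> None:
        self.conv_W = [w.copy() for w in state["conv_W"]]
        self.conv_b = [b.copy() for b in state["conv_b"]]
        self.dense_W = state["dense_W"].copy()
        self.dense_b = state["dense_b"].copy()

    # -- forward / backward ----------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Return logits (and the layer cache when ``want_cache``)."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        cache = {"inputs": [], "acts": [], "pools": []}
        h = x
        last = len(self.channels) - 1
        for l, (W, b) in enumerate(zip(self.conv_W, self.conv_b)):
            cache["inputs"].append(h)
            z = _conv3x3(h, W, b)
            a = np.maximum(z, 0.0)
            cache["acts"].append(a)
            if l < last:
                a, idx, in_shape = _maxpool(a)
                cache["pools"].append((idx, in_shape))
            h = a
        gap = h.mean(axis=(1, 2))
        cache["gap_input"] = h
        logits = gap @ self.dense_W + self.dense_b
        cache["gap"] = gap
        return (logits, cache) if want_cache else logits

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def loss_and_grads(
        self,
        x: np.ndarray,
        targets: np.ndarray,
        sample_weight: np.ndarray | None = None,
        head_only: bool = False,
    ) -> tuple[float, list[np.ndarray]]:
        """Weighted-mean soft cross-entropy loss and parameter gradients.

        ``targets`` is (N, K), rows summing to 1 (one-hot or soft);
        ``sample_weight`` defaults to uniform.  Gradients are returned in
        the order of :meth:`parameters`.
        """
        n = len(x)
        w = (
            np.ones(n, dtype=np.float32)
            if sample_weight is None
            else np.asarray(sample_weight, dtype=np.float32)
        )
        logits, cache = self.forward(x, want_cache=True)
        probs = softmax(logits)
        losses = soft_cross_entropy(probs, targets)
        wsum = w.sum()
        loss = float((w * losses).sum() / wsum)

        dlogits = (probs - targets) * (w / wsum)[:, None]
        gap = cache["gap"]
        d_dense_W = gap.T @ dlogits
        d_dense_b = dlogits.sum(axis=0)
        if head_only:
            return loss, [d_dense_W, d_dense_b]

        h = cache["gap_input"]
        dgap = dlogits @ self.dense_W.T
        da = np.broadcast_to(
            dgap[:, None, None, :] / (h.shape[1] * h.shape[2]), h.shape
        ).astype(np.float32)

        dconv_W, dconv_b = [], []
        last = len(self.channels) - 1
        for l in range(last, -1, -1):
            if l < last:
                idx, in_shape = cache["pools"][l]
                da = _maxpool_backward(da, idx, in_shape)
            da = da * (cache["acts"][l] > 0)
            need_dx = l > 0
            dx, dW, db = _conv3x3_backward(
                cache["inputs"][l], self.conv_W[l], da, need_dx
            )
            dconv_W.append(dW)
            dconv_b.append(db)
            da = dx
        dconv_W.reverse()
        dconv_b.reverse()
        return loss, [*dconv_W, *dconv_b, d_dense_W, d_dense_b]

    # -- Grad-CAM support -------------------------------------------------

    @property
    def cam_layer(self) -> int:
        """Index of the designated Grad-CAM layer (last conv)."""
        return len(self.channels) - 1

    def forward_from(self, layer: int, activation: np.ndarray) -> np.ndarray:
        """Logits from a given post-ReLU activation of ``layer`` onward."""
        h = activation
        last = len(self.channels) - 1
        for l in range(layer, last):
            h, _, _ = _maxpool(h)
            z = _conv3x3(h, self.conv_W[l + 1], self.conv_b[l + 1])
            h = np.maximum(z, 0.0)
        gap = h.mean(axis=(1, 2))
        return gap @ self.dense_W + self.dense_b

    def cam_data(
        self, image: np.ndarray, target_class: int, layer: int | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Activations of a conv layer and d(logit_target)/d(activations).

        ``image`` is a single (H, W, 3) float array in [0, 1].  Returns two
        (H', W', C) arrays: the post-ReLU activation of the designated layer
        and the gradient of the target-class logit with respect to it.
        """
        layer = self.cam_layer if layer is None else layer
        _, cache = self.forward(image[None], want_cache=True)
        A = cache["acts"][layer][0]

        h = cache["gap_input"]
        # d logit_target / d gap, then back through the trailing layers
        da = np.zeros_like(h)
        da += self.dense_W[:, target_class][None, None, None, :] / (
            h.shape[1] * h.shape[2]
        )
        last = len(self.channels) - 1
        for l in range(last, layer, -1):
            da = da * (cache["acts"][l] > 0)
            dx, _, _ = _conv3x3_backward(cache["inputs"][l], self.conv_W[l], da, True)
            idx, in_shape = cache["pools"][l - 1]
            da = _maxpool_backward(dx, idx, in_shape)
        # gradient w.r.t. the post-ReLU activation itself: no ReLU mask here
        return A, da[0]


class Adam:
    """Adam optimizer updating a fixed list of parameter arrays in place."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
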