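"""A compact convolutional regression network in pure numpy.

Architecture: four conv(3x3, same) + ReLU + maxpool(2) blocks, global
average pooling, and a single linear output — a deliberately small network
that trains from scratch in seconds on profile images, optimized with Adam
on mean-squared error and early-stopped on a validation split.

The module also implements Grad-CAM: the gradient of the scalar output with
respect to the last convolutional layer's activations is spatially averaged
into channel weights, the weighted activation sum is rectified, upsampled to
the input size and normalized to [0, 1].
"""

from __future__ import annotations

import numpy as np


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patches for 3x3 stride-1 same conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w)


def _col2im(cols: np.ndarray, shape: tuple) -> np.ndarray:
    """Adjoint of :func:`_im2col` (scatter-add of patch gradients)."""
    n, c, h, w = shape
    grad = np.zeros((n, c, h + 2, w + 2), dtype=cols.dtype)
    cols = cols.reshape(n, c, 3, 3, h, w)
    for i in range(3):
        for j in range(3):
            grad[:, :, i : i + h, j : j + w] += cols[:, :, i, j]
    return grad[:, :, 1 : 1 + h, 1 : 1 + w]


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialization
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * 9)).astype(np.float64)
        self.b = np.zeros(c_out)
        self.params = [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = _im2col(x)
        n, _, h, w = x.shape
        out = self.w @ self._cols + self.b[:, None]
        return out.reshape(n, -1, h, w)

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c_out, h, w = g.shape
        g2 = g.reshape(n, c_out, h * w)
        self.gw = np.einsum("nop,nfp->of", g2, self._cols)
        self.gb = g2.sum(axis=(0, 2))
        gcols = self.w.T @ g2
        return _col2im(gcols, self._shape)

    @property
    def grads(self):
        return [self.gw, self.gb]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class _MaxPool2:
    params: list = []
    grads: list = []

    def forward(self, x):
        self._orig_shape = x.shape
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        x = x[:, :, : 2 * h2, : 2 * w2]  # odd trailing row/col is dropped
        self._shape = x.shape
        xr = x.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, g):
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        out = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(out, self._arg[..., None], g[..., None], axis=-1)
        out = out.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        full = np.zeros(self._orig_shape, dtype=g.dtype)
        full[:, :, :h, :w] = out
        return full


class TinyCNN:
    """Small from-scratch CNN regressor on single-channel images.

    Parameters
    ----------
    in_channels : int
        Input channel count (profile images are fed as a 1-channel ink mask).
    channels : tuple of int
        Output channels of the conv blocks.
    seed : int
        Weight-initialization seed.
    """

    def __init__(self, in_channels: int = 1, channels: tuple = (8, 16, 32, 64), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.blocks: list = []
        c_prev = in_channels
        for c in channels:
            self.blocks += [_Conv(c_prev, c, rng), _ReLU(), _MaxPool2()]
            c_prev = c
        self.head_w = rng.normal(0.0, 1.0 / np.sqrt(c_prev), size=c_prev)
        self.head_b = 0.0
        self._adam_state = None

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        for layer in self.blocks:
            x = layer.forward(x)
        self._last_conv = x  # (N, C, h, w) after final block
        feat = x.mean(axis=(2, 3))
        self._feat_hw = x.shape[2] * x.shape[3]
        return feat @ self.head_w + self.head_b

    def predict(self, x: np.ndarray, batch: int = 64) -> np.ndarray:
        out = [self.forward(x[i : i + batch]) for i in range(0, len(x), batch)]
        return np.concatenate(out) if out else np.empty(0)

    def _backward(self, gout: np.ndarray) -> None:
        n = len(gout)
        feat = self._last_conv.mean(axis=(2, 3))
        self.g_head_w = gout @ feat
        self.g_head_b = gout.sum()
        g = (gout[:, None] * self.head_w[None, :])[:, :, None, None]
        g = np.broadcast_to(g, self._last_conv.shape) / self._feat_hw
        g = np.ascontiguousarray(g)
        for layer in reversed(self.blocks):
            g = layer.backward(g)

    # -- optimization -------------------------------------------------------
    def _parameters(self) -> list[np.ndarray]:
        return [p for layer in self.blocks for p in layer.params]

    def _gradients(self) -> list[np.ndarray]:
        return [g for layer in self.blocks for g in layer.grads]

    def train_step(self, x, y, lr: float, beta1=0.9, beta2=0.999, eps=1e-8) -> float:
        pred = self.forward(x)
        resid = pred - y
        loss = float(np.mean(resid**2))
        self._backward(2.0 * resid / len(y))
        params = self._parameters() + [self.head_w]
        grads = self._gradients() + [self.g_head_w]
        if self._adam_state is None:
            self._adam_state = {
                "t": 0,
                "m": [np.zeros_like(p) for p in params],
                "v": [np.zeros_like(p) for p in params],
                "mb": 0.0,
                "vb": 0.0,
            }
        st = self._adam_state
        st["t"] += 1
        t = st["t"]
        for i, (p, g) in enumerate(zip(params, grads)):
            st["m"][i] = beta1 * st["m"][i] + (1 - beta1) * g
            st["v"][i] = beta2 * st["v"][i] + (1 - beta2) * g**2
            mhat = st["m"][i] / (1 - beta1**t)
            vhat = st["v"][i] / (1 - beta2**t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)
        st["mb"] = beta1 * st["mb"] + (1 - beta1) * self.g_head_b
        st["vb"] = beta2 * st["vb"] + (1 - beta2) * self.g_head_b**2
        self.head_b -= lr * (st["mb"] / (1 - beta1**t)) / (
            np.sqrt(st["vb"] / (1 - beta2**t)) + 1e-8
        )
        return loss

    def get_weights(self) -> list[np.ndarray]:
        params = self._parameters()
        return [p.copy() for p in params] + [self.head_w.copy(), np.array(self.head_b)]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self._parameters()
        for p, w in zip(params, weights[:-2]):
            p[...] = w
        self.head_w[...] = weights[-2]
        self.head_b = float(weights[-1])

    # -- training loop ------------------------------------------------------
    def fit(
        self,
        x_train: np.ndarray,
        y_train: np.ndarray,
        x_val: np.ndarray,
        y_val: np.ndarray,
        lr: float = 3e-3,
        batch_size: int = 16,
        max_epochs: int = 80,
        patience: int = 8,
        seed: int = 0,
    ) -> dict:
        """Mini-batch Adam with early stopping on validation MSE.

        Returns a training log: per-epoch train/val losses, the best epoch and
        the epoch at which training stopped.  Weights are restored to the best
        validation epoch.
        """
        rng = np.random.default_rng(seed)
        n = len(x_train)
        best_val, best_epoch, best_weights = np.inf, -1, self.get_weights()
        log = {"train_loss": [], "val_loss": [], "best_epoch": -1, "stopped_epoch": -1}
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            losses = []
            for i in range(0, n, batch_size):
                idx = order[i : i + batch_size]
                losses.append(self.train_step(x_train[idx], y_train[idx], lr))
            val_pred = self.predict(x_val)
            val_loss = float(np.mean((val_pred - y_val) ** 2))
            log["train_loss"].append(float(np.mean(losses)))
            log["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-12:
                best_val, best_epoch = val_loss, epoch
                best_weights = self.get_weights()
            elif epoch - best_epoch >= patience:
                break
        log["best_epoch"] = best_epoch
        log["stopped_epoch"] = epoch
        self.set_weights(best_weights)
        self.fitted_ = True
        return log

    # -- interpretation -----------------------------------------------------
    def gradcam(self, x: np.ndarray) -> np.ndarray:
        """Gradient-weighted class-activation map for one input (1, C, H, W).

        Returns a heatmap of the input's spatial size with values in [0, 1].
        """
        if not getattr(self, "fitted_", False):
            raise RuntimeError("gradcam requires a trained network")
        if x.ndim == 3:
            x = x[None]
        self.forward(x)
        acts = self._last_conv[0]  # (C, h, w)
        # d(output)/d(acts) for the GAP + linear head is head_w / (h*w) per cell
        grads = self.head_w[:, None, None] / self._feat_hw
        weights = grads.mean(axis=(1, 2))
        cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
        # nearest-neighbour upsample to input resolution
        rep_h = int(np.ceil(x.shape[2] / cam.shape[0]))
        rep_w = int(np.ceil(x.shape[3] / cam.shape[1]))
        cam = np.kron(cam, np.ones((rep_h, rep_w)))[: x.shape[2], : x.shape[3]]
        if cam.max() > 0:
            cam = cam / cam.max()
        return cam
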