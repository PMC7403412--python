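"""A compact convolutional network for phase-map classification, in NumPy.

Four conv(3×3)/ReLU/max-pool(2) blocks followed by two fully connected
layers, trained with stochastic gradient descent with momentum (SGDM),
initial learning rate 1e-4 and 30 epochs — the same protocol used for
the feature-free classification path.  Convolutions run as im2col matrix
products, so training a few hundred 48×48 phase crops takes minutes on
one CPU.  Phase values enter as real numbers (standardized, never
quantized to 8 bits), preserving the quantitative signal.

Everything is seeded: weight init, shuffling, and therefore the final
confusion matrix, are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from skimage.transform import resize

from .types import CLASS_ORDER, ConfusionMatrix, PhaseMap, SplitSpec, TrainConfig
from .classify import split_dataset, _confusion

__all__ = ["SmallCNN", "preprocess_phase", "train_cnn"]

INPUT_SIZE = 48
_CHANNELS = (8, 16, 32, 32)
_HIDDEN = 64


def _im2col(x: np.ndarray, k: int = 3) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*k*k) patches of a zero-padded input."""
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # N,C,H,W,k,k
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(
        x.shape[0], x.shape[2], x.shape[3], -1
    )


class _Conv:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * 9))
        self.W = rng.standard_normal((cin * 9, cout)) * scale
        self.b = np.zeros(cout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cols = _im2col(x)  # N,H,W,cin*9
        self.in_shape = x.shape
        out = self.cols @ self.W + self.b  # N,H,W,cout
        return out.transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        g = g.transpose(0, 2, 3, 1)  # N,H,W,cout
        self.dW = self.cols.reshape(-1, self.cols.shape[-1]).T @ g.reshape(-1, g.shape[-1])
        self.db = g.sum(axis=(0, 1, 2))
        gc = g @ self.W.T  # N,H,W,cin*9
        N, C, H, W = self.in_shape
        gx = np.zeros((N, C, H + 2, W + 2))
        gc = gc.reshape(N, H, W, C, 3, 3)
        for di in range(3):
            for dj in range(3):
                gx[:, :, di : di + H, dj : dj + W] += gc[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        return gx[:, :, 1 : 1 + H, 1 : 1 + W]

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


class _Dense:
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        self.W = rng.standard_normal((nin, nout)) * np.sqrt(2.0 / nin)
        self.b = np.zeros(nout)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.x = x
        return x @ self.W + self.b

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.dW = self.x.T @ g
        self.db = g.sum(axis=0)
        return g @ self.W.T

    def params(self):
        return [(self.W, "dW"), (self.b, "db")]


def _maxpool(x: np.ndarray):
    N, C, H, W = x.shape
    r = x.reshape(N, C, H // 2, 2, W // 2, 2)
    m = r.max(axis=(3, 5))
    mask = r == m[:, :, :, None, :, None]
    # break pooling ties deterministically: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    flat = flat & first
    mask = flat.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
    return m, mask


def _maxpool_back(g: np.ndarray, mask: np.ndarray) -> np.ndarray:
    N, C, Ho, Wo = g.shape
    return (mask * g[:, :, :, None, :, None]).reshape(N, C, Ho * 2, Wo * 2)


class SmallCNN:
    """4-block conv net: 1→8→16→32→32 channels, then 64-unit dense head."""

    def __init__(self, n_classes: int = 4, seed: int = 0, input_size: int = INPUT_SIZE):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 101])
        self.input_size = input_size
        chans = (1,) + _CHANNELS
        self.convs = [_Conv(chans[i], chans[i + 1], rng) for i in range(4)]
        feat = _CHANNELS[-1] * (input_size // 16) ** 2
        self.fc1 = _Dense(feat, _HIDDEN, rng)
        self.fc2 = _Dense(_HIDDEN, n_classes, rng)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._relu_masks = []
        self._pool_masks = []
        h = x
        for conv in self.convs:
            h = conv.forward(h)
            rm = h > 0
            h = h * rm
            h, pm = _maxpool(h)
            if train:
                self._relu_masks.append(rm)
                self._pool_masks.append(pm)
        self._flat_shape = h.shape
        h = h.reshape(h.shape[0], -1)
        h = self.fc1.forward(h)
        self._relu_fc = h > 0
        h = h * self._relu_fc
        return self.fc2.forward(h)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.fc2.backward(glogits)
        g = g * self._relu_fc
        g = self.fc1.backward(g)
        g = g.reshape(self._flat_shape)
        for conv, rm, pm in zip(
            reversed(self.convs), reversed(self._relu_masks), reversed(self._pool_masks)
        ):
            g = _maxpool_back(g, pm)
            g = g * rm
            g = conv.backward(g)

    def layers(self):
        return self.convs + [self.fc1, self.fc2]

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers() for p, _ in layer.params())

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, len(x), batch_size):
            out.append(np.argmax(self.forward(x[i : i + batch_size]), axis=1))
        return np.concatenate(out)


def _softmax_xent(logits: np.ndarray, y: np.ndarray):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = len(y)
    loss = -np.mean(np.log(p[np.arange(n), y] + 1e-12))
    g = p.copy()
    g[np.arange(n), y] -= 1.0
    return loss, g / n


def _pose_normalize(v: np.ndarray) -> np.ndarray:
    """Rotate the cell to a canonical pose: axis horizontal, head left.

    The principal axis of the silhouette is aligned with the columns,
    then the frame is mirrored if needed so the bright head sits on the
    left and the tail trails right.  Removing the rotation nuisance lets
    a small network learn the class differences from a few hundred
    examples instead of needing rotation augmentation at scale.
    """
    from scipy import ndimage as ndi

    sil = v > 0.02
    if sil.sum() < 16:
        return v
    rr, cc = np.nonzero(sil)
    w = v[rr, cc]
    mr, mc = np.average(rr, weights=w), np.average(cc, weights=w)
    yr, xc = rr - mr, cc - mc
    cov = np.array(
        [
            [np.average(xc * xc, weights=w), np.average(xc * yr, weights=w)],
            [np.average(xc * yr, weights=w), np.average(yr * yr, weights=w)],
        ]
    )
    evals, evecs = np.linalg.eigh(cov)
    vx, vy = evecs[:, int(np.argmax(evals))]  # principal axis (x, y)
    angle = np.degrees(np.arctan2(vy, vx))
    rot = ndi.rotate(v, angle, reshape=True, order=1, cval=0.0)
    # head = peak-phase side; mirror so it sits on the low-column side
    cols = rot.clip(min=0.0).sum(axis=0)
    head_col = int(np.argmax(ndi.uniform_filter1d(cols, 15)))
    rr2, cc2 = np.nonzero(rot > 0.02)
    if rr2.size and head_col > np.median(cc2):
        rot = rot[:, ::-1]
    return rot


def preprocess_phase(pm: PhaseMap, size: int = INPUT_SIZE) -> np.ndarray:
    """Pose-normalize, crop to the cell bounding box and resample.

    The crop keeps the whole silhouette — head and tail — so tail-borne
    class signal survives; resampling is bilinear on the real-valued
    phase (no 8-bit quantization).
    """
    v = _pose_normalize(pm.values)
    sil = v > 0.02
    if not sil.any():
        sil = v > v.max() * 0.1 if v.max() > 0 else np.ones_like(v, bool)
    rr, cc = np.nonzero(sil)
    m = 4
    r0, r1 = max(rr.min() - m, 0), min(rr.max() + m + 1, v.shape[0])
    c0, c1 = max(cc.min() - m, 0), min(cc.max() + m + 1, v.shape[1])
    side = max(r1 - r0, c1 - c0)
    # pad the crop to a square so aspect ratio (hence eccentricity) survives
    crop = np.zeros((side, side))
    crop[: r1 - r0, : c1 - c0] = v[r0:r1, c0:c1]
    return resize(crop, (size, size), order=1, anti_aliasing=True, preserve_range=True)


def train_cnn(
    maps: list[PhaseMap] | np.ndarray,
    labels: np.ndarray | None = None,
    config: TrainConfig | None = None,
    spec: SplitSpec | None = None,
):
    """Train the CNN with the SGDM protocol; evaluate on the test split.

    ``maps`` may be labelled :class:`PhaseMap` objects or a pre-built
    ``(N, size, size)`` array with explicit ``labels``.  Returns
    ``(model, ConfusionMatrix, history)`` where ``history`` is the list
    of mean epoch losses.  Aborts with diagnostics on a non-finite loss.
    """
    config = config or TrainConfig()
    spec = spec or SplitSpec(seed=config.seed)
    if labels is None:
        labels = np.array([pm.meta["label"] for pm in maps])
    labels = np.asarray(labels)
    if isinstance(maps, np.ndarray):
        X = maps.astype(float)
    else:
        X = np.stack([preprocess_phase(pm) for pm in maps])
    y = np.array([CLASS_ORDER.index(l) for l in labels])

    train_idx, test_idx = split_dataset(labels, spec)
    mu, sd = X[train_idx].mean(), X[train_idx].std() + 1e-9
    Xn = ((X - mu) / sd)[:, None, :, :]  # N,1,H,W

    model = SmallCNN(n_classes=len(CLASS_ORDER), seed=config.seed, input_size=X.shape[-1])
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 103])
    velocity = {}
    history = []
    for epoch in range(config.max_epochs):
        order = rng.permutation(train_idx)
        losses = []
        for i in range(0, len(order), config.batch_size):
            bi = order[i : i + config.batch_size]
            logits = model.forward(Xn[bi], train=True)
            loss, g = _softmax_xent(logits, y[bi])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // config.batch_size}: "
                    f"loss={loss}, logits range [{logits.min()}, {logits.max()}]"
                )
            losses.append(loss)
            model.backward(g)
            for li, layer in enumerate(model.layers()):
                for p, gname in layer.params():
                    grad = getattr(layer, gname)
                    key = (li, gname)
                    v = velocity.get(key)
                    if v is None:
                        v = np.zeros_like(p)
                    v *= config.momentum
                    v -= config.initial_learning_rate * grad
                    p += v
                    velocity[key] = v
        history.append(float(np.mean(losses)))
    y_pred = model.predict(Xn[test_idx])
    cm = _confusion(
        labels[test_idx], np.array([CLASS_ORDER[k] for k in y_pred])
    )
    return model, cm, history
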