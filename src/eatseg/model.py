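"""The window classifier: a small 1D CNN mapping W minutes of motion to p(eating).

Architecture: three strided (stride 2, valid padding) 1D convolution layers of
10 filters each with kernel lengths 44/20/4 and relu activations, global
average pooling to 10 numbers, a dense layer of 200 relu units, and a single
sigmoid output unit.  Global pooling makes the trainable parameter count
independent of the window length W; with the default configuration it is

    (6*44+1)*10 + (10*20+1)*10 + (10*4+1)*10 + (10+1)*200 + 200+1 = 7471

i.e. approximately 7500 weights.  Convolution weights carry an L1 penalty.
Training uses binary cross-entropy with Adam (learning rate 1e-4, batch 32).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .windowing import LabeledWindow, windows_to_arrays

PREDICT_BATCH = 512


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 6
    f1: int = 10
    f2: int = 10
    f3: int = 10
    L1: int = 44
    L2: int = 20
    L3: int = 4
    conv_stride: int = 2
    l1_penalty: float = 1e-4
    fc: int = 200

    def __post_init__(self) -> None:
        sizes = (self.n_channels, self.f1, self.f2, self.f3,
                 self.L1, self.L2, self.L3, self.conv_stride, self.fc)
        if any(int(s) != s or s <= 0 for s in sizes):
            raise ValueError("all architecture sizes must be positive integers")

    @property
    def fg(self) -> int:
        """Width of the globally pooled vector (one value per last-layer filter)."""
        return self.f3

    def parameter_count(self) -> int:
        """Closed-form trainable parameter count (weights + biases)."""
        return (
            (self.n_channels * self.L1 + 1) * self.f1
            + (self.f1 * self.L2 + 1) * self.f2
            + (self.f2 * self.L3 + 1) * self.f3
            + (self.fg + 1) * self.fc
            + self.fc + 1
        )

    def min_input_length(self) -> int:
        """Smallest window (in samples) for which every conv layer emits >= 1 frame."""
        m = 1
        for length in (self.L3, self.L2, self.L1):
            m = length + self.conv_stride * (m - 1)
        return m


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 150
    seed: int = 0
    loss: str = "binary_cross_entropy"
    optimizer: str = "adam"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class WindowClassifier:
    """Trained (or trainable) CNN classifying fixed-length windows as eating."""

    def __init__(self, config: ModelConfig, n_samples: int, seed: int = 0):
        if n_samples < config.min_input_length():
            raise ValueError(
                f"window of {n_samples} samples is too short for the conv stack; "
                f"minimum is {config.min_input_length()} samples"
            )
        self.config = config
        self.n_samples = int(n_samples)
        rng = np.random.default_rng(seed)
        s = config.conv_stride
        self.convs = [
            nn.Conv1D(config.n_channels, config.f1, config.L1, s, rng),
            nn.Conv1D(config.f1, config.f2, config.L2, s, rng),
            nn.Conv1D(config.f2, config.f3, config.L3, s, rng),
        ]
        self.dense = nn.Dense(config.fg, config.fc, rng)
        self.out = nn.Dense(config.fc, 1, rng, he=False)

    # ------------------------------------------------------------------ core

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in (*self.convs, self.dense, self.out))

    def parameters(self) -> list[np.ndarray]:
        params = []
        for layer in (*self.convs, self.dense, self.out):
            params.extend([layer.W, layer.b])
        return params

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Logits for a batch ``(B, T, 6)``; prediction path (no caches)."""
        a = x
        for conv in self.convs:
            a, _ = conv.forward(a)
        g = a.mean(axis=1)
        h = nn.relu(self.dense.forward(g))
        return self.out.forward(h)[:, 0]

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Probabilities in [0, 1] for a batch ``(B, T, 6)`` (float64 path)."""
        x = np.asarray(x)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.config.n_channels:
            raise ValueError(f"expected {self.config.n_channels} channels")
        if x.shape[1] < self.config.min_input_length():
            raise ValueError("window too short for the conv stack")
        probs = np.empty(x.shape[0])
        for i in range(0, x.shape[0], PREDICT_BATCH):
            batch = np.asarray(x[i : i + PREDICT_BATCH], dtype=np.float64)
            probs[i : i + PREDICT_BATCH] = nn.sigmoid(self.forward_logits(batch))
        return probs

    # ------------------------------------------------- dense whole-day path

    def predict_dense(self, x: np.ndarray, chunk: int = 1 << 16) -> np.ndarray:
        """Probability for every stride-1 window start over a full sequence.

        Evaluates the strided conv stack once over the whole sequence as
        dilated convolutions, then forms every window's global average pool
        with per-phase cumulative sums.  Arithmetically equivalent to calling
        :meth:`predict` on each of the ``n - n_samples + 1`` windows, at a
        fraction of the cost.
        """
        x = np.asarray(x, dtype=np.float64)
        n, m = x.shape[0], self.n_samples
        if n < m:
            raise ValueError(f"sequence of {n} samples shorter than one window ({m})")

        c = x
        dilation = 1
        for conv in self.convs:
            c = _dilated_conv(c, conv, dilation, chunk)
            dilation *= conv.stride

        # frames of the last conv layer that fall inside one window
        k = m
        for conv in self.convs:
            k = conv.out_length(k)
        f = self.convs[-1].c_out
        valid = n - m + 1

        pooled = np.empty((valid, f))
        for phase in range(dilation):
            y = c[phase::dilation]
            cs = np.vstack([np.zeros((1, f)), np.cumsum(y, axis=0)])
            starts = np.arange(phase, valid, dilation)
            i = (starts - phase) // dilation
            pooled[starts] = (cs[i + k] - cs[i]) / k

        h = nn.relu(self.dense.forward(pooled))
        return nn.sigmoid(self.out.forward(h)[:, 0])

    # ----------------------------------------------------------- persistence

    def save(self, path: str | os.PathLike) -> None:
        """Save weights (.npz) plus a JSON sidecar with the configuration."""
        arrays = {}
        for i, layer in enumerate((*self.convs, self.dense, self.out)):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(path, **arrays)
        sidecar = str(path).removesuffix(".npz") + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"model_config": asdict(self.config),
                       "n_samples": self.n_samples}, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "WindowClassifier":
        sidecar = str(path).removesuffix(".npz") + ".json"
        with open(sidecar) as fh:
            meta = json.load(fh)
        clf = cls(ModelConfig(**meta["model_config"]), meta["n_samples"])
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, layer in enumerate((*clf.convs, clf.dense, clf.out)):
            layer.W = data[f"W{i}"].astype(np.float32)
            layer.b = data[f"b{i}"].astype(np.float32)
        return clf


def _dilated_conv(x: np.ndarray, conv: "nn.Conv1D", dilation: int,
                  chunk: int) -> np.ndarray:
    """Stride-1 dilated convolution + relu over a full ``(T, C)`` sequence."""
    span = dilation * (conv.length - 1) + 1
    t_out = x.shape[0] - span + 1
    if t_out < 1:
        raise ValueError("sequence too short for the conv stack")
    w = conv.W.astype(np.float64)
    b = conv.b.astype(np.float64)
    out = np.empty((t_out, conv.c_out))
    from numpy.lib.stride_tricks import sliding_window_view

    for t0 in range(0, t_out, chunk):
        t1 = min(t0 + chunk, t_out)
        win = sliding_window_view(x[t0 : t1 + span - 1], span, axis=0)
        col = np.ascontiguousarray(win[:, :, ::dilation]).reshape(t1 - t0, -1)
        out[t0:t1] = nn.relu(col @ w + b)
    return out


def build_model(
    model_config: ModelConfig | None = None,
    n_samples: int = 5400,
    seed: int = 0,
) -> WindowClassifier:
    """Instantiate the window classifier for windows of ``n_samples`` data."""
    return WindowClassifier(model_config or ModelConfig(), n_samples, seed=seed)


def train_model(
    classifier: WindowClassifier,
    windows: list[LabeledWindow] | tuple[np.ndarray, np.ndarray],
    train_config: TrainConfig | None = None,
) -> tuple[WindowClassifier, dict]:
    """Train in place with Adam on binary cross-entropy; returns (model, history).

    ``windows`` is a balanced list of labeled windows (or a pre-stacked
    ``(x, y)`` pair).  History holds per-epoch mean training loss (including
    the L1 penalty on conv weights) and training accuracy.  Fully deterministic
    given ``train_config.seed``.
    """
    cfg = train_config or TrainConfig()
    if isinstance(windows, tuple):
        x, y = windows
        x = np.asarray(x, dtype=np.float32)
        y = np.asarray(y, dtype=np.float32)
    else:
        x, y = windows_to_arrays(windows)
    if x.shape[0] == 0:
        raise ValueError("no training windows")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both eating and non-eating windows")

    rng = np.random.default_rng(cfg.seed)
    params = classifier.parameters()
    adam = nn.Adam(params, lr=cfg.learning_rate)
    l1 = classifier.config.l1_penalty
    c1, c2, c3 = classifier.convs
    dense, out = classifier.dense, classifier.out

    history = {"loss": [], "accuracy": []}
    n = x.shape[0]
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        correct = 0
        for i0 in range(0, n, cfg.batch_size):
            idx = order[i0 : i0 + cfg.batch_size]
            xb, yb = x[idx], y[idx]

            a1, k1 = c1.forward(xb, train=True)
            a2, k2 = c2.forward(a1, train=True)
            a3, k3 = c3.forward(a2, train=True)
            g = a3.mean(axis=1)
            h_pre = dense.forward(g)
            h = nn.relu(h_pre)
            logits = out.forward(h)[:, 0]

            loss, dlogits = nn.bce_with_logits(logits, yb)
            penalty = l1 * sum(float(np.abs(c.W).sum()) for c in classifier.convs)
            total_loss += (loss + penalty) * len(idx)
            correct += int(np.sum((logits >= 0.0) == (yb >= 0.5)))

            dh, dw_out, db_out = out.backward(h, dlogits[:, None].astype(np.float32))
            dg, dw_d, db_d = dense.backward(g, dh * (h_pre > 0))
            da3 = np.broadcast_to(
                (dg / a3.shape[1])[:, None, :], a3.shape
            )
            dx3, dw3, db3 = c3.backward(da3, k3, need_dx=True)
            dx2, dw2, db2 = c2.backward(dx3, k2, need_dx=True)
            _, dw1, db1 = c1.backward(dx2, k1, need_dx=False)

            dw1 += l1 * np.sign(c1.W)
            dw2 += l1 * np.sign(c2.W)
            dw3 += l1 * np.sign(c3.W)
            adam.step([dw1, db1, dw2, db2, dw3, db3, dw_d, db_d, dw_out, db_out])

        history["loss"].append(total_loss / n)
        history["accuracy"].append(correct / n)
    return classifier, history


def predict_windows(
    classifier: WindowClassifier,
    windows: list[LabeledWindow] | np.ndarray,
) -> np.ndarray:
    """One probability in [0, 1] per window."""
    if isinstance(windows, np.ndarray):
        x = windows
    else:
        x, _ = windows_to_arrays(windows)
    return classifier.predict(x)


def window_accuracy(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> float:
    """Fraction of windows where thresholded probability matches the label."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    return float(np.mean((p >= threshold) == (y >= 0.5)))
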