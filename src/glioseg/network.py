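"""Random-projection spiking segmentation network.

Per-pixel features come from a fixed, seeded convolutional stack applied
to rate-coded (integrate-and-fire spike-count) channel images:

    conv 9x9 -> average pool 7x7 -> conv 9x9 -> max pool 5x5

all stride 1 with replicate padding, so every pixel keeps a feature
vector. The classifier is an extreme-learning-machine-style network: a
random, immutable input-to-hidden map ``h = g(W x + b)`` and a
closed-form hidden-to-output solve ``beta = H^+ Y`` by the minimum-norm
generalized inverse against one-hot targets. Class probabilities are the
softmax of the per-pixel output scores.

The model/results split follows the usual statistical-modelling shape:
:class:`SpikingSegmenter` holds the data and configuration, ``fit()``
returns a :class:`SegmenterResults` carrying the solved weights, the
train/test split, the training MSE and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import linalg
from scipy.ndimage import maximum_filter, uniform_filter
from scipy.signal import fftconvolve

__all__ = [
    "NetConfig",
    "SegModel",
    "SpikingSegmenter",
    "SegmenterResults",
    "encode_spikes",
    "make_filters",
    "extract_features",
    "hidden_map",
    "solve_output_weights",
    "refine_output_weights",
    "train",
    "predict_proba",
    "predict_labels",
]

_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60))),
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
    "identity": lambda z: z,
}


@dataclass(frozen=True)
class NetConfig:
    """Architecture and training parameters.

    The window sizes follow the stated layer geometry (9x9 convolution,
    7x7 pooling, 9x9 convolution, 5x5 max pooling); filter counts and
    the hidden width ``n_hidden`` are desk-scale knobs. ``epochs_cap``
    and ``mse_target`` only govern the optional iterative refinement of
    the output layer — the default training path is the one-shot
    generalized-inverse solve.
    """

    conv_window: int = 9
    pool_window: int = 7
    conv2_window: int = 9
    maxpool_window: int = 5
    n_filters1: int = 8
    n_filters2: int = 8
    n_hidden: int = 64
    activation: str = "sigmoid"
    spike_window: int = 16
    threshold: float = 1.0
    include_raw: bool = True
    ridge: float = 1e-8
    epochs_cap: int = 7000
    mse_target: float = 1e-5
    train_fraction: float = 0.75
    pixel_subsample: int = 4
    seed: int = 0

    def validate(self) -> None:
        for w in (self.conv_window, self.pool_window, self.conv2_window,
                  self.maxpool_window):
            if w < 1 or w % 2 == 0:
                raise ValueError("window sizes must be odd and positive")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation: {self.activation!r}")
        if self.spike_window < 1:
            raise ValueError("spike_window must be >= 1")


@dataclass
class SegModel:
    """A trained segmenter: immutable random projection + solved readout."""

    W: np.ndarray            # (n_features, n_hidden) random, fixed
    b: np.ndarray            # (n_hidden,) random, fixed
    beta_out: np.ndarray     # (n_active_hidden, n_classes) solved readout
    classes: np.ndarray      # label values, sorted
    config: NetConfig
    filters: dict
    feature_mask: np.ndarray | None = None   # boolean over hidden units
    logit_offsets: np.ndarray | None = None  # (n_classes,) additive scores
    train_mse: float = float("nan")
    # cached normal-equation blocks so the decision layer can be
    # re-solved under a hidden-unit mask without revisiting the data
    gram: np.ndarray | None = field(default=None, repr=False)
    cross: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def encode_spikes(
    patch: np.ndarray, window: int, threshold: float = 1.0
) -> np.ndarray:
    """Deterministic integrate-and-fire rate code.

    An intensity accumulates membrane potential linearly over ``window``
    timesteps and emits a spike each time the (scaled) threshold is
    crossed: ``count = floor(intensity * window / (255 * threshold))``,
    capped at ``window``. Zero intensity emits nothing and the code is
    monotone non-decreasing in intensity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x = np.asarray(patch, dtype=float)
    counts = np.floor(x * window / (255.0 * threshold))
    return np.clip(counts, 0, window)


def make_filters(config: NetConfig, n_channels: int = 4) -> dict:
    """Seeded random filter bank for the two convolution stages."""
    rng = np.random.default_rng(config.seed)
    k1, k2 = config.conv_window, config.conv2_window
    f1 = rng.normal(0.0, 1.0, size=(config.n_filters1, n_channels, k1, k1))
    f1 /= np.sqrt(n_channels * k1 * k1)
    f2 = rng.normal(0.0, 1.0, size=(config.n_filters2, config.n_filters1, k2, k2))
    f2 /= np.sqrt(config.n_filters1 * k2 * k2)
    return {"conv1": f1, "conv2": f2}


def _conv_same_replicate(planes: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Multi-channel 2-D correlation, stride 1, replicate padding."""
    n_out, n_in, k, _ = bank.shape
    pad = k // 2
    padded = np.pad(planes, ((0, 0), (pad, pad), (pad, pad)), mode="edge")
    h, w = planes.shape[1:]
    out = np.zeros((n_out, h, w))
    for o in range(n_out):
        acc = np.zeros((h, w))
        for c in range(n_in):
            # correlation = convolution with the flipped kernel
            acc += fftconvolve(padded[c], bank[o, c, ::-1, ::-1], mode="valid")
        out[o] = acc
    return out


def extract_features(
    channels: np.ndarray,
    config: NetConfig | None = None,
    filters: dict | None = None,
) -> np.ndarray:
    """Per-pixel feature volume (H, W, d) from the fixed conv/pool stack.

    Channels are rate-coded first; the final features are the max-pooled
    second-stage maps plus (by default) the rate-coded raw channels, so
    plain channel contrast stays directly visible to the classifier.
    """
    cfg = config or NetConfig()
    cfg.validate()
    x = np.asarray(channels, dtype=float)
    if x.ndim == 2:
        x = x[None]
    h, w = x.shape[1:]
    biggest = max(cfg.conv_window, cfg.pool_window, cfg.conv2_window,
                  cfg.maxpool_window)
    if h < biggest or w < biggest:
        raise ValueError("image smaller than the largest window")
    if filters is None:
        filters = make_filters(cfg, n_channels=x.shape[0])
    act = _ACTIVATIONS[cfg.activation]

    rates = encode_spikes(x, cfg.spike_window, cfg.threshold) / cfg.spike_window
    c1 = act(_conv_same_replicate(rates, filters["conv1"]))
    p1 = uniform_filter(c1, size=(1, cfg.pool_window, cfg.pool_window),
                        mode="nearest")
    c2 = act(_conv_same_replicate(p1, filters["conv2"]))
    p2 = maximum_filter(c2, size=(1, cfg.maxpool_window, cfg.maxpool_window),
                        mode="nearest")
    maps = [p2]
    if cfg.include_raw:
        maps.append(rates)
    return np.concatenate(maps, axis=0).transpose(1, 2, 0)


def hidden_map(
    x: np.ndarray, W: np.ndarray, b: np.ndarray, g: str | Callable = "sigmoid"
) -> np.ndarray:
    """Hidden activations ``g(x W + b)`` (rows of the H matrix)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    W = np.asarray(W, dtype=float)
    b = np.asarray(b, dtype=float)
    if x.shape[-1] != W.shape[0] or W.shape[1] != b.shape[0]:
        raise ValueError("dimension mismatch between x, W and b")
    fn = _ACTIVATIONS[g] if isinstance(g, str) else g
    return fn(x @ W + b)


def solve_output_weights(
    H: np.ndarray, Y: np.ndarray, ridge: float = 0.0
) -> np.ndarray:
    """Minimum-norm least-squares readout ``beta = H^+ Y``.

    With ``ridge > 0`` the normal equations are Tikhonov-stabilized;
    at ``ridge = 0`` the LAPACK gelsd driver returns the pseudo-inverse
    (minimum-norm) solution, whose residual is orthogonal to the column
    space of H.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if H.size == 0:
        raise ValueError("empty design matrix")
    if H.shape[0] != Y.shape[0]:
        raise ValueError("H and Y row counts differ")
    if ridge > 0:
        G = H.T @ H + ridge * np.eye(H.shape[1])
        return linalg.solve(G, H.T @ Y, assume_a="pos")
    beta, *_ = linalg.lstsq(H, Y, lapack_driver="gelsd")
    return beta


def refine_output_weights(
    H: np.ndarray,
    Y: np.ndarray,
    beta0: np.ndarray | None = None,
    epochs_cap: int = 7000,
    mse_target: float = 1e-5,
) -> tuple[np.ndarray, list[float]]:
    """Optional resilient-propagation refinement of the readout.

    Sign-based iRprop- updates on the output weights, stopping at the
    MSE target or the epoch cap. The closed-form solve is already the
    least-squares optimum, so this exists for the iterative training
    mode only; it returns the weights and the per-epoch MSE trace.
    """
    H = np.asarray(H, dtype=float)
    Y = np.asarray(Y, dtype=float)
    beta = (np.zeros((H.shape[1], Y.shape[1])) if beta0 is None
            else np.array(beta0, dtype=float))
    step = np.full_like(beta, 0.01)
    prev_grad = np.zeros_like(beta)
    n = H.shape[0]
    trace = []
    for _ in range(epochs_cap):
        resid = H @ beta - Y
        err = float(np.mean(resid**2))
        trace.append(err)
        if err <= mse_target:
            break
        grad = 2.0 * H.T @ resid / n
        same = np.sign(grad) * np.sign(prev_grad)
        step = np.where(same > 0, np.minimum(step * 1.2, 1.0),
                        np.where(same < 0, np.maximum(step * 0.5, 1e-9), step))
        grad = np.where(same < 0, 0.0, grad)  # iRprop-: skip after sign flip
        beta -= step * np.sign(grad)
        prev_grad = grad
    return beta, trace


def _active_mask(model: SegModel) -> np.ndarray:
    if model.feature_mask is None:
        return np.ones(model.W.shape[1], dtype=bool)
    return np.asarray(model.feature_mask, dtype=bool)


def _hidden_for_image(channels: np.ndarray, model: SegModel) -> np.ndarray:
    feats = extract_features(channels, model.config, model.filters)
    X = feats.reshape(-1, feats.shape[-1])
    return hidden_map(X, model.W, model.b, model.config.activation)


def predict_proba(channels: np.ndarray, model: SegModel) -> np.ndarray:
    """Per-pixel class probability map (H, W, C) via softmax scores."""
    if model.beta_out is None:
        raise ValueError("model is not trained")
    h, w = np.asarray(channels).shape[-2:]
    H = _hidden_for_image(channels, model)
    scores = H[:, _active_mask(model)] @ model.beta_out
    if model.logit_offsets is not None:
        scores = scores + model.logit_offsets
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs.reshape(h, w, model.n_classes)


def predict_labels(channels: np.ndarray, model: SegModel) -> np.ndarray:
    """Per-pixel MAP labels in the original label values."""
    probs = predict_proba(channels, model)
    return model.classes[np.argmax(probs, axis=-1)]


class SpikingSegmenter:
    """Segmentation model over a dataset of (channels, labels) pairs.

    Parameters
    ----------
    images : sequence of (C, H, W) arrays
    labels : sequence of (H, W) integer label maps
    config : NetConfig, optional
    """

    def __init__(
        self,
        images: Sequence[np.ndarray],
        labels: Sequence[np.ndarray],
        config: NetConfig | None = None,
    ):
        if len(images) < 2:
            raise ValueError("need at least 2 images to form a train/test split")
        if len(images) != len(labels):
            raise ValueError("images and labels length mismatch")
        self.images = [np.asarray(im, dtype=float) for im in images]
        self.labels = [np.asarray(lb) for lb in labels]
        self.config = config or NetConfig()
        self.config.validate()

    def fit(self) -> "SegmenterResults":
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        n = len(self.images)
        order = rng.permutation(n)
        n_train = max(1, int(round(cfg.train_fraction * n)))
        n_train = min(n_train, n - 1)  # keep the test split nonempty
        train_idx = np.sort(order[:n_train])
        test_idx = np.sort(order[n_train:])

        train_labels = np.concatenate(
            [self.labels[i].ravel() for i in train_idx]
        )
        classes = np.unique(train_labels)
        if classes.size < 2:
            raise ValueError("training labels contain a single class")

        filters = make_filters(cfg, n_channels=self.images[0].shape[0])
        feats = []
        labs = []
        sub = max(1, cfg.pixel_subsample)
        for i in train_idx:
            f = extract_features(self.images[i], cfg, filters)
            X = f.reshape(-1, f.shape[-1])
            y = self.labels[i].ravel()
            if sub > 1:
                keep = rng.permutation(X.shape[0])[: X.shape[0] // sub]
                X, y = X[keep], y[keep]
            feats.append(X)
            labs.append(y)
        X = np.concatenate(feats)
        y = np.concatenate(labs)

        d = X.shape[1]
        W = rng.normal(0.0, 1.0, size=(d, cfg.n_hidden)) / np.sqrt(d)
        b = rng.uniform(-1.0, 1.0, size=cfg.n_hidden)
        H = hidden_map(X, W, b, cfg.activation)
        Y = (y[:, None] == classes[None, :]).astype(float)
        beta = solve_output_weights(H, Y, ridge=cfg.ridge)
        train_mse = float(np.mean((H @ beta - Y) ** 2))

        model = SegModel(
            W=W, b=b, beta_out=beta, classes=classes, config=cfg,
            filters=filters, train_mse=train_mse,
            gram=H.T @ H, cross=H.T @ Y,
        )
        return SegmenterResults(self, model, train_idx, test_idx)


@dataclass
class SegmenterResults:
    """Fit artifacts: the trained model, the split and diagnostics."""

    segmenter: SpikingSegmenter
    model: SegModel
    train_idx: np.ndarray
    test_idx: np.ndarray

    @property
    def train_mse(self) -> float:
        return self.model.train_mse

    def predict_proba(self, channels: np.ndarray) -> np.ndarray:
        return predict_proba(channels, self.model)

    def predict_labels(self, channels: np.ndarray) -> np.ndarray:
        return predict_labels(channels, self.model)

    def test_accuracy(self) -> float:
        """Pixel accuracy averaged over the held-out images."""
        accs = []
        for i in self.test_idx:
            pred = self.predict_labels(self.segmenter.images[i])
            accs.append(float(np.mean(pred == self.segmenter.labels[i])))
        return float(np.mean(accs))

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Spiking random-projection segmenter",
            "===================================",
            f"images: {len(self.segmenter.images)} "
            f"(train {len(self.train_idx)} / test {len(self.test_idx)})",
            f"classes: {self.model.classes.tolist()}",
            f"features -> hidden: {self.model.W.shape[0]} -> {cfg.n_hidden} "
            f"({cfg.activation})",
            f"train MSE (one-hot regression): {self.train_mse:.6f}",
        ]
        return "\n".join(lines)


def resolve_with_mask(model: SegModel, mask: np.ndarray,
                      ridge: float | None = None) -> np.ndarray:
    """Re-solve the readout restricted to the masked hidden units.

    Uses the cached normal-equation blocks from the original fit, so no
    training data is revisited. Returns the (k, C) readout for the k
    active units.
    """
    if model.gram is None or model.cross is None:
        raise ValueError("model carries no cached normal equations")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask disables every hidden unit")
    lam = model.config.ridge if ridge is None else ridge
    G = model.gram[np.ix_(mask, mask)] + max(lam, 1e-10) * np.eye(int(mask.sum()))
    return linalg.solve(G, model.cross[mask], assume_a="pos")


def train(
    images: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
    config: NetConfig | None = None,
) -> SegmenterResults:
    """Functional wrapper: fit a :class:`SpikingSegmenter` on a dataset."""
    return SpikingSegmenter(images, labels, config).fit()
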