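"""U-net-style encoder-decoder segmenter with superpixel-centered inference.

The model is a conventional 2-D U-net: ``depth`` encoder levels of two 3x3
convolutions + ReLU followed by 2x2 max pooling, a two-convolution
bottleneck, and a mirrored decoder of nearest-neighbor upsampling, a 3x3
up-convolution, skip concatenation and two further convolutions, closed by a
1x1 convolution to a per-pixel 2-class score map. Channel width doubles per
level from ``base_channels``. Training minimizes soft Dice loss (optionally
cross-entropy or their mean) with Adam.

Inference can run in two modes: ``dense`` (per-pixel argmax) or ``centered``,
where the class score is read only at each superpixel's center pixel and
broadcast to the whole superpixel — since a schematic image is constant
within each superpixel, the center pixel represents the whole cluster, which
is what makes this acceleration sound.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ..errors import InvalidConfigError, InvalidInputError
from ..metrics import dice_coefficient
from ..types import PredictionMask, SchematicImage, SuperpixelMap, TrainHistory
from .layers import (Adam, Conv2D, MaxPool2, ReLU, UpsampleNearest2, bce_loss,
                     sigmoid, soft_dice_loss)

__all__ = [
    "NetworkConfig", "UNet", "UNetSegmenter", "build_network", "train",
    "predict_mask", "evaluate_batch", "dice_coefficient",
]


@dataclass
class NetworkConfig:
    """Hyperparameters of the segmentation network."""

    depth: int = 2
    base_channels: int = 8
    input_size: int = 128
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss: Literal["dice", "cross-entropy", "combined"] = "dice"
    seed: int = 0
    encoder_init: Literal["scratch", "transferred"] = "scratch"

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise InvalidConfigError("depth must be >= 2")
        if self.epochs < 1:
            raise InvalidConfigError("epochs must be >= 1")
        if self.base_channels < 1:
            raise InvalidConfigError("base_channels must be >= 1")
        if self.input_size % (2**self.depth) != 0:
            raise InvalidConfigError(
                f"input_size {self.input_size} not divisible by 2^depth={2**self.depth}")
        if self.loss not in ("dice", "cross-entropy", "combined"):
            raise InvalidConfigError(f"unknown loss {self.loss!r}")


class _EncBlock:
    def __init__(self, in_ch, out_ch, rng):
        self.layers = [Conv2D(in_ch, out_ch, 3, rng), ReLU(),
                       Conv2D(out_ch, out_ch, 3, rng), ReLU()]


class _DecBlock:
    def __init__(self, in_ch, out_ch, rng):
        self.up = UpsampleNearest2()
        self.upconv = Conv2D(in_ch, out_ch, 3, rng)
        self.uprelu = ReLU()
        self.layers = [Conv2D(2 * out_ch, out_ch, 3, rng), ReLU(),
                       Conv2D(out_ch, out_ch, 3, rng), ReLU()]


class UNet:
    """The bare model: forward/backward over float32 (B, 1, H, W) batches."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        if config.encoder_init == "transferred":
            warnings.warn("pretrained encoder weights are not available offline; "
                          "initializing from scratch instead", stacklevel=2)
        rng = np.random.default_rng(config.seed)
        c, d = config.base_channels, config.depth
        self.enc = []
        in_ch = 1
        for i in range(d):
            out_ch = c * 2**i
            self.enc.append(_EncBlock(in_ch, out_ch, rng))
            in_ch = out_ch
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = _EncBlock(in_ch, c * 2**d, rng)
        self.dec = []
        for i in reversed(range(d)):
            self.dec.append(_DecBlock(c * 2**(i + 1), c * 2**i, rng))
        self.final = Conv2D(c, 2, 1, rng)

    # -- plumbing ---------------------------------------------------------
    def _conv_layers(self):
        for blk in self.enc + [self.bottleneck]:
            for lay in blk.layers:
                if isinstance(lay, Conv2D):
                    yield lay
        for blk in self.dec:
            yield blk.upconv
            for lay in blk.layers:
                if isinstance(lay, Conv2D):
                    yield lay
        yield self.final

    def parameters(self):
        params = []
        for conv in self._conv_layers():
            params.extend(conv.params)
        return params

    @property
    def n_params(self) -> int:
        return sum(conv.n_params for conv in self._conv_layers())

    # -- forward / backward ----------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        d = self.config.depth
        if x.shape[2] % 2**d or x.shape[3] % 2**d:
            raise InvalidInputError(
                f"input spatial size {x.shape[2:]} not divisible by 2^depth={2**d}")
        skips = []
        h = x.astype(np.float32, copy=False)
        for i in range(d):
            for lay in self.enc[i].layers:
                h = lay.forward(h, train)
            skips.append(h)
            h = self.pools[i].forward(h, train)
        for lay in self.bottleneck.layers:
            h = lay.forward(h, train)
        self._skip_channels = []
        for j, blk in enumerate(self.dec):
            h = blk.up.forward(h, train)
            h = blk.upconv.forward(h, train)
            h = blk.uprelu.forward(h, train)
            skip = skips[d - 1 - j]
            self._skip_channels.append(skip.shape[1])
            h = np.concatenate([skip, h], axis=1)
            for lay in blk.layers:
                h = lay.forward(h, train)
        return self.final.forward(h, train)

    def backward(self, dlogits: np.ndarray):
        d = self.config.depth
        dh = self.final.backward(dlogits)
        dskips = [None] * d
        for j in reversed(range(len(self.dec))):
            blk = self.dec[j]
            for lay in reversed(blk.layers):
                dh = lay.backward(dh)
            nskip = self._skip_channels[j]
            dskip, dh = dh[:, :nskip], dh[:, nskip:]
            dskips[d - 1 - j] = dskip
            dh = blk.uprelu.backward(dh)
            dh = blk.upconv.backward(dh)
            dh = blk.up.backward(dh)
        for lay in reversed(self.bottleneck.layers):
            dh = lay.backward(dh)
        for i in reversed(range(d)):
            dh = self.pools[i].backward(dh)
            dh = dh + dskips[i]
            for lay in reversed(self.enc[i].layers):
                dh = lay.backward(dh)
        return dh

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Foreground probability map, shape (B, H, W)."""
        logits = self.forward(x, train=False)
        return sigmoid(logits[:, 1] - logits[:, 0])


def build_network(config: NetworkConfig) -> UNet:
    """Construct the model; weights are deterministic from ``config.seed``."""
    return UNet(config)


def _normalize_slice(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=np.float32)
    lo, hi = float(arr.min()), float(arr.max())
    if hi > lo:
        return (arr - lo) / (hi - lo)
    return np.zeros_like(arr)


def _to_batch(images: Sequence[np.ndarray]) -> np.ndarray:
    return np.stack([_normalize_slice(im) for im in images])[:, None, :, :]


def _safe_dice(pred: np.ndarray, gt: np.ndarray) -> float:
    if not pred.any() and not gt.any():
        return 1.0
    return dice_coefficient(pred, gt)


def _loss_and_grad(p, y, kind):
    if kind == "dice":
        return soft_dice_loss(p, y)
    if kind == "cross-entropy":
        return bce_loss(p, y)
    l1, g1 = soft_dice_loss(p, y)
    l2, g2 = bce_loss(p, y)
    return 0.5 * (l1 + l2), 0.5 * (g1 + g2)


class UNetSegmenter(BaseEstimator):
    """Sklearn-style wrapper: ``fit(images, masks)``, ``predict(images)``.

    Images are 2-D arrays (any common intensity scale; each slice is min-max
    normalized), masks are binary. After fitting, ``model_`` holds the
    trained :class:`UNet` and ``history_`` the per-epoch train/validation
    Dice scores.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8,
                 input_size: int = 128, epochs: int = 20, batch_size: int = 4,
                 learning_rate: float = 1e-3, loss: str = "dice",
                 seed: int = 0, encoder_init: str = "scratch",
                 val_fraction: float = 0.2):
        self.depth = depth
        self.base_channels = base_channels
        self.input_size = input_size
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.loss = loss
        self.seed = seed
        self.encoder_init = encoder_init
        self.val_fraction = val_fraction

    def _config(self) -> NetworkConfig:
        return NetworkConfig(depth=self.depth, base_channels=self.base_channels,
                             input_size=self.input_size, epochs=self.epochs,
                             batch_size=self.batch_size,
                             learning_rate=self.learning_rate, loss=self.loss,
                             seed=self.seed, encoder_init=self.encoder_init)

    def fit(self, X, y, X_val=None, y_val=None):
        """Train on (image, mask) pairs; a tail split provides validation.

        If no explicit validation set is given, the last ``val_fraction`` of
        the samples (after a seeded shuffle) is held out — callers wanting a
        leakage-safe split by subject should pass ``X_val/y_val`` explicitly.
        """
        X = list(X)
        y = list(y)
        if len(X) == 0:
            raise InvalidInputError("empty training set")
        if len(X) != len(y):
            raise InvalidInputError("images and masks differ in length")
        if len(X) < 2:
            raise InvalidInputError("need at least 2 samples")
        config = self._config()
        rng = np.random.default_rng(config.seed)
        if X_val is None:
            order = rng.permutation(len(X))
            n_val = max(1, int(round(self.val_fraction * len(X))))
            val_idx, tr_idx = order[:n_val], order[n_val:]
            X_val = [X[i] for i in val_idx]
            y_val = [y[i] for i in val_idx]
            X = [X[i] for i in tr_idx]
            y = [y[i] for i in tr_idx]

        model = build_network(config)
        xb_all = _to_batch(X)
        yb_all = np.stack([np.asarray(m, dtype=np.float32) for m in y])
        xv = _to_batch(X_val)
        yv = [np.asarray(m, dtype=bool) for m in y_val]
        opt = Adam(model.parameters(), lr=config.learning_rate)
        history = TrainHistory()
        n = len(X)
        bs = config.batch_size
        for _ in range(config.epochs):
            order = rng.permutation(n)
            dices = []
            for start in range(0, n, bs):
                idx = order[start:start + bs]
                xb, yb = xb_all[idx], yb_all[idx]
                logits = model.forward(xb, train=True)
                s = logits[:, 1] - logits[:, 0]
                p = sigmoid(s)
                _, dp = _loss_and_grad(p, yb, config.loss)
                ds = (dp * p * (1.0 - p)).astype(np.float32)
                dlogits = np.stack([-ds, ds], axis=1)
                model.backward(dlogits)
                opt.step()
                for bi in range(len(idx)):
                    dices.append(_safe_dice(p[bi] > 0.5, yb[bi] > 0.5))
            val = [
                _safe_dice(pm, gm)
                for pm, gm in zip(self._predict_batched(model, xv), yv)
            ]
            history.train_dice.append(float(np.mean(dices)))
            history.val_dice.append(float(np.mean(val)))
        self.model_ = model
        self.history_ = history
        return self

    @staticmethod
    def _predict_batched(model: UNet, xb: np.ndarray, bs: int = 8):
        masks = []
        for start in range(0, len(xb), bs):
            p = model.predict_proba(xb[start:start + bs])
            masks.extend(list(p > 0.5))
        return masks

    def predict(self, X) -> np.ndarray:
        """Dense binary masks for a sequence of images."""
        xb = _to_batch(list(X))
        return np.stack(self._predict_batched(self.model_, xb))

    def predict_proba(self, X) -> np.ndarray:
        return self.model_.predict_proba(_to_batch(list(X)))

    def score(self, X, y) -> float:
        """Mean Dice over the given samples."""
        preds = self.predict(X)
        return float(np.mean([_safe_dice(p, np.asarray(m, dtype=bool))
                              for p, m in zip(preds, y)]))


def train(model: UNet, dataset: Sequence[tuple], config: NetworkConfig):
    """Functional training entry: (model, dataset of (image, mask)) -> history.

    The dataset is split 80:20 (seeded shuffle) into disjoint train and
    validation parts. Returns the trained model and its history.
    """
    if len(dataset) == 0:
        raise InvalidInputError("empty dataset")
    est = UNetSegmenter(depth=config.depth, base_channels=config.base_channels,
                        input_size=config.input_size, epochs=config.epochs,
                        batch_size=config.batch_size,
                        learning_rate=config.learning_rate, loss=config.loss,
                        seed=config.seed, encoder_init=config.encoder_init)
    est.fit([d[0] for d in dataset], [d[1] for d in dataset])
    model.__dict__.update(est.model_.__dict__)  # hand the weights back
    return model, est.history_


def predict_mask(model, schematic, spmap: SuperpixelMap | None = None,
                 mode: Literal["dense", "centered"] = "dense") -> PredictionMask:
    """Segment one slice, densely or via superpixel-centered classification.

    ``centered`` mode reads the class decision only at each superpixel's
    center pixel and broadcasts it to the whole superpixel, so the output is
    a union of whole superpixels of ``spmap``.
    """
    net = model.model_ if isinstance(model, UNetSegmenter) else model
    values = schematic.values if isinstance(schematic, SchematicImage) else np.asarray(schematic)
    if spmap is None and isinstance(schematic, SchematicImage):
        spmap = schematic.source_map
    if mode == "centered":
        if spmap is None:
            raise InvalidInputError("centered mode needs a superpixel map")
        if values.shape != spmap.labels.shape:
            raise InvalidInputError("schematic and superpixel map shapes must match")
    p = net.predict_proba(_to_batch([values]))[0]
    if mode == "dense":
        return PredictionMask(mask=p > 0.5, mode="dense", source_map=spmap)
    center_cls = p[spmap.centers[:, 0], spmap.centers[:, 1]] > 0.5
    return PredictionMask(mask=center_cls[spmap.labels], mode="centered",
                          source_map=spmap)


def evaluate_batch(model, samples, mode: Literal["dense", "centered"] = "dense"):
    """Per-sample DSC and the mean over a test set.

    ``samples``: iterables of ``(image, gt_mask)`` or ``(image, gt_mask,
    superpixel_map)``; centered mode requires the map. Returns
    ``(mean_dsc, rows)`` where rows are dicts with ``sample`` and ``dsc``.
    """
    rows = []
    for i, item in enumerate(samples):
        image, gt = item[0], item[1]
        spmap = item[2] if len(item) > 2 else None
        pred = predict_mask(model, image, spmap, mode=mode)
        rows.append({"sample": i, "dsc": _safe_dice(pred.mask, np.asarray(gt, bool))})
    if not rows:
        raise InvalidInputError("empty test set")
    return float(np.mean([r["dsc"] for r in rows])), rows
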