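"""A U-Net encoder-decoder for 256x256 single-channel binary segmentation.

The architecture: four encoder blocks of paired 3x3 same-padded ReLU
convolutions at widths 64/128/256/512, each followed by 2x2 max pooling,
with 0.5 dropout after the 512-level convolutions; a 1024-wide two-conv
bottleneck with a second 0.5 dropout; four decoder stages of non-learned
2x2 upsampling followed by a 2x2 ReLU "up-convolution" at the stage
width, concatenation with the matching encoder map (the dropout-modified
map at the 512 level), and two 3x3 ReLU convolutions; finally a 3x3
two-filter ReLU convolution and a 1x1 sigmoid output.  With the default
configuration this network has exactly 31,031,685 trainable parameters.

Training minimizes mean binary cross-entropy with Adam, streaming
mini-batches so memory stays bounded in the dataset size.  At inference
the continuous sigmoid output is cut at 0.7 (>= rule) to produce the
binary mask.  Everything runs on NumPy; dropout is active only during
training, so inference is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from sklearn.base import BaseEstimator

from ..io import BinaryMask, QPIImage, normalize_to_uint8, pad_to_canvas, unpad
from .layers import Adam, Conv2D, Dropout, MaxPool2x2, UpSample2x2, bce_with_logits, sigmoid


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters; the defaults are the full-scale model."""

    canvas: int = 256
    in_channels: int = 1
    encoder_widths: tuple[int, int, int, int] = (64, 128, 256, 512)
    bottleneck_width: int = 1024
    dropout_rate: float = 0.5
    threshold: float = 0.7
    kernel: int = 3
    upsample: int = 2

    def __post_init__(self) -> None:
        if self.canvas % 16 != 0:
            raise ValueError(
                f"canvas must be divisible by 16 (four 2x2 poolings), got {self.canvas}"
            )
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must lie in [0, 1)")


def reduced_config(canvas: int = 64) -> UNetConfig:
    """Widths/8 desk-scale configuration for CPU-sized experiments."""
    return UNetConfig(
        canvas=canvas, encoder_widths=(8, 16, 32, 64), bottleneck_width=128
    )


@dataclass
class TrainRecord:
    """Per-epoch binary cross-entropy history plus the run's knobs."""

    epochs: int
    losses: list[float]
    batch_size: int
    seed: int
    learning_rate: float

    def __post_init__(self) -> None:
        if len(self.losses) != self.epochs:
            raise ValueError("loss history length must equal epochs run")
        if any(l < 0 for l in self.losses):
            raise ValueError("binary cross-entropy is non-negative")


class UNetModel:
    """The layer graph, weights, and forward/backward passes."""

    def __init__(self, config: UNetConfig | None = None, seed: int = 0):
        self.config = config or UNetConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        w1, w2, w3, w4 = cfg.encoder_widths
        wb = cfg.bottleneck_width
        k = cfg.kernel

        def conv(cin, cout, kernel=k, relu=True):
            return Conv2D(cin, cout, kernel, rng, relu=relu)

        self.enc = [
            [conv(cfg.in_channels, w1), conv(w1, w1)],
            [conv(w1, w2), conv(w2, w2)],
            [conv(w2, w3), conv(w3, w3)],
            [conv(w3, w4), conv(w4, w4)],
        ]
        self.pools = [MaxPool2x2() for _ in range(4)]
        self.drop_enc = Dropout(cfg.dropout_rate)
        self.bott = [conv(w4, wb), conv(wb, wb)]
        self.drop_bott = Dropout(cfg.dropout_rate)
        self.ups = [UpSample2x2() for _ in range(4)]
        # decoder stages from deepest (width w4) to shallowest (width w1)
        self.upconvs = [
            conv(wb, w4, kernel=cfg.upsample),
            conv(w4, w3, kernel=cfg.upsample),
            conv(w3, w2, kernel=cfg.upsample),
            conv(w2, w1, kernel=cfg.upsample),
        ]
        self.dec = [
            [conv(2 * w4, w4), conv(w4, w4)],
            [conv(2 * w3, w3), conv(w3, w3)],
            [conv(2 * w2, w2), conv(w2, w2)],
            [conv(2 * w1, w1), conv(w1, w1)],
        ]
        self.head = conv(w1, 2)
        self.out = conv(2, 1, kernel=1, relu=False)  # logits; sigmoid applied outside

    # -- structure ---------------------------------------------------------

    def conv_layers(self) -> list[Conv2D]:
        layers: list[Conv2D] = []
        for block in self.enc:
            layers.extend(block)
        layers.extend(self.bott)
        for up, block in zip(self.upconvs, self.dec):
            layers.append(up)
            layers.extend(block)
        layers.append(self.head)
        layers.append(self.out)
        return layers

    @property
    def trainable_parameter_count(self) -> int:
        return sum(layer.n_params for layer in self.conv_layers())

    # -- passes ------------------------------------------------------------

    def forward_logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        skips = []
        for i, (block, pool) in enumerate(zip(self.enc, self.pools)):
            for conv in block:
                x = conv.forward(x, training)
            if i == 3:
                x = self.drop_enc.forward(x, training)
            skips.append(x)
            x = pool.forward(x, training)
        for conv in self.bott:
            x = conv.forward(x, training)
        x = self.drop_bott.forward(x, training)
        self._concat_widths = []
        for up, upconv, block, skip in zip(
            self.ups, self.upconvs, self.dec, reversed(skips)
        ):
            x = upconv.forward(up.forward(x, training), training)
            self._concat_widths.append(x.shape[-1])
            x = np.concatenate([x, skip], axis=-1)
            for conv in block:
                x = conv.forward(x, training)
        x = self.head.forward(x, training)
        return self.out.forward(x, training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logits(x, training=False))

    def backward(self, grad: np.ndarray) -> None:
        grad = self.head.backward(self.out.backward(grad))
        skip_grads = [None] * 4
        for stage in range(3, -1, -1):
            for conv in reversed(self.dec[stage]):
                grad = conv.backward(grad)
            w = self._concat_widths[stage]
            grad, skip_grad = grad[..., :w], grad[..., w:]
            skip_grads[3 - stage] = skip_grad  # skip index in encoder order
            grad = self.ups[stage].backward(self.upconvs[stage].backward(grad))
        grad = self.drop_bott.backward(grad)
        for conv in reversed(self.bott):
            grad = conv.backward(grad)
        for i in range(3, -1, -1):
            grad = self.pools[i].backward(grad)
            grad = grad + skip_grads[i]
            if i == 3:
                grad = self.drop_enc.backward(grad)
            for conv in reversed(self.enc[i]):
                grad = conv.backward(grad)

    # -- persistence -------------------------------------------------------

    def save_weights(self, path: str) -> None:
        arrays = {}
        for i, layer in enumerate(self.conv_layers()):
            arrays[f"W{i}"] = layer.W
            arrays[f"b{i}"] = layer.b
        np.savez(path, **arrays)
        with open(str(path) + ".yaml", "w") as fh:
            yaml.safe_dump(
                {
                    "canvas": self.config.canvas,
                    "encoder_widths": list(self.config.encoder_widths),
                    "bottleneck_width": self.config.bottleneck_width,
                    "dropout_rate": self.config.dropout_rate,
                    "threshold": self.config.threshold,
                },
                fh,
            )

    @classmethod
    def load_weights(cls, path: str) -> "UNetModel":
        with open(str(path) + ".yaml") as fh:
            meta = yaml.safe_load(fh)
        cfg = UNetConfig(
            canvas=meta["canvas"],
            encoder_widths=tuple(meta["encoder_widths"]),
            bottleneck_width=meta["bottleneck_width"],
            dropout_rate=meta["dropout_rate"],
            threshold=meta["threshold"],
        )
        model = cls(cfg)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path))
        for i, layer in enumerate(model.conv_layers()):
            layer.W = data[f"W{i}"]
            layer.b = data[f"b{i}"]
        return model


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNetModel:
    """Construct the network with freshly initialized weights."""
    return UNetModel(config=config, seed=seed)


def count_trainable_parameters(model: UNetModel) -> int:
    """Sum of (kh*kw*in_ch + 1)*out_ch over every convolution."""
    return model.trainable_parameter_count


def train_unet(
    model: UNetModel,
    images: list[np.ndarray],
    masks: list[np.ndarray],
    epochs: int,
    batch_size: int = 2,
    seed: int = 0,
    learning_rate: float = 1e-3,
) -> tuple[UNetModel, TrainRecord]:
    """Fit the network with Adam on mean binary cross-entropy.

    ``images`` are canvas x canvas arrays already scaled to [0, 1];
    ``masks`` are canvas x canvas {0, 1} arrays.  Batches stream through
    the model so peak memory does not grow with the dataset.  Dropout
    masks and the per-epoch shuffle derive from ``seed``, making two runs
    with the same seed bit-identical.
    """
    if len(images) == 0:
        raise ValueError("training requires at least one image")
    if len(images) != len(masks):
        raise ValueError("images and masks differ in count")
    c = model.config.canvas
    for i, (im, mk) in enumerate(zip(images, masks)):
        if np.shape(im) != (c, c) or np.shape(mk) != (c, c):
            raise ValueError(
                f"item {i}: expected {c}x{c} canvas arrays, got "
                f"{np.shape(im)} / {np.shape(mk)}"
            )
    X = np.stack([np.asarray(im, dtype=np.float32) for im in images])[..., None]
    Y = np.stack([np.asarray(mk, dtype=np.float32) for mk in masks])[..., None]

    rng = np.random.default_rng(seed)
    model.drop_enc.reseed(np.random.default_rng(rng.integers(2**31)))
    model.drop_bott.reseed(np.random.default_rng(rng.integers(2**31)))
    optimizer = Adam(model.conv_layers(), lr=learning_rate)

    losses: list[float] = []
    n = X.shape[0]
    for _epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward_logits(X[idx], training=True)
            loss, grad = bce_with_logits(logits, Y[idx])
            model.backward(grad)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / n_batches)
    record = TrainRecord(
        epochs=epochs, losses=losses, batch_size=batch_size, seed=seed,
        learning_rate=learning_rate,
    )
    return model, record


def preprocess_image(image: QPIImage, canvas: int):
    """Normalize to 8-bit, scale to [0, 1], centre-pad to the canvas."""
    norm = normalize_to_uint8(image)
    padded, record = pad_to_canvas(norm.pixels, canvas=canvas)
    return padded.astype(np.float32) / 255.0, record


def segment(model: UNetModel, image: QPIImage) -> tuple[np.ndarray, BinaryMask]:
    """Segment one phase image.

    The image is normalized, padded to the canvas, forward-passed, and the
    probability map cut at the configured threshold (>= rule); both the
    probability map and the mask are un-padded back to the original size.
    """
    canvas = model.config.canvas
    scaled, record = preprocess_image(image, canvas)
    prob = model.predict_proba(scaled[None, ..., None])[0, :, :, 0]
    prob = unpad(prob, record)
    mask = (prob >= model.config.threshold).astype(np.uint8)
    return prob, BinaryMask(pixels=mask)


class UNetSegmenter(BaseEstimator):
    """sklearn-style wrapper: fit on (image, mask) pairs, predict masks.

    Parameters mirror :class:`UNetConfig` plus the training knobs.  The
    defaults build the full-scale 31M-parameter network; pass
    ``encoder_widths=(8, 16, 32, 64), bottleneck_width=128, canvas=64``
    for the desk-scale configuration.
    """

    def __init__(self, canvas: int = 256,
                 encoder_widths: tuple[int, int, int, int] = (64, 128, 256, 512),
                 bottleneck_width: int = 1024, dropout_rate: float = 0.5,
                 threshold: float = 0.7, epochs: int = 30, batch_size: int = 2,
                 learning_rate: float = 1e-3, seed: int = 0):
        self.canvas = canvas
        self.encoder_widths = encoder_widths
        self.bottleneck_width = bottleneck_width
        self.dropout_rate = dropout_rate
        self.threshold = threshold
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed

    def _config(self) -> UNetConfig:
        return UNetConfig(
            canvas=self.canvas,
            encoder_widths=tuple(self.encoder_widths),
            bottleneck_width=self.bottleneck_width,
            dropout_rate=self.dropout_rate,
            threshold=self.threshold,
        )

    def fit(self, images: list[QPIImage], masks: list[BinaryMask]):
        cfg = self._config()
        prepared, targets = [], []
        for img, msk in zip(images, masks):
            scaled, _ = preprocess_image(img, cfg.canvas)
            padded_mask, _ = pad_to_canvas(msk.pixels, canvas=cfg.canvas)
            prepared.append(scaled)
            targets.append(padded_mask)
        self.model_ = build_unet(cfg, seed=self.seed)
        self.model_, self.train_record_ = train_unet(
            self.model_, prepared, targets, epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed,
            learning_rate=self.learning_rate,
        )
        return self

    def predict(self, images: list[QPIImage]) -> list[BinaryMask]:
        return [segment(self.model_, img)[1] for img in images]

    def predict_proba(self, images: list[QPIImage]) -> list[np.ndarray]:
        return [segment(self.model_, img)[0] for img in images]
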