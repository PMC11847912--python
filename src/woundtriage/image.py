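"""Wound-image preprocessing, augmentation, CNN classifier and Grad-CAM.

Images are colour photographs of surgical wounds, rescaled to a fixed
square size (study standard 256x256). Training-time augmentation uses
similarity transforms only — translation, rotation, isotropic scaling,
flips — never shear or elastic warps, so wound shape is preserved.

The default classifier is a small four-block convolutional network
trained from scratch (conv3x3 + ReLU + 2x2 max-pool per block, global
average pooling, sigmoid output) with the study's training recipe:
RMSprop, batch size 10, 30 epochs, early stopping on the training
binary cross-entropy evaluated every ten steps with a patience of ten.
A checkpoint of the same architecture can be supplied and fine-tuned
with the early blocks frozen (the transfer-learning configuration);
no weights are bundled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _engine as eng
from .tabular import _validate_binary

DEFAULT_IMAGE_SIZE = 256


@dataclass
class ImageBatch:
    """A preprocessed image batch: (n, s, s, 3) floats in [0, 1]."""

    pixels: np.ndarray
    labels: np.ndarray | None = None
    augmentation_spec: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 4 or px.shape[3] != 3 or px.shape[1] != px.shape[2]:
            raise ValueError(f"pixels must be (n, s, s, 3), got {px.shape}")
        self.pixels = px


@dataclass
class ActivationHeatmap:
    """Grad-CAM output: non-negative weights on the image grid, max 1."""

    weights: np.ndarray  # (s, s) in [0, 1]
    overlay: np.ndarray  # (s, s, 3) RGB composite in [0, 1]


def _load_rgb(path: str | Path) -> np.ndarray:
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                warnings.warn(f"grayscale image {path}: replicating to 3 channels")
            im = im.convert("RGB")
            return np.asarray(im, dtype=float) / 255.0
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc


def _resize_center_crop(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear-resize the short side to ``size`` then centre-crop."""
    h, w = img.shape[:2]
    scale = size / min(h, w)
    nh, nw = max(size, int(round(h * scale))), max(size, int(round(w * scale)))
    pil = Image.fromarray(np.clip(np.rint(img * 255.0), 0, 255).astype(np.uint8))
    pil = pil.resize((nw, nh), Image.BILINEAR)
    arr = np.asarray(pil, dtype=float) / 255.0
    top, left = (nh - size) // 2, (nw - size) // 2
    return arr[top : top + size, left : left + size]


def preprocess_images(
    inputs,
    labels=None,
    target_size: int = DEFAULT_IMAGE_SIZE,
) -> ImageBatch:
    """Load and standardise images into an :class:`ImageBatch`.

    ``inputs`` may be file paths (PNG/JPEG) or already-decoded arrays
    (``(h, w, 3)`` floats in [0, 1]). Aspect ratio is handled by
    resizing the short side then centre-cropping.
    """
    arrays = []
    for item in inputs:
        img = _load_rgb(item) if isinstance(item, (str, Path)) else np.asarray(item, dtype=float)
        if img.ndim == 2:
            warnings.warn("grayscale array input: replicating to 3 channels")
            img = np.repeat(img[..., None], 3, axis=2)
        if img.shape[:2] != (target_size, target_size):
            img = _resize_center_crop(img, target_size)
        arrays.append(np.clip(img, 0.0, 1.0))
    pixels = np.stack(arrays) if arrays else np.empty((0, target_size, target_size, 3))
    return ImageBatch(pixels=pixels, labels=None if labels is None else np.asarray(labels))


DEFAULT_AUGMENTATION = {
    "max_translation": 0.08,  # fraction of image size
    "max_rotation_deg": 20.0,
    "scale_range": (0.9, 1.1),
    "flip": True,
}


def augment(pixels: np.ndarray, rng: np.random.Generator, spec: dict | None = None) -> np.ndarray:
    """Random similarity transform + flips per image; labels are untouched.

    Only rigid/similarity transforms are used (rotation, translation,
    isotropic scale, horizontal/vertical flip) — no shear or elastic
    deformation, preserving wound morphology.
    """
    spec = {**DEFAULT_AUGMENTATION, **(spec or {})}
    out = np.empty_like(pixels)
    n, s = pixels.shape[0], pixels.shape[1]
    c = (s - 1) / 2.0
    for i in range(n):
        img = pixels[i]
        if spec["flip"]:
            if rng.random() < 0.5:
                img = img[:, ::-1]
            if rng.random() < 0.5:
                img = img[::-1, :]
        theta = np.deg2rad(rng.uniform(-spec["max_rotation_deg"], spec["max_rotation_deg"]))
        zoom = rng.uniform(*spec["scale_range"])
        shift = rng.uniform(-spec["max_translation"], spec["max_translation"], size=2) * s
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]) / zoom
        offset = np.array([c, c]) - rot @ np.array([c, c]) - shift
        for ch in range(3):
            out[i, :, :, ch] = ndimage.affine_transform(
                img[:, :, ch], rot, offset=offset, order=1, mode="nearest"
            )
    return out


class WoundCnnClassifier(BaseEstimator, ClassifierMixin):
    """Small convolutional classifier for wound images.

    Parameters
    ----------
    channels:
        Output channels of the four conv blocks.
    epochs, batch_size, learning_rate:
        Training schedule (RMSprop); defaults follow the study recipe
        (30 epochs, batches of 10).
    eval_every, patience:
        Early stopping: training loss is evaluated every ``eval_every``
        optimisation steps and training stops after ``patience``
        evaluations without improvement, restoring the best weights.
    augmentation:
        ``None`` uses :data:`DEFAULT_AUGMENTATION`, ``False`` disables
        training-time augmentation, a dict overrides individual fields.
        Never applied at prediction time.
    pretrained_weights:
        Optional path to a saved checkpoint of the same architecture to
        fine-tune from, with blocks before ``unfreeze_from_block``
        frozen (the transfer-learning configuration).
    """

    def __init__(
        self,
        channels: tuple[int, ...] = (12, 24, 32, 32),
        epochs: int = 30,
        batch_size: int = 10,
        learning_rate: float = 1e-3,
        eval_every: int = 10,
        patience: int = 10,
        class_weight: str | None = "balanced",
        augmentation: dict | None = None,
        pretrained_weights: str | None = None,
        unfreeze_from_block: int = 3,
        random_state: int = 0,
    ):
        self.channels = channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.eval_every = eval_every
        self.patience = patience
        self.class_weight = class_weight
        self.augmentation = augmentation
        self.pretrained_weights = pretrained_weights
        self.unfreeze_from_block = unfreeze_from_block
        self.random_state = random_state

    def _build(self, rng: np.random.Generator) -> eng.Sequential:
        layers: list[eng.Layer] = []
        c_in = 3
        for c_out in self.channels:
            layers += [eng.Conv2D(c_in, c_out, rng), eng.ReLU(), eng.MaxPool2()]
            c_in = c_out
        layers += [eng.GlobalAvgPool(), eng.Dense(c_in, 1, rng)]
        return eng.Sequential(layers)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be (n, s, s, 3), got {X.shape}")
        if X.shape[1] % 2 ** len(self.channels) != 0:
            raise ValueError("image size must be divisible by the pooling pyramid")
        y = _validate_binary(y)
        self.classes_ = np.array([0, 1])
        self.image_size_ = X.shape[1]
        rng = np.random.default_rng(np.random.SeedSequence([int(self.random_state), 0xC44]))
        self._net = self._build(rng)
        frozen: set[int] = set()
        if self.pretrained_weights is not None:
            with np.load(self.pretrained_weights) as data:
                self._net.set_weights([data[f"w{i}"] for i in range(len(self._net.params()))])
            # freeze conv blocks below the unfreezing point (2 params per conv)
            frozen = set(range(2 * (self.unfreeze_from_block - 1)))
        weights = None
        if self.class_weight == "balanced":
            p = y.mean()
            weights = np.where(y == 1, 0.5 / p, 0.5 / (1 - p))
        # augmentation: None -> defaults, False -> disabled, dict -> override
        if self.augmentation is False:
            augment_fn = None
        else:
            spec = self.augmentation if isinstance(self.augmentation, dict) else None
            augment_fn = lambda batch, r: augment(batch, r, spec)  # noqa: E731

        params = self._net.params()
        keep = [i for i in range(len(params)) if i not in frozen]
        if frozen:
            net = self._net

            class _Masked:
                def __init__(self, opt):
                    self.opt = opt

                def step(self, ps, gs):
                    self.opt.step([ps[i] for i in keep], [gs[i] for i in keep])

            optimizer = _Masked(eng.RMSprop(lr=self.learning_rate))
        else:
            optimizer = eng.RMSprop(lr=self.learning_rate)
        self.training_meta_ = eng.train_network(
            self._net,
            X,
            y,
            optimizer=optimizer,
            epochs=self.epochs,
            batch_size=self.batch_size,
            rng=rng,
            sample_weight=weights,
            eval_every=self.eval_every,
            patience=self.patience,
            augment_fn=augment_fn,
        )
        return self

    def _forward_logits(self, X: np.ndarray, chunk: int = 32) -> np.ndarray:
        logits = [
            self._net.forward(X[i : i + chunk]).ravel() for i in range(0, len(X), chunk)
        ]
        return np.concatenate(logits) if logits else np.empty(0)

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 4 or X.shape[1] != self.image_size_:
            raise ValueError(f"X must be (n, {self.image_size_}, {self.image_size_}, 3)")
        p = eng.sigmoid(self._forward_logits(X))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def class_activation_map(self, image: np.ndarray) -> ActivationHeatmap:
        """Gradient-weighted class-activation map for one image.

        Backpropagates the risk logit to the post-activation feature map of
        the last convolutional block, weights each channel by its average
        gradient, removes the spatially constant component (it shifts the
        logit uniformly and carries no localisation information — with a
        single sigmoid output it would otherwise swamp the map), rectifies,
        upsamples to the input grid and normalises to a maximum of 1.
        """
        check_is_fitted(self, "classes_")
        conv_idx = [i for i, lay in enumerate(self._net.layers) if isinstance(lay, eng.Conv2D)]
        if not conv_idx:
            raise ValueError("model has no convolutional layer; cannot compute a CAM")
        relu_idx = conv_idx[-1] + 1  # ReLU directly after the last conv

        x = np.asarray(image, dtype=float)[None]
        out = x
        feature = None
        for i, lay in enumerate(self._net.layers):
            out = lay.forward(out)
            if i == relu_idx:
                feature = out
        grad = self._net.backward_to(relu_idx, np.ones((1, 1)))
        alpha = grad[0].mean(axis=(0, 1))
        contrib = (feature[0] * alpha).sum(axis=-1)
        cam = np.maximum(contrib - contrib.mean(), 0.0)
        zoom = self.image_size_ / cam.shape[0]
        cam = ndimage.zoom(cam, zoom, order=1)
        m = cam.max()
        if m > 0:
            cam = cam / m
        overlay = np.clip(0.5 * x[0] + 0.5 * np.stack([cam, 0.1 * cam, 1.0 - cam], axis=-1), 0, 1)
        return ActivationHeatmap(weights=cam, overlay=overlay)

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        check_is_fitted(self, "classes_")
        path = Path(path)
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in self.get_params().items()},
            "image_size": int(self.image_size_),
        }
        arrays = {f"w{i}": w for i, w in enumerate(self._net.get_weights())}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "WoundCnnClassifier":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            params = meta["params"]
            params["channels"] = tuple(params["channels"])
            model = cls(**params)
            model.classes_ = np.array([0, 1])
            model.image_size_ = meta["image_size"]
            model._net = model._build(np.random.default_rng(0))
            model._net.set_weights([data[f"w{i}"] for i in range(len(model._net.params()))])
        model.training_meta_ = {"loaded": True}
        return model


def fit_cnn(X, y, seed: int = 0, **kwargs) -> WoundCnnClassifier:
    """Fit the wound-image CNN (thin estimator wrapper)."""
    return WoundCnnClassifier(random_state=seed, **kwargs).fit(X, y)


def cam(model: WoundCnnClassifier, image: np.ndarray) -> ActivationHeatmap:
    """Class-activation heatmap of ``model`` on one preprocessed image."""
    return model.class_activation_map(image)
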