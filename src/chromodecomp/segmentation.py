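"""Skin segmentation: a lightweight encoder-decoder producing binary masks.

The forward model only applies to skin, so non-skin areas (background,
eyes, nostrils, lips) must be excluded before decomposition.  A
reduced-channel U-Net predicts a per-pixel skin probability at a fixed
working resolution (default 640x480); masks are bilinearly resized and
re-thresholded for other sizes.  Training minimizes pixelwise binary
cross-entropy on labeled (image, mask) pairs — here, synthetic scenes with
exact masks.  An external mask can always be supplied instead, so the
pipeline runs without a trained segmenter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize

from .errors import DataError, ModelStateError, ShapeError
from .imaging import LinearImage
from .maps import SkinMask, iou  # re-exported: iou lives with the mask type
from .nn import Adam, UNet, cosine_annealing_lr, sigmoid
from .nn.unet import UNetConfig

__all__ = ["SegmentationModel", "SegTrainConfig", "segment", "train_segmentation", "iou"]


@dataclass
class SegTrainConfig:
    epochs: int = 40
    batch_size: int = 4
    lr: float = 2e-3
    weight_decay: float = 1e-5
    lr_min: float = 1e-5
    seed: int = 0


class SegmentationModel:
    """Reduced U-Net (logit head) plus its working resolution."""

    def __init__(
        self,
        working_size: tuple[int, int] = (480, 640),   # (H, W), divisible by 2^depth
        base_width: int = 8,
        depth: int = 3,
        seed: int = 0,
    ):
        self.config = UNetConfig(
            in_channels=3, out_channels=1, base_width=base_width, depth=depth,
            final_sigmoid=False,
        )
        div = 2**depth
        if working_size[0] % div or working_size[1] % div:
            raise ShapeError(f"working size must be divisible by {div}")
        self.working_size = working_size
        self.unet = UNet(self.config, np.random.default_rng(seed))
        self.seed = seed
        self.trained = False

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.unet.params)
        meta = {"unet": asdict(self.config), "working_size": list(self.working_size),
                "seed": self.seed, "trained": self.trained}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SegmentationModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(working_size=tuple(meta["working_size"]),
                    base_width=meta["unet"]["base_width"],
                    depth=meta["unet"]["depth"], seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as data:
            model.unet.load_state_dict(dict(data))
        model.trained = meta["trained"]
        return model


def _to_array(image) -> np.ndarray:
    if isinstance(image, LinearImage):
        return image.pixels
    arr = np.asarray(image, float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError("segmentation expects a (H, W, 3) image")
    return arr


def _forward_prob(model: SegmentationModel, batch_hw3: np.ndarray, want_cache=False):
    x = batch_hw3.transpose(0, 3, 1, 2).astype(np.float32)
    z, cache = model.unet.forward(x, want_cache=want_cache)
    return z[:, 0], cache


def segment(image, model: SegmentationModel, threshold: float = 0.5) -> SkinMask:
    """Predict a binary skin mask at the input resolution."""
    if not model.trained:
        raise ModelStateError("segmentation model has not been trained")
    arr = _to_array(image)
    h, w = arr.shape[:2]
    work = resize(arr, model.working_size, order=1, anti_aliasing=False)
    z, _ = _forward_prob(model, work[None])
    prob = sigmoid(z[0].astype(float))
    if (h, w) != model.working_size:
        prob = resize(prob, (h, w), order=1, anti_aliasing=False)
    return SkinMask(prob > threshold)


def _bce_and_grad(z: np.ndarray, t: np.ndarray):
    """Stable pixelwise binary cross-entropy from logits; returns loss, dL/dz."""
    n = z.size
    loss = float(np.mean(np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - t) / n
    return loss, dz


def train_segmentation(
    images: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    config: SegTrainConfig = SegTrainConfig(),
    model: Optional[SegmentationModel] = None,
    working_size: tuple[int, int] = (480, 640),
    verbose: bool = False,
) -> tuple[SegmentationModel, list[dict]]:
    """Fit the segmenter on (image, mask) pairs; returns (model, loss log)."""
    if len(images) == 0:
        raise DataError("empty segmentation dataset")
    if len(images) != len(masks):
        raise ShapeError("need one mask per image")
    model = model or SegmentationModel(working_size=working_size, seed=config.seed)
    xs = np.stack([
        resize(_to_array(im), model.working_size, order=1, anti_aliasing=False)
        for im in images
    ])
    ts = np.stack([
        resize(np.asarray(m, float), model.working_size, order=0) > 0.5 for m in masks
    ]).astype(np.float32)
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.unet.params, lr=config.lr, weight_decay=config.weight_decay)
    history = []
    n = len(xs)
    for epoch in range(config.epochs):
        optimizer.lr = cosine_annealing_lr(config.lr, epoch, config.epochs, config.lr_min)
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, config.batch_size):
            idx = order[s : s + config.batch_size]
            z, cache = _forward_prob(model, xs[idx], want_cache=True)
            loss, dz = _bce_and_grad(z.astype(float), ts[idx])
            grads = model.unet.backward(cache, dz[:, None].astype(np.float32))
            optimizer.step(grads)
            losses.append(loss)
        history.append({"epoch": epoch, "bce": float(np.mean(losses)), "lr": optimizer.lr})
        if verbose:
            print(f"epoch {epoch}: bce={history[-1]['bce']:.5f}")
    model.trained = True
    return model, history
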