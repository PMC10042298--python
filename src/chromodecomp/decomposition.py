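"""Self-supervised chromophore decomposition.

A four-head U-Net maps a linear-RGB skin patch to melanin, hemoglobin,
shading and specular maps.  No ground truth is used: training pushes the
predicted maps through the forward renderer and minimizes the masked mean
squared error between the reconstruction and the input patch, so the
network learns the inverse of the light-skin-camera model.

Network outputs are sigmoid-bounded in [0, 1] and mapped affinely onto the
physical ranges (melanin 0.013-0.43, hemoglobin 0.02-0.07, shading 0-2,
specular 0-1), which keeps every prediction inside the physiological box
by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DataError,
    ModelStateError,
    NoSignalError,
    ShapeError,
    SizeError,
)
from .maps import ChromophoreMaps, SHADING_RANGE, SPECULAR_RANGE
from .nn import Adam, UNet, cosine_annealing_lr
from .nn.unet import UNetConfig
from .optics import HEMOGLOBIN_RANGE, MELANIN_RANGE
from .render import ForwardRenderer

#: affine ranges for the four heads, in output-channel order
HEAD_RANGES = (MELANIN_RANGE, HEMOGLOBIN_RANGE, SHADING_RANGE, SPECULAR_RANGE)


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0, cap: float = 100.0,
         mask: Optional[np.ndarray] = None) -> float:
    """10 log10(peak^2 / MSE) in dB, capped when the images are identical."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ShapeError(f"image shapes differ: {a.shape} vs {b.shape}")
    if mask is not None:
        sel = np.asarray(mask, bool)
        a, b = a[sel], b[sel]
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return cap
    return min(cap, 10.0 * math.log10(peak**2 / mse))


@dataclass
class TrainConfig:
    """Hyperparameters of the self-supervised run.

    The defaults are the short-schedule configuration used throughout the
    package: small crops and batches maximize the number of optimizer
    updates per unit compute, the loss is compared in gamma-encoded units,
    and the priors regularize the decomposition (smooth tissue fields and
    shading, near-zero specular under cross-polarization, and a weak pull
    toward the renderer's analytic pixelwise inverse, which pins the
    chromophore mixture that reconstruction error alone leaves free).
    """

    epochs: int = 60
    batch_size: int = 4
    lr: float = 1e-3
    weight_decay: float = 1e-5
    cosine_period: Optional[int] = None   # defaults to `epochs`
    lr_min: float = 1e-5
    crop: Optional[int] = 64              # random square crop during training
    flip: bool = True
    rotate: bool = True                   # random 90-degree rotations
    scale: bool = False                   # random rescale before cropping
    loss_space: str = "srgb"              # "srgb" or "linear" comparison space
    shading_smoothness: float = 0.3       # |grad|^2 prior on the shading head
    chromophore_smoothness: float = 3.0   # |grad|^2 prior on the mel/hb heads
    specular_weight: float = 0.01         # l2 prior on the specular head
    physics_anchor: float = 0.3           # pull toward the analytic pixelwise inverse
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.epochs, self.batch_size) < 1 or self.lr <= 0 or self.weight_decay < 0:
            raise ShapeError("rates and sizes must be positive")


class DecompositionModel:
    """U-Net + range mapping; the inference-side object.

    ``input_encode=True`` (default) gamma-encodes the linear patch before it
    enters the network — a feature transform that spreads the dark
    green/blue channels over a wider numeric range.  The public contract is
    unchanged: patches are supplied in working-linear RGB.
    """

    def __init__(self, config: Optional[UNetConfig] = None, seed: int = 0,
                 patch_size: int = 256, input_encode: bool = True,
                 physics_features: bool = True,
                 renderer: Optional[ForwardRenderer] = None):
        if config is None:
            config = UNetConfig(
                in_channels=3 + (3 if physics_features else 0), out_channels=4
            )
        self.config = config
        self.unet = UNet(self.config, np.random.default_rng(seed))
        self.patch_size = patch_size
        self.seed = seed
        self.input_encode = input_encode
        self.physics_features = physics_features
        self.renderer = renderer
        self.trained = False

    def _features(self, linear: np.ndarray) -> np.ndarray:
        """Input featurization of a (..., H, W, 3) linear-RGB array.

        Besides the (optionally gamma-encoded) color channels, the network
        receives the renderer's analytic pixelwise inverse (melanin,
        hemoglobin, shading under a zero-specular assumption) as three
        range-normalized channels, so training refines a physical estimate
        instead of rediscovering the inverse from scratch.
        """
        clipped = np.clip(linear, 0.0, None)
        if self.input_encode:
            from .imaging import GAMMA_EXP, GAMMA_OFFSET
            color = (1 + GAMMA_OFFSET) * clipped ** (1.0 / GAMMA_EXP) - GAMMA_OFFSET
        else:
            color = linear
        if not self.physics_features:
            return color
        if self.renderer is None:
            raise ModelStateError(
                "physics features require a renderer attached to the model"
            )
        mel, hb, sh = self.renderer.pixelwise_inverse(clipped)
        extra = [
            (chan - lo) / (hi - lo)
            for chan, (lo, hi) in zip((mel, hb, sh), HEAD_RANGES)
        ]
        return np.concatenate([color] + [e[..., None] for e in extra], axis=-1)

    # -- range mapping --------------------------------------------------
    @staticmethod
    def maps_from_network(out: np.ndarray) -> list[ChromophoreMaps]:
        """(N, 4, H, W) sigmoid outputs -> per-sample physical maps."""
        result = []
        for sample in out:
            chans = [
                lo + (hi - lo) * sample[k] for k, (lo, hi) in enumerate(HEAD_RANGES)
            ]
            result.append(ChromophoreMaps(*chans))
        return result

    @staticmethod
    def network_from_maps(maps: ChromophoreMaps) -> np.ndarray:
        """Inverse of the affine range mapping, (4, H, W) in [0, 1]."""
        chans = [maps.mel_map, maps.hb_map, maps.shading_map, maps.specular_map]
        return np.stack(
            [(c - lo) / (hi - lo) for c, (lo, hi) in zip(chans, HEAD_RANGES)]
        )

    # -- inference ------------------------------------------------------
    def decompose_patch(self, patch: np.ndarray) -> ChromophoreMaps:
        """Linear-RGB (H, W, 3) patch -> four physical maps.

        The patch must match the model's working patch size.
        """
        patch = np.asarray(patch, float)
        if patch.shape != (self.patch_size, self.patch_size, 3):
            raise SizeError(
                f"expected a {self.patch_size}x{self.patch_size}x3 patch, got {patch.shape}"
            )
        x = np.ascontiguousarray(
            self._features(patch).transpose(2, 0, 1)
        )[None].astype(np.float32)
        out, _ = self.unet.forward(x)
        return self.maps_from_network(out.astype(float))[0]

    # -- persistence ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.unet.params)
        meta = {
            "unet": asdict(self.config),
            "patch_size": self.patch_size,
            "seed": self.seed,
            "input_encode": self.input_encode,
            "physics_features": self.physics_features,
            "trained": self.trained,
            "head_ranges": HEAD_RANGES,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path,
             renderer: Optional[ForwardRenderer] = None) -> "DecompositionModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        model = cls(UNetConfig(**meta["unet"]), seed=meta["seed"],
                    patch_size=meta["patch_size"],
                    input_encode=meta.get("input_encode", True),
                    physics_features=meta.get("physics_features", True),
                    renderer=renderer)
        with np.load(path.with_suffix(".npz")) as data:
            model.unet.load_state_dict(dict(data))
        model.trained = meta["trained"]
        return model


def reconstruct(maps: ChromophoreMaps, renderer: ForwardRenderer):
    """Render maps back to a working-linear-RGB image (the forward problem)."""
    return renderer.render_image(maps)


def _masked_mse_grad(recon: np.ndarray, target: np.ndarray, mask: np.ndarray,
                     loss_space: str = "srgb"):
    """Masked MSE and d(loss)/d(recon) (3 channels per masked pixel).

    With ``loss_space="srgb"`` both images pass through the power-law gamma
    encode before comparison, so the error is measured in the same units as
    the original photograph; the chain rule factor enc'(recon) re-weights
    the gradient accordingly.  ``"linear"`` compares working-linear values.
    """
    sel = mask[..., None]
    n_eff = sel.sum() * 3
    if n_eff == 0:
        raise NoSignalError("every pixel of the batch is masked out")
    if loss_space == "srgb":
        from .imaging import GAMMA_EXP, GAMMA_OFFSET
        safe = np.maximum(recon, 1e-4)
        enc_r = (1 + GAMMA_OFFSET) * safe ** (1.0 / GAMMA_EXP) - GAMMA_OFFSET
        enc_t = (1 + GAMMA_OFFSET) * np.maximum(target, 0.0) ** (1.0 / GAMMA_EXP) - GAMMA_OFFSET
        diff = (enc_r - enc_t) * sel
        loss = float(np.sum(diff**2) / n_eff)
        denc = ((1 + GAMMA_OFFSET) / GAMMA_EXP) * safe ** (1.0 / GAMMA_EXP - 1.0)
        return loss, 2.0 * diff * denc / n_eff
    if loss_space != "linear":
        raise ShapeError(f"unknown loss space {loss_space!r}")
    diff = (recon - target) * sel
    loss = float(np.sum(diff**2) / n_eff)
    return loss, 2.0 * diff / n_eff


def _laplacian(a: np.ndarray) -> np.ndarray:
    """4-neighbor Laplacian over the last two axes, replicating edges."""
    pad = [(0, 0)] * (a.ndim - 2) + [(1, 1), (1, 1)]
    p = np.pad(a, pad, mode="edge")
    return (p[..., :-2, 1:-1] + p[..., 2:, 1:-1]
            + p[..., 1:-1, :-2] + p[..., 1:-1, 2:] - 4.0 * a)


def training_step(
    batch: np.ndarray,
    masks: np.ndarray,
    model: DecompositionModel,
    renderer: ForwardRenderer,
    optimizer: Adam,
    loss_space: str = "srgb",
    shading_smoothness: float = 0.0,
    specular_weight: float = 0.0,
    physics_anchor: float = 0.0,
    chromophore_smoothness: float = 0.0,
) -> float:
    """One optimizer update on a (N, H, W, 3) linear-RGB batch.

    The returned loss is the mean over skin pixels of the squared
    reconstruction error after pushing the predicted maps through the
    forward renderer.  Optional priors act on the gradient only: a shading
    smoothness term (squared spatial gradient — shading encodes
    low-frequency geometry), a specular l2 term (cross-polarized
    acquisition suppresses surface reflection), and a physics anchor — a
    quadratic pull of the melanin/hemoglobin/shading heads toward the
    renderer's analytic pixelwise inverse, in normalized map units.  The
    anchor pins the chromophore mixture whose color signature is nearly
    collinear with the other maps, which the reconstruction error alone
    leaves free.  All default to off.
    """
    batch = np.asarray(batch, float)
    masks = np.asarray(masks, bool)
    if batch.ndim != 4 or batch.shape[:3] != masks.shape:
        raise ShapeError("batch (N,H,W,3) and masks (N,H,W) must align")
    feats = model._features(batch)
    x = np.ascontiguousarray(feats.transpose(0, 3, 1, 2)).astype(np.float32)
    out, cache = model.unet.forward(x, want_cache=True)
    out = out.astype(float)
    maps_list = model.maps_from_network(out)
    n = batch.shape[0]
    recon = np.empty_like(batch)
    rcaches = []
    for i, maps in enumerate(maps_list):
        recon[i], rc = renderer.render(maps, want_cache=True)
        rcaches.append(rc)
    loss, drecon = _masked_mse_grad(recon, batch, masks, loss_space)
    n_px = float(batch.shape[0] * batch.shape[1] * batch.shape[2])
    dout = np.empty_like(out)
    for i in range(n):
        dmel, dhb, dshading, dspec = renderer.backward(rcaches[i], drecon[i])
        for k, (lo, hi) in enumerate(HEAD_RANGES):
            grad = (dmel, dhb, dshading, dspec)[k]
            dout[i, k] = grad * (hi - lo)
    # priors act on the normalized [0, 1] head outputs
    if specular_weight > 0:
        dout[:, 3] += (2.0 * specular_weight / n_px) * out[:, 3]
    for k, lam in ((0, chromophore_smoothness), (1, chromophore_smoothness),
                   (2, shading_smoothness)):
        if lam > 0:
            dout[:, k] -= (2.0 * lam / n_px) * _laplacian(out[:, k])
    if physics_anchor > 0:
        if not model.physics_features:
            raise ShapeError("physics anchor requires physics features")
        sel = masks[:, None, :, :]
        anchor = feats[..., 3:6].transpose(0, 3, 1, 2)
        dout[:, :3] += (2.0 * physics_anchor / n_px) * (out[:, :3] - anchor) * sel
    grads = model.unet.backward(cache, dout)
    optimizer.step(grads)
    return loss


def _augment(patch: np.ndarray, mask: np.ndarray, cfg: TrainConfig,
             rng: np.random.Generator):
    if cfg.scale:
        from skimage.transform import rescale
        f = rng.uniform(0.8, 1.25)
        lo = (cfg.crop or patch.shape[0] // 2) + 8
        if min(patch.shape[0], patch.shape[1]) * f >= lo:
            patch = rescale(patch, f, channel_axis=2, order=1, anti_aliasing=False)
            mask = rescale(mask.astype(float), f, order=0) > 0.5
    if cfg.crop and (patch.shape[0] > cfg.crop or patch.shape[1] > cfg.crop):
        y = rng.integers(0, patch.shape[0] - cfg.crop + 1)
        x = rng.integers(0, patch.shape[1] - cfg.crop + 1)
        patch = patch[y : y + cfg.crop, x : x + cfg.crop]
        mask = mask[y : y + cfg.crop, x : x + cfg.crop]
    if cfg.flip:
        if rng.random() < 0.5:
            patch, mask = patch[:, ::-1], mask[:, ::-1]
        if rng.random() < 0.5:
            patch, mask = patch[::-1], mask[::-1]
    if cfg.rotate:
        k = int(rng.integers(0, 4))
        patch, mask = np.rot90(patch, k), np.rot90(mask, k)
    return np.ascontiguousarray(patch), np.ascontiguousarray(mask)


def train(
    patches: Sequence[np.ndarray],
    masks: Sequence[np.ndarray],
    renderer: ForwardRenderer,
    config: TrainConfig,
    model: Optional[DecompositionModel] = None,
    val_patches: Optional[Sequence[np.ndarray]] = None,
    val_masks: Optional[Sequence[np.ndarray]] = None,
    log_path: Optional[str | Path] = None,
    verbose: bool = False,
) -> tuple[DecompositionModel, list[dict]]:
    """Run the self-supervised loop; returns the best model and history.

    ``patches`` are linear-RGB (H, W, 3) arrays (sRGB inputs must be gamma
    decoded first); ``masks`` select skin pixels for the loss.  History rows
    carry epoch, training MSE, validation MSE/PSNR and learning rate; the
    best validation (or training) loss checkpoint is restored at the end.
    """
    if len(patches) == 0:
        raise DataError("empty training dataset")
    if len(patches) != len(masks):
        raise ShapeError("need one mask per patch")
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = DecompositionModel(seed=config.seed, patch_size=patches[0].shape[0],
                                   renderer=renderer)
    if model.renderer is None:
        model.renderer = renderer
    optimizer = Adam(model.unet.params, lr=config.lr, weight_decay=config.weight_decay)
    period = config.cosine_period or config.epochs
    history: list[dict] = []
    best = (np.inf, None)
    n = len(patches)
    for epoch in range(config.epochs):
        lr = cosine_annealing_lr(config.lr, epoch, period, config.lr_min)
        optimizer.lr = lr
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            pairs = [_augment(patches[i], masks[i], config, rng) for i in idx]
            xb = np.stack([p for p, _ in pairs])
            mb = np.stack([m for _, m in pairs])
            losses.append(training_step(xb, mb, model, renderer, optimizer,
                                        config.loss_space,
                                        config.shading_smoothness,
                                        config.specular_weight,
                                        config.physics_anchor,
                                        config.chromophore_smoothness))
        train_mse = float(np.mean(losses))
        row = {"epoch": epoch, "mse": train_mse, "lr": lr,
               "psnr": min(100.0, 10 * math.log10(1.0 / max(train_mse, 1e-12)))}
        if val_patches is not None:
            vm = evaluate(model, renderer, val_patches, val_masks)
            row["val_mse"], row["val_psnr"] = vm["mse"], vm["psnr"]
            score = vm["mse"]
        else:
            score = train_mse
        history.append(row)
        if verbose:
            print(", ".join(f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
                            for k, v in row.items()))
        if score < best[0]:
            best = (score, model.unet.state_dict())
    if best[1] is not None:
        model.unet.load_state_dict(best[1])
    model.trained = True
    if log_path is not None:
        import pandas as pd

        pd.DataFrame(history).to_csv(log_path, index=False)
    return model, history


def evaluate(
    model: DecompositionModel,
    renderer: ForwardRenderer,
    patches: Sequence[np.ndarray],
    masks: Optional[Sequence[np.ndarray]] = None,
    space: str = "srgb",
) -> dict:
    """Mean masked reconstruction MSE / PSNR over linear-RGB patches.

    With ``space="srgb"`` (default) the comparison happens after gamma
    encoding, i.e. in the units of the original photograph.
    """
    from .imaging import gamma_encode as _enc

    mses = []
    psnrs = []
    for i, patch in enumerate(patches):
        mask = np.ones(patch.shape[:2], bool) if masks is None else np.asarray(masks[i], bool)
        saved = model.patch_size
        model.patch_size = patch.shape[0]
        try:
            maps = model.decompose_patch(patch)
        finally:
            model.patch_size = saved
        recon = renderer.render(maps)
        a, b = recon[mask], patch[mask]
        if space == "srgb":
            a = _enc(np.clip(a, 0.0, None))
            b = _enc(np.clip(b, 0.0, None))
        mse = float(np.mean((a - b) ** 2))
        mses.append(mse)
        psnrs.append(min(100.0, 10 * math.log10(1.0 / max(mse, 1e-12))))
    return {"mse": float(np.mean(mses)), "psnr": float(np.mean(psnrs))}
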