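"""Desk-scale self-supervised replication benchmark.

One routine generates the study conditions end to end: synthetic
cross-polarized skin patches (256 x 256, sensor noise sigma 0.002), a
short self-supervised training run of the reduced U-Net through the
forward renderer, and held-out evaluation — mean reconstruction PSNR plus
Pearson correlation between predicted and ground-truth chromophore maps.
Both the test suite and the acceptance script call this module, so the
reported numbers always come from the same computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decomposition import DecompositionModel, TrainConfig, evaluate, train
from .nn.unet import UNetConfig
from .imaging import gamma_decode
from .pipeline import pearson_correlation
from .render import ForwardRenderer, default_renderer
from .synthetic import SceneParams, generate_scene

#: generator settings for training/evaluation patches: the full frame is
#: skin (patches are cut from face interiors) with the default noise level
PATCH_PARAMS = SceneParams(skin_margin=0.0, noise_sigma=0.002)


@dataclass
class BenchmarkResult:
    psnr: float                  # mean held-out reconstruction PSNR, dB
    mel_corr: float              # mean Pearson r, predicted vs true melanin
    hb_corr: float               # mean Pearson r, predicted vs true hemoglobin
    n_train: int
    n_eval: int
    history: list = field(default_factory=list)
    model: Optional[DecompositionModel] = None
    renderer: Optional[ForwardRenderer] = None


def default_train_config(seed: int = 0) -> TrainConfig:
    """The short-schedule configuration used for the desk-scale run."""
    return TrainConfig(seed=seed)


def run_benchmark(
    seed: int = 0,
    n_train: int = 200,
    n_eval: int = 20,
    patch_size: int = 256,
    config: Optional[TrainConfig] = None,
    renderer: Optional[ForwardRenderer] = None,
    verbose: bool = False,
) -> BenchmarkResult:
    """Train on ``n_train`` synthetic patches and evaluate on held-out ones.

    All randomness derives from ``seed``: scene seeds are spawned from it
    and the training seed equals it.
    """
    renderer = renderer or default_renderer()
    config = config or default_train_config(seed)
    ss = np.random.SeedSequence(seed)
    scene_seeds = ss.generate_state(n_train + n_eval) >> 1
    patches, masks = [], []
    for i in range(n_train):
        s = generate_scene(int(scene_seeds[i]), patch_size, patch_size,
                           PATCH_PARAMS, renderer)
        patches.append(gamma_decode(s.image))
        masks.append(s.mask.as_bool())
    eval_scenes = [
        generate_scene(int(scene_seeds[n_train + i]), patch_size, patch_size,
                       PATCH_PARAMS, renderer)
        for i in range(n_eval)
    ]
    # the desk-scale reduced U-Net: 3 pooling stages, 12 base channels
    model = DecompositionModel(
        UNetConfig(in_channels=6, out_channels=4, base_width=12, depth=3),
        seed=config.seed, patch_size=patch_size, renderer=renderer,
    )
    model, history = train(patches, masks, renderer, config, model=model,
                           verbose=verbose)

    eval_patches = [gamma_decode(s.image) for s in eval_scenes]
    eval_masks = [s.mask.as_bool() for s in eval_scenes]
    ev = evaluate(model, renderer, eval_patches, eval_masks)
    mel_r, hb_r = [], []
    for s, lin in zip(eval_scenes, eval_patches):
        saved = model.patch_size
        model.patch_size = patch_size
        try:
            maps = model.decompose_patch(lin)
        finally:
            model.patch_size = saved
        mel_r.append(pearson_correlation(maps.mel_map, s.truth.mel_map, s.mask))
        hb_r.append(pearson_correlation(maps.hb_map, s.truth.hb_map, s.mask))
    return BenchmarkResult(
        psnr=float(ev["psnr"]),
        mel_corr=float(np.mean(mel_r)),
        hb_corr=float(np.mean(hb_r)),
        n_train=n_train,
        n_eval=n_eval,
        history=history,
        model=model,
        renderer=renderer,
    )
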