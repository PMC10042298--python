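"""Decomposition model, differentiable reconstruction, self-supervised training."""

import numpy as np
import pytest

from chromodecomp.decomposition import (
    DecompositionModel,
    TrainConfig,
    psnr,
    reconstruct,
    train,
    training_step,
)
from chromodecomp.errors import NoSignalError, ShapeError, SizeError
from chromodecomp.imaging import gamma_decode
from chromodecomp.maps import ChromophoreMaps
from chromodecomp.nn import Adam
from chromodecomp.nn.unet import UNetConfig
from chromodecomp.optics import HEMOGLOBIN_RANGE, MELANIN_RANGE
from chromodecomp.synthetic import SceneParams, generate_scene

SMALL_CFG = UNetConfig(in_channels=6, out_channels=4, base_width=4, depth=1)


def small_model(renderer, seed=0, patch=16):
    return DecompositionModel(SMALL_CFG, seed=seed, patch_size=patch,
                              renderer=renderer)


def training_patch(renderer, seed=0, size=16):
    scene = generate_scene(seed, 64, 64, SceneParams(skin_margin=0.0), renderer)
    lin = gamma_decode(scene.image)
    return lin[:size, :size], scene


class TestDecomposePatch:
    def test_outputs_satisfy_invariants_for_any_weights(self, renderer, rng):
        for seed in (0, 1, 2):
            model = small_model(renderer, seed=seed)
            patch = rng.uniform(0, 0.6, (16, 16, 3))
            maps = model.decompose_patch(patch)
            maps.validate_ranges()
            assert maps.shape == (16, 16)

    def test_inference_deterministic(self, renderer, rng):
        model = small_model(renderer)
        patch = rng.uniform(0, 0.6, (16, 16, 3))
        a = model.decompose_patch(patch)
        b = model.decompose_patch(patch)
        assert np.array_equal(a.mel_map, b.mel_map)

    def test_wrong_patch_size_rejected(self, renderer, rng):
        model = small_model(renderer)
        with pytest.raises(SizeError):
            model.decompose_patch(rng.random((17, 16, 3)))

    def test_range_mapping_round_trip(self):
        rng = np.random.default_rng(0)
        maps = ChromophoreMaps(
            rng.uniform(*MELANIN_RANGE, (4, 4)),
            rng.uniform(*HEMOGLOBIN_RANGE, (4, 4)),
            rng.uniform(0, 2, (4, 4)),
            rng.uniform(0, 1, (4, 4)),
        )
        norm = DecompositionModel.network_from_maps(maps)
        assert norm.min() >= 0 and norm.max() <= 1
        back = DecompositionModel.maps_from_network(norm[None])[0]
        assert np.allclose(back.mel_map, maps.mel_map)
        assert np.allclose(back.specular_map, maps.specular_map)

    def test_save_load_round_trip(self, renderer, rng, tmp_path):
        model = small_model(renderer)
        model.save(tmp_path / "m")
        loaded = DecompositionModel.load(tmp_path / "m", renderer=renderer)
        patch = rng.uniform(0, 0.6, (16, 16, 3))
        assert np.array_equal(model.decompose_patch(patch).hb_map,
                              loaded.decompose_patch(patch).hb_map)


class TestReconstruct:
    def test_generator_truth_reproduces_generator_image(self, renderer):
        params = SceneParams(noise_sigma=0.0, specular_count=0, skin_margin=0.0)
        scene = generate_scene(4, 64, 64, params, renderer)
        recon = reconstruct(scene.truth, renderer)
        assert recon.space == "rgb_linear"
        assert np.abs(recon.pixels - gamma_decode(scene.image)).max() < 1e-6

    def test_zero_shading_and_specular_is_black(self, renderer):
        maps = ChromophoreMaps(np.full((4, 4), 0.2), np.full((4, 4), 0.04),
                               np.zeros((4, 4)), np.zeros((4, 4)))
        assert np.all(reconstruct(maps, renderer).pixels == 0.0)

    def test_doubling_shading_doubles_diffuse_term(self, renderer, rng):
        mel = rng.uniform(*MELANIN_RANGE, (4, 4))
        hb = rng.uniform(*HEMOGLOBIN_RANGE, (4, 4))
        sh = rng.uniform(0.2, 0.9, (4, 4))
        one = reconstruct(ChromophoreMaps(mel, hb, sh, np.zeros((4, 4))), renderer)
        two = reconstruct(ChromophoreMaps(mel, hb, 2 * sh, np.zeros((4, 4))), renderer)
        assert np.allclose(two.pixels, 2 * one.pixels)


class TestTrainingStep:
    def test_loss_matches_hand_computed_masked_mse(self, renderer):
        model = small_model(renderer)
        patch, _ = training_patch(renderer)
        mask = np.ones(patch.shape[:2], bool)
        # oracle: run the same forward pieces by hand before the update
        maps = model.decompose_patch(patch)
        recon = renderer.render(maps)
        expected = float(np.mean((recon - patch) ** 2))
        opt = Adam(model.unet.params, lr=0.0, weight_decay=0.0)  # no movement
        loss = training_step(patch[None], mask[None], model, renderer, opt,
                             loss_space="linear")
        assert loss == pytest.approx(expected, rel=1e-10)

    def test_loss_nonnegative_and_update_applied(self, renderer):
        model = small_model(renderer)
        patch, _ = training_patch(renderer)
        mask = np.ones(patch.shape[:2], bool)
        before = model.unet.params["head_w"].copy()
        opt = Adam(model.unet.params, lr=1e-3)
        loss = training_step(patch[None], mask[None], model, renderer, opt)
        assert loss >= 0.0
        assert not np.array_equal(before, model.unet.params["head_w"])

    def test_fully_masked_batch_rejected(self, renderer):
        model = small_model(renderer)
        patch, _ = training_patch(renderer)
        opt = Adam(model.unet.params)
        with pytest.raises(NoSignalError):
            training_step(patch[None], np.zeros((1, 16, 16), bool), model,
                          renderer, opt)

    def test_mismatched_mask_shape_rejected(self, renderer):
        model = small_model(renderer)
        patch, _ = training_patch(renderer)
        opt = Adam(model.unet.params)
        with pytest.raises(ShapeError):
            training_step(patch[None], np.ones((1, 8, 8), bool), model, renderer, opt)

    def test_priors_leave_reported_loss_unchanged(self, renderer):
        patch, _ = training_patch(renderer)
        mask = np.ones(patch.shape[:2], bool)
        losses = []
        for priors in ((0, 0, 0, 0), (0.3, 0.01, 0.3, 3.0)):
            model = small_model(renderer)  # identical init both times
            opt = Adam(model.unet.params, lr=0.0, weight_decay=0.0)
            sh, sp, anchor, chromo = priors
            losses.append(training_step(patch[None], mask[None], model, renderer,
                                        opt, "srgb", sh, sp, anchor, chromo))
        assert losses[0] == losses[1]


class TestTrainLoop:
    def make_data(self, renderer, n=4):
        patches, masks = [], []
        for i in range(n):
            scene = generate_scene(100 + i, 64, 64, SceneParams(skin_margin=0.0),
                                   renderer)
            patches.append(gamma_decode(scene.image)[:32, :32])
            masks.append(np.ones((32, 32), bool))
        return patches, masks

    def config(self, epochs=4):
        return TrainConfig(epochs=epochs, batch_size=2, lr=2e-3, crop=16, seed=3)

    def test_loss_descends_and_history_logged(self, renderer, tmp_path):
        patches, masks = self.make_data(renderer)
        model = small_model(renderer, patch=32)
        model, history = train(patches, masks, renderer, self.config(8), model=model,
                               log_path=tmp_path / "log.csv")
        assert history[-1]["mse"] < history[0]["mse"]
        assert (tmp_path / "log.csv").exists()
        assert {"epoch", "mse", "psnr", "lr"} <= set(history[0])
        assert model.trained

    def test_fixed_seed_reproduces_history_exactly(self, renderer):
        patches, masks = self.make_data(renderer)
        histories = []
        for _ in range(2):
            model = small_model(renderer, patch=32)
            _, history = train(patches, masks, renderer, self.config(), model=model)
            histories.append([row["mse"] for row in history])
        assert histories[0] == histories[1]

    def test_empty_dataset_rejected(self, renderer):
        from chromodecomp.errors import DataError

        with pytest.raises(DataError):
            train([], [], renderer, self.config())


class TestPsnr:
    def test_identical_images_hit_cap(self, rng):
        img = rng.random((8, 8, 3))
        assert psnr(img, img) == 100.0

    def test_known_mse_gives_20_db(self):
        a = np.zeros((10, 10))
        b = np.full((10, 10), 0.1)  # MSE 0.01 on unit-range images
        assert psnr(a, b) == pytest.approx(20.0)

    def test_random_pair_matches_direct_formula(self, rng):
        a = rng.random((6, 6, 3))
        b = rng.random((6, 6, 3))
        expected = 10 * np.log10(1.0 / np.mean((a - b) ** 2))
        assert psnr(a, b) == pytest.approx(expected)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ShapeError):
            psnr(rng.random((4, 4)), rng.random((5, 4)))
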