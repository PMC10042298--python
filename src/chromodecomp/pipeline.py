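"""End-to-end inference and chromophore-manipulation simulation.

``analyze_image`` runs the full chain on an sRGB image: skin segmentation
(or an external mask), gamma linearization, overlapping patch division,
per-patch decomposition, gradient-blend recombination and off-mask
zeroing.  ``simulate_modification`` re-renders an image after scaling the
melanin map and shifting the hemoglobin map, the chromophore-editing
application of the forward model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .decomposition import DecompositionModel, reconstruct
from .errors import DegenerateScaleError, InvalidValueError, ShapeError
from .imaging import LinearImage, gamma_decode, gamma_encode
from .maps import ChromophoreMaps, SkinMask
from .patching import PatchGrid, PatchSet, combine, divide, plan_grid
from .render import ForwardRenderer
from .segmentation import SegmentationModel, segment


@dataclass
class AnalysisResult:
    """Full-resolution decomposition of one image."""

    maps: ChromophoreMaps
    mask: SkinMask
    grid: PatchGrid
    provenance: dict = field(default_factory=dict)

    def grayscale(self, which: str = "mel", invert: bool = False) -> np.ndarray:
        arr = {"mel": self.maps.mel_map, "hb": self.maps.hb_map,
               "shading": self.maps.shading_map, "specular": self.maps.specular_map}[which]
        return to_grayscale(arr, self.mask, invert=invert)


def _digest(arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def analyze_image(
    image: LinearImage,
    model: DecompositionModel,
    renderer: ForwardRenderer,
    patch_size: int | None = None,
    overlap: int = 15,
    mask: Optional[SkinMask] = None,
    segmenter: Optional[SegmentationModel] = None,
) -> AnalysisResult:
    """sRGB image -> chromophore maps at input resolution.

    A mask may be supplied directly; otherwise a trained segmenter is
    required.  Off-mask pixels are exactly zero in all four output maps.
    """
    image.require_space("srgb")
    h, w = image.shape
    if mask is None:
        if segmenter is None:
            raise InvalidValueError("supply either a mask or a trained segmenter")
        mask = segment(image, segmenter)
    if mask.shape != (h, w):
        raise ShapeError("mask shape must equal image shape")
    if model.renderer is None:
        model.renderer = renderer
    patch_size = patch_size or model.patch_size
    linear = gamma_decode(image).pixels
    grid = plan_grid(h, w, patch_size, overlap)
    patches = divide(linear, grid)
    out_blocks = []
    saved = model.patch_size
    model.patch_size = patch_size
    try:
        for r, c, block in patches:
            m = model.decompose_patch(block)
            out_blocks.append((r, c, np.stack(
                [m.mel_map, m.hb_map, m.shading_map, m.specular_map], axis=-1)))
    finally:
        model.patch_size = saved
    stacked = combine(PatchSet(out_blocks, grid), grid)
    sel = mask.as_bool()
    maps = ChromophoreMaps(*(np.where(sel, stacked[..., k], 0.0) for k in range(4)))
    prov = {
        "model_hash": _digest(model.unet.params.values()),
        "profile_hash": _digest([renderer.profile.spd.values,
                                 renderer.profile.sensitivities]),
        "grid": (grid.rows, grid.cols, grid.patch_size, grid.overlap),
        "visualization": "min-max over skin pixels",
    }
    return AnalysisResult(maps=maps, mask=mask, grid=grid, provenance=prov)


def simulate_modification(
    image: LinearImage,
    model: DecompositionModel,
    renderer: ForwardRenderer,
    mel_factor: float = 1.0,
    hb_delta: float = 0.0,
    mask: Optional[SkinMask] = None,
    segmenter: Optional[SegmentationModel] = None,
    patch_size: int | None = None,
    overlap: int = 15,
) -> LinearImage:
    """Re-render the image with edited chromophore maps.

    The melanin map is scaled multiplicatively and the hemoglobin map
    shifted additively, both in normalized [0, 1] map units, then
    re-clamped to the physiological ranges and pushed through the forward
    renderer.  Non-skin pixels keep their original values.
    """
    result = analyze_image(image, model, renderer, patch_size=patch_size,
                           overlap=overlap, mask=mask, segmenter=segmenter)
    sel = result.mask.as_bool()
    norm = DecompositionModel.network_from_maps(result.maps)
    norm[0] = np.clip(norm[0] * mel_factor, 0.0, 1.0)
    norm[1] = np.clip(norm[1] + hb_delta, 0.0, 1.0)
    edited = DecompositionModel.maps_from_network(norm[None])[0].clamped()
    rendered = reconstruct(edited, renderer).pixels
    original_linear = gamma_decode(image).pixels
    out_linear = np.where(sel[..., None], rendered, original_linear)
    return gamma_encode(LinearImage(np.clip(out_linear, 0.0, None)))


def to_grayscale(map_: np.ndarray, mask: Optional[SkinMask] = None,
                 invert: bool = False) -> np.ndarray:
    """Min-max scale a map to [0, 1] over skin pixels; optionally invert.

    Off-mask pixels are set to 0 (or 1 when inverted) after scaling.
    """
    arr = np.asarray(map_, float)
    if not np.all(np.isfinite(arr)):
        raise InvalidValueError("map contains non-finite values")
    sel = np.ones(arr.shape, bool) if mask is None else mask.as_bool()
    vals = arr[sel]
    if vals.size == 0 or vals.max() - vals.min() < 1e-15:
        raise DegenerateScaleError("cannot min-max scale a constant map")
    scaled = (arr - vals.min()) / (vals.max() - vals.min())
    scaled = np.clip(scaled, 0.0, 1.0)
    if invert:
        scaled = 1.0 - scaled
    return np.where(sel, scaled, 0.0 if not invert else 1.0)


def pearson_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        mask: Optional[SkinMask] = None) -> float:
    """Product-moment correlation over masked pixels."""
    a = np.asarray(map_a, float)
    b = np.asarray(map_b, float)
    if a.shape != b.shape:
        raise ShapeError("maps must share a shape")
    sel = np.ones(a.shape, bool) if mask is None else mask.as_bool()
    x, y = a[sel], b[sel]
    if x.size < 2:
        raise InvalidValueError("need at least two masked pixels")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateScaleError("correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])
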