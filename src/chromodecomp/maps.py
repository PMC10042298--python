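"""Per-pixel containers shared across modules: chromophore maps and skin masks."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidValueError, ShapeError
from .optics import HEMOGLOBIN_RANGE, MELANIN_RANGE

#: range of the scalar shading / specular maps after range mapping
SHADING_RANGE = (0.0, 2.0)
SPECULAR_RANGE = (0.0, 1.0)


@dataclass
class ChromophoreMaps:
    """The four decomposition outputs (and simulator inputs).

    ``mel_map``/``hb_map`` are per-pixel volume fractions inside the
    physiological boxes; ``shading_map`` is the per-pixel geometric
    attenuation of diffuse light; ``specular_map`` the per-pixel surface
    reflection strength.  All share one spatial shape (H, W).
    """

    mel_map: np.ndarray
    hb_map: np.ndarray
    shading_map: np.ndarray
    specular_map: np.ndarray

    def __post_init__(self) -> None:
        arrs = [
            np.asarray(a, dtype=float)
            for a in (self.mel_map, self.hb_map, self.shading_map, self.specular_map)
        ]
        shape = arrs[0].shape
        if any(a.shape != shape for a in arrs):
            raise ShapeError("all four maps must share one spatial shape")
        if any(a.ndim != 2 for a in arrs):
            raise ShapeError("maps must be 2-d (H, W)")
        self.mel_map, self.hb_map, self.shading_map, self.specular_map = arrs

    @property
    def shape(self) -> tuple[int, int]:
        return self.mel_map.shape

    def validate_ranges(self, atol: float = 1e-9) -> None:
        lo, hi = MELANIN_RANGE
        if self.mel_map.min() < lo - atol or self.mel_map.max() > hi + atol:
            raise InvalidValueError("melanin map outside physiological range")
        lo, hi = HEMOGLOBIN_RANGE
        if self.hb_map.min() < lo - atol or self.hb_map.max() > hi + atol:
            raise InvalidValueError("hemoglobin map outside physiological range")
        if self.shading_map.min() < -atol or self.specular_map.min() < -atol:
            raise InvalidValueError("shading/specular maps must be non-negative")

    def clamped(self) -> "ChromophoreMaps":
        return ChromophoreMaps(
            np.clip(self.mel_map, *MELANIN_RANGE),
            np.clip(self.hb_map, *HEMOGLOBIN_RANGE),
            np.clip(self.shading_map, *SHADING_RANGE),
            np.clip(self.specular_map, *SPECULAR_RANGE),
        )

    def copy(self) -> "ChromophoreMaps":
        return ChromophoreMaps(
            self.mel_map.copy(), self.hb_map.copy(),
            self.shading_map.copy(), self.specular_map.copy(),
        )


@dataclass
class SkinMask:
    """Binary skin mask with the same spatial size as its image."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise ShapeError("mask must be 2-d")
        m = (m > 0.5).astype(np.uint8) if m.dtype != np.uint8 else (m > 0).astype(np.uint8)
        self.mask = m

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def coverage(self) -> float:
        return float(self.mask.mean())

    def as_bool(self) -> np.ndarray:
        return self.mask.astype(bool)


def iou(pred: SkinMask, truth: SkinMask) -> float:
    """Intersection over union; the both-empty convention returns 1."""
    if pred.shape != truth.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    p, t = pred.as_bool(), truth.as_bool()
    union = np.logical_or(p, t).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(p, t).sum() / union)
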