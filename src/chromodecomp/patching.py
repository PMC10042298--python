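"""Overlapping patch tiling with seamless gradient-blend recombination.

A full-resolution image is divided into fixed-size square patches whose
borders overlap; after per-patch processing the outputs are recombined by
multiplying each overlap band with opposite linear ramp weights so that the
contributing weights sum to one at every output pixel (partition of unity).
With the default geometry (256-pixel patches, 15-pixel overlap) a 4x6 grid
recombines to 979 x 1461 pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .errors import IncompleteSetError, SizeError

DEFAULT_PATCH_SIZE = 256
DEFAULT_OVERLAP = 15


@dataclass(frozen=True)
class PatchGrid:
    """Tiling geometry for one image."""

    rows: int
    cols: int
    patch_size: int
    overlap: int
    image_height: int
    image_width: int

    @property
    def stride(self) -> int:
        return self.patch_size - self.overlap

    @property
    def padded_height(self) -> int:
        return self.rows * self.patch_size - (self.rows - 1) * self.overlap

    @property
    def padded_width(self) -> int:
        return self.cols * self.patch_size - (self.cols - 1) * self.overlap

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def origin(self, r: int, c: int) -> tuple[int, int]:
        return r * self.stride, c * self.stride

    def blend_weight(self, r: int, c: int) -> np.ndarray:
        """Separable (patch_size, patch_size) blend-weight tile for patch (r, c).

        Linear ramps 1/(o+1) .. o/(o+1) rise across each interior overlap
        band; the neighboring patch carries the complementary ramp, so the
        two sum to one everywhere in the band.
        """
        return np.outer(
            _axis_weight(r, self.rows, self.patch_size, self.overlap),
            _axis_weight(c, self.cols, self.patch_size, self.overlap),
        )


def _axis_weight(i: int, n: int, p: int, o: int) -> np.ndarray:
    w = np.ones(p)
    if o > 0:
        ramp = np.arange(1, o + 1) / (o + 1.0)
        if i > 0:
            w[:o] = ramp
        if i < n - 1:
            w[-o:] = ramp[::-1]
    return w


@dataclass
class PatchSet:
    """Ordered (row, col)-indexed pixel blocks cut from one image."""

    patches: list[tuple[int, int, np.ndarray]]
    grid: PatchGrid

    def __iter__(self) -> Iterator[tuple[int, int, np.ndarray]]:
        return iter(self.patches)

    def __len__(self) -> int:
        return len(self.patches)


def plan_grid(
    image_height: int,
    image_width: int,
    patch_size: int = DEFAULT_PATCH_SIZE,
    overlap: int = DEFAULT_OVERLAP,
) -> PatchGrid:
    """Smallest rows x cols tiling covering the image at the stated stride."""
    if not 0 <= overlap < patch_size:
        raise SizeError("require patch_size > overlap >= 0")
    if image_height < patch_size or image_width < patch_size:
        raise SizeError(
            f"image {image_height}x{image_width} smaller than one {patch_size}-pixel patch"
        )
    stride = patch_size - overlap
    rows = max(1, math.ceil((image_height - overlap) / stride))
    cols = max(1, math.ceil((image_width - overlap) / stride))
    return PatchGrid(rows, cols, patch_size, overlap, image_height, image_width)


def divide(image: np.ndarray, grid: PatchGrid) -> PatchSet:
    """Cut the image into overlapping patches, reflect-padding bottom/right."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if (h, w) != (grid.image_height, grid.image_width):
        raise SizeError(
            f"image {h}x{w} does not match grid geometry "
            f"{grid.image_height}x{grid.image_width}"
        )
    pad_h = grid.padded_height - h
    pad_w = grid.padded_width - w
    if pad_h or pad_w:
        pad = [(0, pad_h), (0, pad_w)] + [(0, 0)] * (image.ndim - 2)
        image = np.pad(image, pad, mode="reflect")
    blocks = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            y, x = grid.origin(r, c)
            blocks.append((r, c, image[y : y + grid.patch_size, x : x + grid.patch_size].copy()))
    return PatchSet(blocks, grid)


def combine(patches: PatchSet, grid: PatchGrid | None = None) -> np.ndarray:
    """Blend-weighted recombination; inverse of :func:`divide` up to padding."""
    grid = grid or patches.grid
    seen = {(r, c) for r, c, _ in patches}
    expected = {(r, c) for r in range(grid.rows) for c in range(grid.cols)}
    if seen != expected:
        raise IncompleteSetError(f"missing patches: {sorted(expected - seen)[:5]} ...")
    first = patches.patches[0][2]
    extra = first.shape[2:]
    out = np.zeros((grid.padded_height, grid.padded_width, *extra), dtype=float)
    for r, c, block in patches:
        if block.shape[:2] != (grid.patch_size, grid.patch_size):
            raise SizeError("patch block has the wrong size")
        y, x = grid.origin(r, c)
        wt = grid.blend_weight(r, c)
        out[y : y + grid.patch_size, x : x + grid.patch_size] += (
            block * wt.reshape(wt.shape + (1,) * len(extra))
        )
    return out[: grid.image_height, : grid.image_width]
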