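"""A reduced-channel U-Net with explicit forward/backward passes.

``depth`` pooling stages halve the resolution; channel width doubles per
stage from ``base_width``.  Each stage is two 3x3 conv + leaky-ReLU blocks;
the decoder upsamples (nearest), concatenates the encoder skip and applies
the same double-conv; a 1x1 head with optional sigmoid produces
``out_channels`` maps in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import ShapeError, SizeError
from . import layers as L


@dataclass
class UNetConfig:
    in_channels: int = 3
    out_channels: int = 4
    base_width: int = 16
    depth: int = 4           # number of pooling stages
    final_sigmoid: bool = True
    lrelu_slope: float = 0.1

    def width(self, level: int) -> int:
        return self.base_width * (2**level)


class UNet:
    """Parameters live in ``self.params`` (name -> float32 array)."""

    def __init__(self, config: UNetConfig, rng: np.random.Generator):
        self.config = config
        self.params: dict[str, np.ndarray] = {}
        c_in = config.in_channels
        for l in range(config.depth + 1):  # encoder stages + bottleneck
            c_out = config.width(l)
            self._add_conv(f"enc{l}a", c_in, c_out, rng)
            self._add_conv(f"enc{l}b", c_out, c_out, rng)
            c_in = c_out
        for l in range(config.depth - 1, -1, -1):
            c_cat = config.width(l) + config.width(l + 1)
            self._add_conv(f"dec{l}a", c_cat, config.width(l), rng)
            self._add_conv(f"dec{l}b", config.width(l), config.width(l), rng)
        w0 = config.width(0)
        self.params["head_w"] = (
            rng.standard_normal((config.out_channels, w0)) * np.sqrt(2.0 / w0)
        ).astype(np.float32)
        self.params["head_b"] = np.zeros(config.out_channels, dtype=np.float32)

    def _add_conv(self, name: str, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        fan_in = c_in * 9
        self.params[f"{name}_w"] = (
            rng.standard_normal((c_out, c_in, 3, 3)) * np.sqrt(2.0 / fan_in)
        ).astype(np.float32)
        self.params[f"{name}_b"] = np.zeros(c_out, dtype=np.float32)

    # ------------------------------------------------------------------
    def _block(self, name: str, x: np.ndarray, cache: Optional[dict]) -> np.ndarray:
        z = L.conv3x3_forward(x, self.params[f"{name}_w"], self.params[f"{name}_b"])
        y = L.leaky_relu_forward(z, self.config.lrelu_slope)
        if cache is not None:
            cache[name] = (x, z)
        return y

    def _block_backward(self, name: str, cache: dict, dy: np.ndarray, grads: dict) -> np.ndarray:
        x, z = cache[name]
        dz = L.leaky_relu_backward(z, dy, self.config.lrelu_slope)
        dx, dw, db = L.conv3x3_backward(x, self.params[f"{name}_w"], dz)
        grads[f"{name}_w"] = dw
        grads[f"{name}_b"] = db
        return dx

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Returns (output, cache); cache is None unless requested."""
        cfg = self.config
        x = np.ascontiguousarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ShapeError(f"expected (N, {cfg.in_channels}, H, W) input")
        div = 2**cfg.depth
        if x.shape[2] % div or x.shape[3] % div:
            raise SizeError(f"spatial dims must be divisible by {div}")
        cache: Optional[dict] = {} if want_cache else None
        skips = []
        h = x
        for l in range(cfg.depth):
            h = self._block(f"enc{l}a", h, cache)
            h = self._block(f"enc{l}b", h, cache)
            skips.append(h)
            h = L.avgpool2_forward(h)
        h = self._block(f"enc{cfg.depth}a", h, cache)
        h = self._block(f"enc{cfg.depth}b", h, cache)
        for l in range(cfg.depth - 1, -1, -1):
            u = L.upsample2_forward(h)
            cat = np.concatenate([u, skips[l]], axis=1)
            h = self._block(f"dec{l}a", cat, cache)
            h = self._block(f"dec{l}b", h, cache)
        z = L.conv1x1_forward(h, self.params["head_w"], self.params["head_b"])
        out = L.sigmoid(z) if cfg.final_sigmoid else z
        if want_cache:
            cache["head"] = (h,)
            cache["out"] = out
        return out, cache

    def backward(self, cache: dict, dout: np.ndarray) -> dict[str, np.ndarray]:
        """Gradient of a scalar loss w.r.t. all parameters given d(loss)/d(output)."""
        cfg = self.config
        grads: dict[str, np.ndarray] = {}
        if cfg.final_sigmoid:
            out = cache["out"]
            dz = dout * out * (1.0 - out)
        else:
            dz = dout
        (h_head,) = cache["head"]
        dh, dw, db = L.conv1x1_backward(h_head, self.params["head_w"], dz.astype(np.float32))
        grads["head_w"], grads["head_b"] = dw, db
        dskips: dict[int, np.ndarray] = {}
        for l in range(cfg.depth):
            dh = self._block_backward(f"dec{l}b", cache, dh, grads)
            dcat = self._block_backward(f"dec{l}a", cache, dh, grads)
            c_up = cfg.width(l + 1)
            dskips[l] = dcat[:, c_up:]
            dh = L.upsample2_backward(dcat[:, :c_up])
        dh = self._block_backward(f"enc{cfg.depth}b", cache, dh, grads)
        dh = self._block_backward(f"enc{cfg.depth}a", cache, dh, grads)
        for l in range(cfg.depth - 1, -1, -1):
            dh = L.avgpool2_backward(dh) + dskips[l]
            dh = self._block_backward(f"enc{l}b", cache, dh, grads)
            dh = self._block_backward(f"enc{l}a", cache, dh, grads)
        return grads

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)
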