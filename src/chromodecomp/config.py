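"""YAML configuration: sections ``optics``, ``imaging``, ``patching``, ``training``.

Every default in the package can be overridden here; unknown keys raise.
Example::

    optics:
      d_epi_cm: 0.006
      oxygen_saturation: 0.7
      scattering: {a: 45.0, b_mie: 1.3, f_ray: 0.4, lambda0_nm: 500.0}
    imaging:
      profile_dir: /path/to/profile   # spd.csv + sensitivity_{r,g,b}.csv
      colorchecker_degree: 1
    patching:
      patch_size: 256
      overlap: 15
    training:
      epochs: 60
      batch_size: 8
      lr: 1.0e-3
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .decomposition import TrainConfig
from .errors import ConfigError
from .imaging import AcquisitionProfile, default_profile, load_profile
from .optics import OpticsConfig, ScatteringParams, default_optics
from .render import ForwardRenderer


@dataclass
class PipelineConfig:
    optics: OpticsConfig
    profile: AcquisitionProfile
    patch_size: int = 256
    overlap: int = 15
    colorchecker_degree: int = 1
    training: TrainConfig = field(default_factory=TrainConfig)

    def renderer(self) -> ForwardRenderer:
        from .imaging import build_virtual_colorchecker_transform

        t = build_virtual_colorchecker_transform(self.profile, degree=self.colorchecker_degree)
        return ForwardRenderer(self.profile, self.optics, transform=t)


def _take(section: dict, key, default):
    return section.pop(key, default)


def load_config(path: Optional[str | Path] = None) -> PipelineConfig:
    cfg = {}
    if path is not None:
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}

    opt = dict(cfg.pop("optics", {}) or {})
    scat = opt.pop("scattering", None)
    scattering = ScatteringParams(**scat) if scat else None
    optics = default_optics(
        d_epi=_take(opt, "d_epi_cm", 0.006),
        oxygen_saturation=_take(opt, "oxygen_saturation", 0.7),
        scattering=scattering,
    )
    if opt:
        raise ConfigError(f"unknown optics keys: {sorted(opt)}")

    img = dict(cfg.pop("imaging", {}) or {})
    profile_dir = _take(img, "profile_dir", None)
    profile = load_profile(profile_dir) if profile_dir else default_profile()
    degree = int(_take(img, "colorchecker_degree", 1))
    if img:
        raise ConfigError(f"unknown imaging keys: {sorted(img)}")

    pat = dict(cfg.pop("patching", {}) or {})
    patch_size = int(_take(pat, "patch_size", 256))
    overlap = int(_take(pat, "overlap", 15))
    if pat:
        raise ConfigError(f"unknown patching keys: {sorted(pat)}")

    train_kwargs = dict(cfg.pop("training", {}) or {})
    training = TrainConfig(**train_kwargs)

    if cfg:
        raise ConfigError(f"unknown config sections: {sorted(cfg)}")
    return PipelineConfig(optics=optics, profile=profile, patch_size=patch_size,
                          overlap=overlap, colorchecker_degree=degree, training=training)
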