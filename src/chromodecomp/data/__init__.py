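"""Bundled reference spectra.

The CSVs here are regenerated by ``scripts/make_bundled_spectra.py``:
melanin/hemoglobin extinction curves, a D65-like illuminant, the CIE 1931
2-degree observer (analytic fit), synthetic DSLR-like camera sensitivities
and a synthetic 24-patch ColorChecker.  All are swappable via config; none
are measured data.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from ..spectral import SpectralCurve


def data_path(name: str) -> Path:
    return Path(resources.files(__package__).joinpath(name))


def load_curve(name: str) -> SpectralCurve:
    return SpectralCurve.from_csv(data_path(name))


def load_extinction_melanin() -> SpectralCurve:
    return load_curve("extinction_melanin.csv")


def load_extinction_hemoglobin(oxygen_saturation: float = 0.7) -> SpectralCurve:
    """Whole-blood extinction as a fixed oxy/deoxy mixture (default 70% HbO2)."""
    oxy = load_curve("extinction_hemoglobin_oxy.csv")
    deoxy = load_curve("extinction_hemoglobin_deoxy.csv")
    s = float(oxygen_saturation)
    return SpectralCurve(oxy.wavelengths_nm, s * oxy.values + (1.0 - s) * deoxy.values)


def load_cie_observer() -> tuple[SpectralCurve, SpectralCurve, SpectralCurve]:
    return (
        load_curve("cie1931_xbar.csv"),
        load_curve("cie1931_ybar.csv"),
        load_curve("cie1931_zbar.csv"),
    )


def load_d65() -> SpectralCurve:
    return load_curve("d65_approx_spd.csv")


def load_colorchecker() -> list[SpectralCurve]:
    """The synthetic 24-patch chart, ordered patch_01..patch_24."""
    df = pd.read_csv(data_path("colorchecker_synthetic.csv"))
    wl = df["wavelength_nm"].to_numpy(float)
    return [
        SpectralCurve(wl, df[c].to_numpy(float))
        for c in sorted(c for c in df.columns if c.startswith("patch_"))
    ]


def default_profile_dir() -> Path:
    return data_path("profile_default")
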