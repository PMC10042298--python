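"""Spectral curves: the carrier for SPDs, sensitivities, extinction and
reflectance spectra.

A :class:`SpectralCurve` is a strictly increasing wavelength grid (nm) with
one value per wavelength.  Units depend on the quantity carried: cm^-1 for
absorption/scattering coefficients, dimensionless for reflectance and
transmittance.  Off-grid queries use linear interpolation.

CSV interface: two columns ``wavelength_nm,value`` with a header row,
wavelengths ascending.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import BandCoverageError, GridMismatchError, InvalidValueError


@dataclass(frozen=True)
class SpectralCurve:
    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.shape != wl.shape:
            raise InvalidValueError("wavelengths and values must be 1-d and equal length")
        if wl.size < 2:
            raise InvalidValueError("a spectral curve needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise InvalidValueError("wavelengths must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(vals))):
            raise InvalidValueError("non-finite entries in spectral curve")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "values", vals)

    # -- construction -----------------------------------------------------
    @classmethod
    def from_csv(cls, path: str | Path) -> "SpectralCurve":
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise InvalidValueError(f"{path}: expected two columns wavelength_nm,value")
        return cls(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths_nm, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def constant(cls, grid: np.ndarray, value: float) -> "SpectralCurve":
        grid = np.asarray(grid, dtype=float)
        return cls(grid, np.full(grid.shape, float(value)))

    # -- queries ----------------------------------------------------------
    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation onto ``grid``; raises if outside coverage."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.wavelengths_nm[0] - 1e-9 or grid.max() > self.wavelengths_nm[-1] + 1e-9:
            raise BandCoverageError(
                f"curve covers [{self.wavelengths_nm[0]}, {self.wavelengths_nm[-1]}] nm, "
                f"requested [{grid.min()}, {grid.max()}] nm"
            )
        return np.interp(grid, self.wavelengths_nm, self.values)

    def on_grid(self, grid: np.ndarray) -> "SpectralCurve":
        return SpectralCurve(np.asarray(grid, float), self.interp(grid))

    def covers(self, lo: float, hi: float) -> bool:
        return self.wavelengths_nm[0] <= lo + 1e-9 and self.wavelengths_nm[-1] >= hi - 1e-9

    # -- arithmetic on a shared grid --------------------------------------
    def _check_grid(self, other: "SpectralCurve") -> None:
        if self.wavelengths_nm.shape != other.wavelengths_nm.shape or not np.allclose(
            self.wavelengths_nm, other.wavelengths_nm
        ):
            raise GridMismatchError("spectral curves are on different wavelength grids")

    def __add__(self, other: "SpectralCurve") -> "SpectralCurve":
        self._check_grid(other)
        return SpectralCurve(self.wavelengths_nm, self.values + other.values)

    def __mul__(self, other):
        if isinstance(other, SpectralCurve):
            self._check_grid(other)
            return SpectralCurve(self.wavelengths_nm, self.values * other.values)
        return SpectralCurve(self.wavelengths_nm, self.values * float(other))

    __rmul__ = __mul__


def default_grid(lambda_min: float = 450.0, lambda_max: float = 750.0, step: float = 5.0) -> np.ndarray:
    """The working wavelength grid, 450-750 nm at 5 nm by default."""
    n = int(round((lambda_max - lambda_min) / step))
    return lambda_min + step * np.arange(n + 1)
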