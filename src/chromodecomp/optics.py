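"""Two-layer skin optics.

The skin is modeled as an epidermis that only absorbs (melanin) and a
semi-infinite dermis that absorbs (hemoglobin) and scatters (collagen /
elastin fibers).  Total reflectance follows the simplified two-flux
(Kubelka-Munk style) composition

    R(lambda) = T_epidermis(lambda)^2 * R_dermis(lambda),

i.e. light crosses the epidermis twice and is diffusely reflected once by
the dermis.

Absorption is a volume-fraction-weighted sum of chromophore extinction
spectra; reduced scattering is a Rayleigh + Mie power-law mixture.  The
dermis reflectance uses the standard diffusion-approximation closed form
for a semi-infinite medium with internal reflection at a relative
refractive index of 1.4 (see :func:`dermis_reflectance`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import DegenerateMediumError, DomainError, InvalidValueError
from .spectral import SpectralCurve

#: physiological volume-fraction bounds (dimensionless)
MELANIN_RANGE = (0.013, 0.43)
HEMOGLOBIN_RANGE = (0.02, 0.07)


@dataclass(frozen=True)
class ChromophoreState:
    """Volume fractions of the two chromophores.

    ``c_mel``/``c_hb`` are fixed concentration multipliers kept at 1.0: the
    extinction spectra shipped with the package are already scaled to
    absorption per unit volume fraction, so the fractions are the only free
    parameters.
    """

    f_mel: float
    f_hb: float
    c_mel: float = 1.0
    c_hb: float = 1.0


@dataclass(frozen=True)
class ScatteringParams:
    """Reduced-scattering power law: a, b_Mie, Rayleigh fraction, lambda0."""

    a: float = 45.0          # cm^-1 at the reference wavelength
    b_mie: float = 1.3       # Mie scattering power
    f_ray: float = 0.4       # fraction of scattering that is Rayleigh
    lambda0_nm: float = 500.0

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise InvalidValueError("scattering amplitude a must be positive")
        if not 0.0 <= self.f_ray <= 1.0:
            raise InvalidValueError("f_ray must lie in [0, 1]")


@dataclass(frozen=True)
class LayerConfig:
    """Epidermis path length and per-chromophore extinction spectra."""

    d_epi: float                      # epidermis optical path length, cm
    extinction_mel: SpectralCurve     # cm^-1 per unit melanin fraction
    extinction_hb: SpectralCurve      # cm^-1 per unit hemoglobin (blood) fraction

    def __post_init__(self) -> None:
        if self.d_epi <= 0:
            raise InvalidValueError("epidermis path length must be positive")


def clamp_fractions(f_mel_raw: float, f_hb_raw: float) -> ChromophoreState:
    """Clip raw fractions into the physiological boxes.

    Melanin is limited to 1.3-43 % and hemoglobin to 2-7 % of layer volume.
    """
    f_mel_raw = np.asarray(f_mel_raw, dtype=float)
    f_hb_raw = np.asarray(f_hb_raw, dtype=float)
    if not (np.all(np.isfinite(f_mel_raw)) and np.all(np.isfinite(f_hb_raw))):
        raise InvalidValueError("chromophore fractions must be finite")
    f_mel = np.clip(f_mel_raw, *MELANIN_RANGE)
    f_hb = np.clip(f_hb_raw, *HEMOGLOBIN_RANGE)
    return ChromophoreState(float(f_mel), float(f_hb))


def absorption_coefficient(
    state: ChromophoreState, extinctions: Mapping[str, SpectralCurve]
) -> SpectralCurve:
    """mu_a(lambda) = sum_i S_i * eps_i(lambda) * C_i over the chromophores.

    ``extinctions`` maps chromophore names (``"melanin"``, ``"hemoglobin"``)
    to extinction curves sharing one wavelength grid.
    """
    curves = list(extinctions.values())
    if not curves:
        raise InvalidValueError("no extinction curves supplied")
    grid = curves[0].wavelengths_nm
    for c in curves[1:]:
        curves[0]._check_grid(c)
    weights = {"melanin": state.f_mel * state.c_mel, "hemoglobin": state.f_hb * state.c_hb}
    total = np.zeros_like(grid)
    for name, curve in extinctions.items():
        if name not in weights:
            raise InvalidValueError(f"unknown chromophore {name!r}")
        total = total + weights[name] * curve.values
    return SpectralCurve(grid, total)


def reduced_scattering(params: ScatteringParams, grid: np.ndarray) -> SpectralCurve:
    """mu_s'(lambda) = a * (f_ray (l/l0)^-4 + (1-f_ray)(l/l0)^-b_mie)."""
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise DomainError("wavelengths must be positive")
    ratio = grid / params.lambda0_nm
    mus = params.a * (
        params.f_ray * ratio ** -4.0 + (1.0 - params.f_ray) * ratio ** -params.b_mie
    )
    return SpectralCurve(grid, mus)


def epidermis_transmittance(
    state: ChromophoreState, layers: LayerConfig, grid: np.ndarray
) -> SpectralCurve:
    """Beer-Lambert transmittance of the melanin-bearing epidermis.

    T(lambda) = exp(-f_mel * eps_mel(lambda) * d_epi); scattering in the thin
    epidermis is neglected (absorption-only layer).
    """
    grid = np.asarray(grid, dtype=float)
    eps = layers.extinction_mel.interp(grid)
    mu_a = state.f_mel * state.c_mel * eps
    return SpectralCurve(grid, np.exp(-mu_a * layers.d_epi))


# Internal-reflection parameter for the diffusion closed form.  The diffuse
# reflection coefficient r_d for a refractive-index mismatch n follows the
# Groenhuis polynomial fit; k = (1 + r_d) / (1 - r_d).
def _internal_reflection_k(n: float = 1.4) -> float:
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


_K_DEFAULT = _internal_reflection_k(1.4)


def dermis_reflectance(mu_a: SpectralCurve, mu_s_prime: SpectralCurve) -> SpectralCurve:
    """Semi-infinite diffusion-approximation reflectance of the dermis.

    Uses the closed form R = a' / (1 + 2k(1-a') + (1 + 2k/3) sqrt(3(1-a')))
    with transport albedo a' = mu_s' / (mu_a + mu_s') and internal-reflection
    parameter k for tissue refractive index 1.4.  The result depends on the
    absorption/scattering ratio only, equals 1 for a lossless half-space and
    decreases monotonically to 0 as absorption dominates.
    """
    mu_a._check_grid(mu_s_prime)
    if np.any(mu_s_prime.values <= 0):
        raise DegenerateMediumError("reduced scattering must be strictly positive")
    if np.any(mu_a.values < 0):
        raise DomainError("absorption coefficient must be non-negative")
    albedo = mu_s_prime.values / (mu_a.values + mu_s_prime.values)
    k = _K_DEFAULT
    r = albedo / (1.0 + 2.0 * k * (1.0 - albedo) + (1.0 + 2.0 * k / 3.0) * np.sqrt(3.0 * (1.0 - albedo)))
    return SpectralCurve(mu_a.wavelengths_nm, r)


def skin_reflectance(
    state: ChromophoreState,
    layers: LayerConfig,
    scattering: ScatteringParams,
    grid: np.ndarray,
) -> SpectralCurve:
    """Total reflectance R = T_epidermis^2 * R_dermis on ``grid``."""
    grid = np.asarray(grid, dtype=float)
    t_epi = epidermis_transmittance(state, layers, grid)
    eps_hb = SpectralCurve(grid, layers.extinction_hb.interp(grid))
    mu_a_dermis = SpectralCurve(grid, state.f_hb * state.c_hb * eps_hb.values)
    mu_s = reduced_scattering(scattering, grid)
    r_dermis = dermis_reflectance(mu_a_dermis, mu_s)
    return SpectralCurve(grid, t_epi.values**2 * r_dermis.values)


@dataclass(frozen=True)
class OpticsConfig:
    """Layer geometry + scattering law + blood oxygenation, bundled."""

    layers: LayerConfig
    scattering: ScatteringParams = ScatteringParams()
    oxygen_saturation: float = 0.7


def default_optics(
    d_epi: float = 0.006,
    oxygen_saturation: float = 0.7,
    scattering: ScatteringParams | None = None,
) -> OpticsConfig:
    """Default optical configuration built from the bundled extinction spectra.

    d_epi is the epidermal optical path length in cm (default 60 um).
    """
    from . import data as _data

    layers = LayerConfig(
        d_epi=d_epi,
        extinction_mel=_data.load_extinction_melanin(),
        extinction_hb=_data.load_extinction_hemoglobin(oxygen_saturation),
    )
    return OpticsConfig(layers=layers, scattering=scattering or ScatteringParams(),
                        oxygen_saturation=oxygen_saturation)
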