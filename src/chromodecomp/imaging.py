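"""Camera image formation and color pipeline.

Renders device-RGB images from spectral reflectance by quadrature of
L(lambda) * R(lambda) * C_m(lambda) over the integration band, then takes
them to sRGB through white balance, a camera->XYZ transform fitted on a
virtual ColorChecker, the standard XYZ->linear-RGB matrix, and a pure
power-law gamma transfer (exponent 2.4 with the 0.055 offset, no linear
toe segment).

Pixel images are (H, W, 3) float arrays wrapped in :class:`LinearImage`
with a color-space tag; operations check the tag so stages cannot be
chained out of order.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import data as _data
from .errors import (
    BandCoverageError,
    DegenerateProfileError,
    DomainError,
    FitDegenerateError,
    InvalidValueError,
    ShapeError,
    SpaceError,
)
from .maps import ChromophoreMaps
from .optics import OpticsConfig, reduced_scattering
from .spectral import SpectralCurve, default_grid

GAMMA_EXP = 2.4
GAMMA_OFFSET = 0.055

#: sRGB linear-RGB <-> XYZ (D65 white), IEC 61966-2-1
XYZ_TO_RGB = np.array(
    [
        [3.2406, -1.5372, -0.4986],
        [-0.9689, 1.8758, 0.0415],
        [0.0557, -0.2040, 1.0570],
    ]
)
RGB_TO_XYZ = np.linalg.inv(XYZ_TO_RGB)
#: XYZ of the working-space white, exactly consistent with XYZ_TO_RGB
WORKING_WHITE_XYZ = RGB_TO_XYZ @ np.ones(3)

SPACES = ("camera", "camera_wb", "xyz", "rgb_linear", "srgb")


@dataclass
class LinearImage:
    """A 3-channel pixel array plus the color space it lives in."""

    pixels: np.ndarray
    space: str = "rgb_linear"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError("image must be (H, W, 3)")
        if self.space not in SPACES:
            raise SpaceError(f"unknown color space tag {self.space!r}")
        if self.space == "srgb" and (px.min() < -1e-9 or px.max() > 1 + 1e-9):
            raise InvalidValueError("srgb images must be bounded in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def require_space(self, space: str) -> None:
        if self.space != space:
            raise SpaceError(f"expected a {space!r}-space image, got {self.space!r}")


@dataclass(frozen=True)
class AcquisitionProfile:
    """Everything image formation needs: SPD, sensitivities, band, white point.

    All curves are resampled to one grid over [lambda_min, lambda_max] at
    ``step_nm``.  ``white_response`` is the per-channel quadrature of
    L(lambda) * C_m(lambda) — the camera's response to the bare light source.
    """

    spd: SpectralCurve
    sensitivity_r: SpectralCurve
    sensitivity_g: SpectralCurve
    sensitivity_b: SpectralCurve
    lambda_min_nm: float = 450.0
    lambda_max_nm: float = 750.0
    step_nm: float = 5.0

    def __post_init__(self) -> None:
        grid = default_grid(self.lambda_min_nm, self.lambda_max_nm, self.step_nm)
        for name in ("spd", "sensitivity_r", "sensitivity_g", "sensitivity_b"):
            curve: SpectralCurve = getattr(self, name)
            if not curve.covers(self.lambda_min_nm, self.lambda_max_nm):
                raise BandCoverageError(f"{name} does not cover the integration band")
            object.__setattr__(self, name, curve.on_grid(grid))

    @property
    def grid(self) -> np.ndarray:
        return self.spd.wavelengths_nm

    @property
    def sensitivities(self) -> np.ndarray:
        """(3, n_wl) array of the r/g/b sensitivity curves."""
        return np.stack(
            [self.sensitivity_r.values, self.sensitivity_g.values, self.sensitivity_b.values]
        )

    @property
    def white_response(self) -> np.ndarray:
        return np.trapezoid(self.spd.values * self.sensitivities, self.grid, axis=1)


def load_profile(directory: str | Path) -> "AcquisitionProfile":
    """Read a profile bundle: spd.csv, sensitivity_{r,g,b}.csv, optional meta.yaml."""
    directory = Path(directory)
    kwargs = {}
    meta = directory / "meta.yaml"
    if meta.exists():
        with open(meta) as fh:
            cfg = yaml.safe_load(fh) or {}
        for key in ("lambda_min_nm", "lambda_max_nm", "step_nm"):
            if key in cfg:
                kwargs[key] = float(cfg[key])
    profile = AcquisitionProfile(
        spd=SpectralCurve.from_csv(directory / "spd.csv"),
        sensitivity_r=SpectralCurve.from_csv(directory / "sensitivity_r.csv"),
        sensitivity_g=SpectralCurve.from_csv(directory / "sensitivity_g.csv"),
        sensitivity_b=SpectralCurve.from_csv(directory / "sensitivity_b.csv"),
        **kwargs,
    )
    return normalize_profile(profile)


def default_profile() -> "AcquisitionProfile":
    """The bundled D65-like illuminant with synthetic DSLR-like sensitivities."""
    return load_profile(_data.default_profile_dir())


def normalize_profile(profile: AcquisitionProfile) -> AcquisitionProfile:
    """Rescale the SPD so the maximum channel white response equals 1.

    The scaling factor is the response of the most sensitive channel to the
    bare light source; dividing by it makes renders of a perfect reflector
    peak at 1.  Idempotent and invariant to SPD scale.
    """
    peak = profile.white_response.max()
    if peak <= 0:
        raise DegenerateProfileError("light source produces no camera response")
    return replace(profile, spd=profile.spd * (1.0 / peak))


def camera_response(reflectance: SpectralCurve, profile: AcquisitionProfile) -> np.ndarray:
    """Per-channel trapezoidal quadrature of L * R * C_m over the band."""
    r = reflectance.interp(profile.grid)
    return np.trapezoid(profile.spd.values * r * profile.sensitivities, profile.grid, axis=1)


def camera_response_many(reflectances: np.ndarray, profile: AcquisitionProfile) -> np.ndarray:
    """Vectorized :func:`camera_response` for an (..., n_wl) reflectance stack."""
    reflectances = np.asarray(reflectances, dtype=float)
    if reflectances.shape[-1] != profile.grid.size:
        raise BandCoverageError("reflectance stack is not on the profile grid")
    integrand = reflectances[..., None, :] * (profile.spd.values * profile.sensitivities)
    return np.trapezoid(integrand, profile.grid, axis=-1)


def form_image(
    maps: ChromophoreMaps,
    profile: AcquisitionProfile,
    optics: OpticsConfig,
    chunk_rows: int = 64,
) -> LinearImage:
    """Render a camera-space image from chromophore maps by exact quadrature.

    Per pixel: I_m = shading * integral(L R C_m) + specular * l_m, i.e. a
    diffuse term carrying the skin reflectance spectrum scaled by the shading
    map, plus a specular term with the bare light-source color.
    """
    maps.validate_ranges()
    grid = profile.grid
    eps_mel = optics.layers.extinction_mel.interp(grid)
    eps_hb = optics.layers.extinction_hb.interp(grid)
    mu_s = reduced_scattering(optics.scattering, grid)
    h, w = maps.shape
    out = np.empty((h, w, 3))
    white = profile.white_response
    for r0 in range(0, h, chunk_rows):
        r1 = min(r0 + chunk_rows, h)
        fm = maps.mel_map[r0:r1, :, None]
        fh = maps.hb_map[r0:r1, :, None]
        t_epi = np.exp(-fm * eps_mel * optics.layers.d_epi)
        mu_a = fh * eps_hb
        albedo = mu_s.values / (mu_a + mu_s.values)
        from .optics import _K_DEFAULT as k
        r_dermis = albedo / (
            1.0 + 2.0 * k * (1.0 - albedo) + (1.0 + 2.0 * k / 3.0) * np.sqrt(3.0 * (1.0 - albedo))
        )
        refl = t_epi**2 * r_dermis
        diffuse = camera_response_many(refl, profile)
        out[r0:r1] = (
            maps.shading_map[r0:r1, :, None] * diffuse
            + maps.specular_map[r0:r1, :, None] * white
        )
    return LinearImage(out, space="camera")


def white_balance(image: LinearImage, profile: AcquisitionProfile) -> LinearImage:
    """Divide each channel by the camera's response to the bare light source."""
    image.require_space("camera")
    lm = profile.white_response
    if np.any(lm <= 0):
        raise DegenerateProfileError("white response has a non-positive channel")
    return LinearImage(image.pixels / lm, space="camera_wb")


# --- virtual ColorChecker ----------------------------------------------------

def _expand(rgb: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix rows: degree 1 = [r,g,b]; degree 2 adds root-polynomial
    cross terms sqrt(rg), sqrt(gb), sqrt(rb) (exposure-invariant)."""
    rgb = np.asarray(rgb, dtype=float)
    if degree == 1:
        return rgb
    if degree == 2:
        r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
        extra = np.stack([np.sqrt(r * g), np.sqrt(g * b), np.sqrt(r * b)], axis=-1)
        return np.concatenate([rgb, extra], axis=-1)
    raise InvalidValueError("polynomial degree must be 1 or 2")


@dataclass(frozen=True)
class ColorTransform:
    """White-balanced camera RGB -> XYZ map plus the fixed XYZ -> RGB matrix."""

    matrix: np.ndarray          # (3, n_terms) camera -> XYZ
    degree: int = 1
    residual_rms: float = 0.0
    xyz_to_rgb: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.xyz_to_rgb is None:
            object.__setattr__(self, "xyz_to_rgb", XYZ_TO_RGB)

    def camera_to_xyz(self, rgb: np.ndarray) -> np.ndarray:
        return _expand(rgb, self.degree) @ self.matrix.T


def xyz_response(reflectance: SpectralCurve, profile: AcquisitionProfile) -> np.ndarray:
    """CIE 1931 2-degree XYZ of a surface under the profile's illuminant,
    normalized so the illuminant's Y equals 1."""
    xbar, ybar, zbar = _data.load_cie_observer()
    grid = profile.grid
    cmf = np.stack([xbar.interp(grid), ybar.interp(grid), zbar.interp(grid)])
    r = reflectance.interp(grid)
    raw = np.trapezoid(profile.spd.values * r * cmf, grid, axis=1)
    norm = np.trapezoid(profile.spd.values * cmf[1], grid)
    return raw / norm


def build_virtual_colorchecker_transform(
    profile: AcquisitionProfile,
    checker_reflectances: Sequence[SpectralCurve] | None = None,
    degree: int = 1,
) -> ColorTransform:
    """Fit the camera->XYZ transform on a simulated 24-patch chart.

    Camera RGB (white balanced) and XYZ tristimulus values are computed for
    every patch spectrum under the profile's own illuminant; the map between
    them is a least-squares (root-)polynomial fit.  The fitted matrix is then
    rescaled per XYZ row so the profile's white point lands exactly on the
    working-space white, which keeps the downstream sRGB conversion neutral
    for the light source.
    """
    if checker_reflectances is None:
        checker_reflectances = _data.load_colorchecker()
    lm = profile.white_response
    if np.any(lm <= 0):
        raise DegenerateProfileError("white response has a non-positive channel")
    cam = np.array([camera_response(r, profile) / lm for r in checker_reflectances])
    if not np.all(np.isfinite(cam)) or np.allclose(cam, 0.0):
        raise FitDegenerateError("checker patches produce no usable camera signal")
    # chromatic adaptation: scale XYZ targets channelwise so the profile's
    # illuminant lands on the working-space (sRGB/D65) white
    illuminant_white = xyz_response(
        SpectralCurve.constant(profile.grid, 1.0), profile
    )
    adapt = WORKING_WHITE_XYZ / illuminant_white
    xyz = np.array(
        [xyz_response(r, profile) * adapt for r in checker_reflectances]
    )
    design = _expand(cam, degree)
    # rank-deficient charts (e.g. the neutral-patch subset) fall back to the
    # minimum-norm least-squares solution, which still maps grays correctly
    coef, *_ = np.linalg.lstsq(design, xyz, rcond=None)
    matrix = coef.T  # (3, n_terms)
    # force white exactly: wb'd white point is (1,...,1) in expanded coords
    white_in = _expand(np.ones(3), degree)
    predicted_white = matrix @ white_in
    if np.any(predicted_white <= 0):
        raise FitDegenerateError("fitted transform maps white outside the gamut")
    matrix = (WORKING_WHITE_XYZ / predicted_white)[:, None] * matrix
    resid = _expand(cam, degree) @ matrix.T - xyz
    rms = float(np.sqrt(np.mean(resid**2)))
    return ColorTransform(matrix=matrix, degree=degree, residual_rms=rms)


def apply_color_transform(image: LinearImage, t: ColorTransform) -> LinearImage:
    """camera_wb -> XYZ -> linear RGB."""
    image.require_space("camera_wb")
    xyz = t.camera_to_xyz(image.pixels)
    rgb = xyz @ t.xyz_to_rgb.T
    return LinearImage(rgb, space="rgb_linear")


# --- gamma transfer ----------------------------------------------------------

def gamma_encode(image: LinearImage | np.ndarray) -> LinearImage:
    """I_srgb = 1.055 * I_rgb^(1/2.4) - 0.055, clipped to [0, 1]."""
    arr, was_image = _as_array(image, "rgb_linear")
    if np.any(arr < 0):
        raise DomainError("gamma encode requires non-negative input")
    enc = np.clip((1 + GAMMA_OFFSET) * arr ** (1.0 / GAMMA_EXP) - GAMMA_OFFSET, 0.0, 1.0)
    return LinearImage(enc, space="srgb") if was_image else enc


def gamma_decode(image: LinearImage | np.ndarray) -> LinearImage:
    """I_rgb = ((I_srgb + 0.055) / 1.055)^2.4."""
    arr, was_image = _as_array(image, "srgb")
    if np.any(arr < 0):
        raise DomainError("gamma decode requires non-negative input")
    dec = ((arr + GAMMA_OFFSET) / (1 + GAMMA_OFFSET)) ** GAMMA_EXP
    return LinearImage(dec, space="rgb_linear") if was_image else dec


def _as_array(image, space: str):
    if isinstance(image, LinearImage):
        image.require_space(space)
        return image.pixels, True
    return np.asarray(image, dtype=float), False


# --- image file I/O ----------------------------------------------------------

def read_image(path: str | Path) -> LinearImage:
    """Read a PNG (8-bit) or TIFF (16-bit) file; sRGB encoding assumed."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    arr = arr[:, :, :3]
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    return LinearImage(arr.astype(float) / scale, space="srgb")


def write_image(path: str | Path, image: LinearImage, bits: int = 8) -> None:
    import imageio.v3 as iio

    image.require_space("srgb")
    px = np.clip(image.pixels, 0.0, 1.0)
    if bits == 8:
        iio.imwrite(path, np.round(px * 255.0).astype(np.uint8))
    elif bits == 16:
        iio.imwrite(path, np.round(px * 65535.0).astype(np.uint16))
    else:
        raise InvalidValueError("bits must be 8 or 16")
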