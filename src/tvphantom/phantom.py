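"""Digital Jaszczak phantom: rendering, system blur, bias field and noise.

The Jaszczak phantom is the standard nuclear-medicine quality-control
cylinder: a uniform activity disk (in 2-D section) containing six pie-slice
sectors of cold rods with graded diameters. This module rasterizes that
geometry, applies a Gaussian system point-spread function (the source of the
partial-volume effect), multiplies in a smooth acquisition non-uniformity
field (the knob that distinguishes a more uniform "CAIPI-like" acquisition
from a less uniform "GRAPPA-like" one), and finally degrades the image with
additive zero-mean Gaussian noise on the [0, 1] intensity scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .image import Image

#: FWHM of a Gaussian equals this constant times its standard deviation.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...

#: Standard commercial Jaszczak cold-rod diameters (mm), smallest to largest.
DEFAULT_ROD_DIAMETERS_MM = (4.8, 6.4, 7.9, 9.5, 11.1, 12.7)

#: Rod centre-to-centre pitch as a multiple of rod diameter (standard insert).
DEFAULT_ROD_SPACING_FACTOR = 2.0

#: Offset added to the base seed to derive the bias-field stream, so the bias
#: white noise never coincides with a replicate noise stream (replicate seeds
#: are base_seed + replicate_index).
BIAS_SEED_OFFSET = 1_000_003


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of the digital Jaszczak phantom.

    Attributes
    ----------
    grid_size : int
        Pixels per side of the square image.
    pixel_mm : float
        Physical pixel pitch in mm.
    cylinder_radius_mm : float
        Radius of the uniform activity disk.
    rod_sectors : tuple of (float, float)
        One ``(rod_diameter_mm, rod_spacing_factor)`` pair per pie-slice
        sector; the pitch between rod centres is ``factor * diameter``.
    activity_in, activity_out : float
        Intensity inside active regions / background outside the cylinder.
    rods_cold : bool
        True (default): rods are zero-activity inclusions in a hot cylinder.
    center_clear_radius_mm : float
        Rod-free radius around the phantom axis (the clear hub of the rod
        insert); sized to twice the default reference-ROI radius so the
        reference region stays uniform under blur and denoising.
    """

    grid_size: int = 256
    pixel_mm: float = 2.0
    cylinder_radius_mm: float = 100.0
    rod_sectors: tuple[tuple[float, float], ...] = tuple(
        (d, DEFAULT_ROD_SPACING_FACTOR) for d in DEFAULT_ROD_DIAMETERS_MM
    )
    activity_in: float = 1.0
    activity_out: float = 0.0
    rods_cold: bool = True
    center_clear_radius_mm: float = 32.0

    def __post_init__(self) -> None:
        if self.grid_size < 2:
            raise ConfigurationError(f"grid_size must be >= 2, got {self.grid_size}")
        if self.pixel_mm <= 0:
            raise ConfigurationError(f"pixel_mm must be positive, got {self.pixel_mm}")
        half_fov = self.grid_size * self.pixel_mm / 2.0
        if not (0 < self.cylinder_radius_mm < half_fov):
            raise ConfigurationError(
                f"cylinder_radius_mm={self.cylinder_radius_mm} must lie in "
                f"(0, {half_fov}) so the cylinder fits in the grid"
            )
        diameters = [d for d, _ in self.rod_sectors]
        if any(d <= 0 for d in diameters):
            raise ConfigurationError("rod diameters must be strictly positive")
        if len(set(diameters)) != len(diameters):
            raise ConfigurationError("rod diameters must be distinct across sectors")
        if any(f <= 1 for _, f in self.rod_sectors):
            raise ConfigurationError("rod spacing factors must exceed 1 (rods must not touch)")
        if not self.activity_in > self.activity_out >= 0:
            raise ConfigurationError(
                f"need activity_in > activity_out >= 0, got "
                f"{self.activity_in} / {self.activity_out}"
            )
        if self.center_clear_radius_mm < 0:
            raise ConfigurationError("center_clear_radius_mm must be >= 0")


@dataclass(frozen=True)
class AcquisitionProfile:
    """Acquisition-uniformity profile of an attenuation-corrected PET image.

    ``bias_amplitude`` is the peak-to-mean relative amplitude of a smooth
    multiplicative non-uniformity field; the shipped "caipi_like" profile is
    more uniform (smaller amplitude) than "grappa_like", emulating the
    ordering of MR-AC Dixon-CAIPIRINHA versus Dixon-GRAPPA derived PET
    images. ``psf_fwhm_mm`` is the Gaussian system-blur FWHM.
    """

    name: str
    bias_amplitude: float
    bias_length_mm: float = 60.0
    psf_fwhm_mm: float = 4.0

    def __post_init__(self) -> None:
        if self.bias_amplitude < 0:
            raise ConfigurationError("bias_amplitude must be >= 0")
        if self.bias_length_mm <= 0:
            raise ConfigurationError("bias_length_mm must be positive")
        if self.psf_fwhm_mm < 0:
            raise ConfigurationError("psf_fwhm_mm must be >= 0")


def default_profiles() -> tuple[AcquisitionProfile, AcquisitionProfile]:
    """The two shipped acquisition profiles (more vs less uniform)."""
    return (
        AcquisitionProfile(name="caipi_like", bias_amplitude=0.02),
        AcquisitionProfile(name="grappa_like", bias_amplitude=0.08),
    )


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise on the [0, 1] normalized intensity scale."""

    variance: float = 0.001
    mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ConfigurationError(f"noise variance must be >= 0, got {self.variance}")


# ---------------------------------------------------------------------------
# rod layout


@dataclass(frozen=True)
class SectorLayout:
    """Placed rod centres for one pie-slice sector (phantom-centred mm)."""

    index: int
    rod_diameter_mm: float
    pitch_mm: float
    centers_mm: tuple[tuple[float, float], ...]  # (x, y) pairs

    @property
    def n_rods(self) -> int:
        return len(self.centers_mm)


def rod_layout(spec: PhantomSpec) -> list[SectorLayout]:
    """Place rods on a triangular lattice inside each pie-slice sector.

    Each sector spans an equal wedge of the cylinder. Rods are kept only if
    the full rod circle stays inside the cylinder wall, outside the clear
    central hub, and clear of both wedge boundary lines (leaving the visible
    uniform lanes between sectors that the physical insert has).

    Raises
    ------
    ConfigurationError
        If a sector's diameter/spacing admits no rod inside the cylinder,
        naming the offending sector.
    """
    n_sectors = len(spec.rod_sectors)
    layouts: list[SectorLayout] = []
    if n_sectors == 0:
        return layouts
    wedge = 2.0 * math.pi / n_sectors
    R = spec.cylinder_radius_mm
    for k, (diameter, factor) in enumerate(spec.rod_sectors):
        pitch = factor * diameter
        r_rod = diameter / 2.0
        lane = (pitch - diameter) / 2.0  # half-gap kept from wedge boundaries
        theta0 = k * wedge
        theta1 = (k + 1) * wedge
        bis = 0.5 * (theta0 + theta1)
        ux, uy = math.cos(bis), math.sin(bis)  # along the sector bisector
        vx, vy = -uy, ux
        row_step = pitch * math.sqrt(3.0) / 2.0
        n_rows = int(R / row_step) + 2
        n_cols = int(R / pitch) + 2
        centers: list[tuple[float, float]] = []
        for i in range(n_rows):
            a = i * row_step
            off = 0.5 * pitch if i % 2 else 0.0
            for j in range(-n_cols, n_cols + 1):
                b = j * pitch + off
                x = a * ux + b * vx
                y = a * uy + b * vy
                rho = math.hypot(x, y)
                if rho + r_rod > R - pitch / 2.0:
                    continue
                if rho - r_rod < spec.center_clear_radius_mm:
                    continue
                ang = math.atan2(y, x) % (2.0 * math.pi)
                # angular membership, tolerant at the wrap point
                rel = (ang - theta0) % (2.0 * math.pi)
                if rel >= wedge:
                    continue
                d0 = rho * abs(math.sin(ang - theta0))
                d1 = rho * abs(math.sin(theta1 - ang))
                if d0 < r_rod + lane or d1 < r_rod + lane:
                    continue
                centers.append((x, y))
        if not centers:
            raise ConfigurationError(
                f"rod sector {k} (diameter {diameter} mm, spacing factor {factor}) "
                f"places no rods inside the cylinder"
            )
        centers.sort()
        layouts.append(
            SectorLayout(index=k, rod_diameter_mm=diameter, pitch_mm=pitch,
                         centers_mm=tuple(centers))
        )
    return layouts


# ---------------------------------------------------------------------------
# rendering and degradation stages


def render_phantom(spec: PhantomSpec, supersample: int = 4) -> Image:
    """Rasterize the noise-free phantom with area-weighted anti-aliasing.

    Every pixel is split into ``supersample x supersample`` sub-pixels; the
    pixel value is the area fraction of each region times its activity, so
    boundary pixels take intermediate values.
    """
    if supersample < 1:
        raise ConfigurationError("supersample must be >= 1")
    G = spec.grid_size
    s = supersample
    # sub-pixel centre positions, in pixel units then physical mm,
    # with the phantom axis at the grid centre
    pos = (np.arange(G * s) + 0.5) / s - 0.5
    phys = (pos - (G - 1) / 2.0) * spec.pixel_mm
    X = phys[np.newaxis, :]  # columns -> x
    Y = phys[:, np.newaxis]  # rows -> y
    in_cyl = (X * X + Y * Y) <= spec.cylinder_radius_mm**2

    in_rod = np.zeros_like(in_cyl)
    half_extent = (G - 1) / 2.0 * spec.pixel_mm
    scale = 1.0 / (spec.pixel_mm / s)  # mm -> fine-grid index units
    for sector in rod_layout(spec):
        r = sector.rod_diameter_mm / 2.0
        for (cx, cy) in sector.centers_mm:
            # bounding box in fine-grid indices to avoid full-grid work
            lo_c = max(0, int((cx - r + half_extent) * scale) - 1)
            hi_c = min(G * s, int((cx + r + half_extent) * scale) + 2)
            lo_r = max(0, int((cy - r + half_extent) * scale) - 1)
            hi_r = min(G * s, int((cy + r + half_extent) * scale) + 2)
            sub_x = phys[lo_c:hi_c][np.newaxis, :]
            sub_y = phys[lo_r:hi_r][:, np.newaxis]
            in_rod[lo_r:hi_r, lo_c:hi_c] |= (
                (sub_x - cx) ** 2 + (sub_y - cy) ** 2 <= r * r
            )

    if spec.rods_cold:
        hot = in_cyl & ~in_rod
    else:
        hot = in_cyl
    fine = np.where(hot, spec.activity_in, spec.activity_out)
    values = fine.reshape(G, s, G, s).mean(axis=(1, 3))
    return Image(values=values, pixel_mm=spec.pixel_mm, provenance="render")


def apply_system_blur(img: Image, psf_fwhm_mm: float) -> Image:
    """Convolve with the isotropic Gaussian system PSF (replicate boundary).

    This is the stage that produces the partial-volume effect: apparent
    activity loss in structures small relative to the PSF. A FWHM of zero is
    the identity.
    """
    if psf_fwhm_mm < 0:
        raise ConfigurationError("psf_fwhm_mm must be >= 0")
    if psf_fwhm_mm == 0:
        return img.with_values(img.values.copy(), stage="blur(fwhm=0)")
    sigma_px = psf_fwhm_mm / FWHM_PER_SIGMA / img.pixel_mm
    out = ndimage.gaussian_filter(img.values, sigma=sigma_px, mode="nearest")
    return img.with_values(out, stage=f"blur(fwhm={psf_fwhm_mm}mm)")


def bias_field(shape: tuple[int, int], profile: AcquisitionProfile,
               pixel_mm: float, seed: int) -> np.ndarray:
    """Smooth multiplicative non-uniformity field ``b`` with ``max|b|`` equal
    to the profile amplitude.

    White Gaussian noise is smoothed with a Gaussian kernel of FWHM
    ``bias_length_mm`` (the correlation length) and affinely mapped so the
    field is zero at its maximum and ``-bias_amplitude`` at its minimum:
    the field models regional *signal loss* from imperfect MR-based
    attenuation correction, normalized so the best-corrected region retains
    full intensity. A constant multiplicative offset would be
    indistinguishable from a change in injected activity, so anchoring the
    field at zero makes profiles differ in non-uniformity, not in global
    calibration.
    """
    if profile.bias_amplitude == 0:
        return np.zeros(shape)
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(shape)
    sigma_px = profile.bias_length_mm / FWHM_PER_SIGMA / pixel_mm
    g = ndimage.gaussian_filter(white, sigma=sigma_px, mode="nearest")
    span = g.max() - g.min()
    if span == 0:  # pathological (e.g. tiny grid); treat as uniform
        return np.zeros(shape)
    return profile.bias_amplitude * (g - g.max()) / span


def apply_bias_field(img: Image, profile: AcquisitionProfile, seed: int) -> Image:
    """Multiply the image by ``1 + b`` for the profile's non-uniformity field.

    ``bias_amplitude = 0`` returns the input unchanged; the same seed always
    yields the same field.
    """
    b = bias_field(img.shape, profile, img.pixel_mm, seed)
    return img.with_values(img.values * (1.0 + b),
                           stage=f"bias({profile.name}, a={profile.bias_amplitude})")


def add_gaussian_noise(img: Image, noise: NoiseSpec) -> Image:
    """Add i.i.d. Gaussian noise on the [0, 1] normalized intensity scale.

    If the input exceeds 1, it is first divided by its maximum and the scale
    is recorded in the provenance; all downstream statistics are computed on
    that normalized scale. Values are deliberately NOT clipped: clipping
    would truncate the Gaussian and bias ROI means and standard deviations.
    """
    if noise.variance < 0:
        raise ConfigurationError("noise variance must be >= 0")
    values = img.values
    stage = f"noise(var={noise.variance}, seed={noise.seed})"
    vmax = values.max()
    if vmax > 1.0:
        values = values / vmax
        stage += f" [rescaled by 1/{vmax:.6g}]"
    if noise.variance == 0 and noise.mean == 0:
        return img.with_values(values.copy(), stage=stage)
    rng = np.random.default_rng(noise.seed)
    e = rng.normal(loc=noise.mean, scale=math.sqrt(noise.variance), size=values.shape)
    return img.with_values(values + e, stage=stage)
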