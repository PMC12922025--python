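"""Display geometry and Gabor-plus-noise stimulus synthesis.

An orientation-discrimination trial presents a Gabor patch — a sinusoidal
luminance grating windowed by an isotropic Gaussian envelope — on a uniform
mid-grey background, optionally corrupted by zero-mean Gaussian luminance
noise.  This module models the physical side of that display: converting a
monitor's specification into degrees of visual angle, rendering the Gabor in
luminance units (cd/m²), and injecting seeded external noise whose amplitude
is controlled by a multiplicative scale factor.

Conventions
-----------
Coordinates are in degrees of visual angle with the origin at the patch
centre, x rightward and y upward.  Orientation ``theta`` is measured from
vertical, clockwise positive.  Luminance is clipped to the displayable range
``[0, 2 * background]`` after noise injection; the clipped fraction is
recorded in the image metadata rather than silently discarded.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path

import numpy as np

__all__ = [
    "GeometryError",
    "DisplayGeometry",
    "GaborParams",
    "NoiseSpec",
    "StimulusImage",
    "visual_extent",
    "pixels_per_degree",
    "render_gabor",
    "apply_external_noise",
    "save_stimulus",
    "load_stimulus",
]

CM_PER_INCH = 2.54


class GeometryError(ValueError):
    """Raised when a display geometry cannot yield a visual angle."""


@dataclasses.dataclass(frozen=True)
class DisplayGeometry:
    """Physical monitor specification used to derive visual angles.

    Defaults describe a 24.5-inch 16:9 panel at 1920x1080 viewed from
    100 cm over a 50 cd/m² background.
    """

    diagonal_inches: float = 24.5
    aspect_w: int = 16
    aspect_h: int = 9
    res_x: int = 1920
    res_y: int = 1080
    viewing_distance_cm: float = 100.0
    background_luminance: float = 50.0

    def __post_init__(self) -> None:
        if self.diagonal_inches < 0:
            raise GeometryError("diagonal must be non-negative")
        if self.viewing_distance_cm <= 0:
            raise GeometryError("viewing distance must be positive")
        for name in ("aspect_w", "aspect_h", "res_x", "res_y"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.background_luminance <= 0:
            raise GeometryError("background luminance must be positive")
        aspect = self.aspect_w / self.aspect_h
        pixel_aspect = self.res_x / self.res_y
        if abs(aspect - pixel_aspect) / pixel_aspect > 0.05:
            raise GeometryError(
                "aspect ratio inconsistent with pixel resolution: "
                f"{aspect:.3f} vs {pixel_aspect:.3f}"
            )

    @property
    def width_cm(self) -> float:
        diag_cm = self.diagonal_inches * CM_PER_INCH
        norm = math.hypot(self.aspect_w, self.aspect_h)
        return diag_cm * self.aspect_w / norm

    @property
    def height_cm(self) -> float:
        diag_cm = self.diagonal_inches * CM_PER_INCH
        norm = math.hypot(self.aspect_w, self.aspect_h)
        return diag_cm * self.aspect_h / norm


def visual_extent(display: DisplayGeometry) -> tuple[float, float]:
    """Full horizontal and vertical visual extent of the display, in degrees.

    Each extent is ``2 * atan(half physical extent / viewing distance)``, the
    exact (not small-angle) visual angle subtended at the eye.
    """
    d = display.viewing_distance_cm
    h = 2.0 * math.degrees(math.atan(display.width_cm / (2.0 * d)))
    v = 2.0 * math.degrees(math.atan(display.height_cm / (2.0 * d)))
    return h, v


def pixels_per_degree(display: DisplayGeometry) -> float:
    """Horizontal sampling density in pixels per degree of visual angle."""
    h, _ = visual_extent(display)
    if h <= 0:
        raise GeometryError("display has zero horizontal extent")
    return display.res_x / h


@dataclasses.dataclass(frozen=True)
class GaborParams:
    """Parameters of the oriented Gabor carrier and envelope.

    ``orientation_deg`` is signed tilt from vertical (clockwise positive).
    ``envelope_sigma_deg`` is the Gaussian envelope SD — a spatial quantity,
    not to be confused with the psychometric threshold sigma.
    """

    orientation_deg: float = 0.0
    spatial_freq_cpd: float = 3.0
    envelope_sigma_deg: float = 0.7
    phase_rad: float = 0.0
    michelson_contrast: float = 0.70

    def __post_init__(self) -> None:
        vals = dataclasses.astuple(self)
        if not all(np.isfinite(vals)):
            raise ValueError("Gabor parameters must be finite")
        if self.spatial_freq_cpd <= 0:
            raise ValueError("spatial frequency must be positive")
        if self.envelope_sigma_deg <= 0:
            raise ValueError("envelope sigma must be positive")
        if not 0.0 <= self.michelson_contrast <= 1.0:
            raise ValueError("Michelson contrast must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """External luminance-noise specification.

    ``scale_factor`` multiplies the base noise SD; the experiment uses
    0.5 / 1.5 / 3.0 for the low / medium / high conditions.  ``base_sd`` is
    expressed in Michelson-contrast units of the background.
    """

    scale_factor: float = 1.0
    base_sd: float = 0.10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.scale_factor < 0:
            raise ValueError("scale factor must be non-negative")
        if self.base_sd < 0:
            raise ValueError("base noise SD must be non-negative")


@dataclasses.dataclass
class StimulusImage:
    """A rendered stimulus patch: square luminance grid plus placement."""

    pixels: np.ndarray
    pixels_per_degree: float
    eccentricity_deg: float = 0.0
    background_luminance: float = 50.0
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixel grid must be square")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixel values must be finite")
        if self.pixels_per_degree <= 0:
            raise ValueError("pixels_per_degree must be positive")

    @property
    def extent_deg(self) -> float:
        return self.pixels.shape[0] / self.pixels_per_degree


def render_gabor(
    params: GaborParams,
    grid_extent_deg: float = 4.2,
    ppd: float = 63.0,
    background_luminance: float = 50.0,
    eccentricity_deg: float = 0.0,
) -> StimulusImage:
    """Render a Gabor patch into a luminance image.

    The luminance at point ``(x, y)`` degrees is::

        L(x, y) = L_bg * (1 + C * exp(-(x'^2 + y'^2) / (2 sigma^2))
                              * cos(2 pi f x' + phi))

    with rotated coordinates ``x' = x cos(theta) + y sin(theta)`` and
    ``y' = -x sin(theta) + y cos(theta)``.  The grid is sampled at ``ppd``
    pixels per degree and made odd-sized so that the exact centre pixel sits
    at the origin; a warning is raised if the grid does not span at least six
    envelope SDs.
    """
    if not (np.isfinite(grid_extent_deg) and grid_extent_deg > 0):
        raise ValueError("grid extent must be positive and finite")
    if ppd <= 0:
        raise ValueError("ppd must be positive")
    if grid_extent_deg < 6.0 * params.envelope_sigma_deg:
        warnings.warn(
            "grid extent smaller than 6 envelope SDs; envelope will be truncated",
            stacklevel=2,
        )
    n = int(round(grid_extent_deg * ppd))
    if n % 2 == 0:
        n += 1
    half = (n - 1) / 2.0
    coords = (np.arange(n) - half) / ppd
    x = coords[np.newaxis, :]
    y = coords[::-1, np.newaxis]  # row 0 is the top of the image (y positive)
    theta = math.radians(params.orientation_deg)
    xp = x * math.cos(theta) + y * math.sin(theta)
    yp = -x * math.sin(theta) + y * math.cos(theta)
    sigma = params.envelope_sigma_deg
    envelope = np.exp(-(xp**2 + yp**2) / (2.0 * sigma**2))
    carrier = np.cos(2.0 * math.pi * params.spatial_freq_cpd * xp + params.phase_rad)
    modulation = params.michelson_contrast * envelope * carrier
    pixels = background_luminance * (1.0 + modulation)
    return StimulusImage(
        pixels=pixels,
        pixels_per_degree=ppd,
        eccentricity_deg=eccentricity_deg,
        background_luminance=background_luminance,
        meta={"gabor": dataclasses.asdict(params)},
    )


def apply_external_noise(
    img: StimulusImage,
    spec: NoiseSpec,
    rng: np.random.Generator | None = None,
    clip: bool = True,
) -> StimulusImage:
    """Add seeded zero-mean Gaussian luminance noise to a stimulus.

    Per-pixel noise is drawn from ``N(0, (scale_factor * base_sd)^2)`` in
    Michelson-contrast units and converted to luminance against the image
    background.  With ``clip`` the result is limited to the displayable range
    ``[0, 2 * L_bg]`` and the clipped fraction is recorded under
    ``meta['clip_rate']``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    sd_contrast = spec.scale_factor * spec.base_sd
    noise = rng.normal(0.0, 1.0, size=img.pixels.shape) * (
        sd_contrast * img.background_luminance
    )
    out = img.pixels + noise
    clip_rate = 0.0
    if clip:
        lo, hi = 0.0, 2.0 * img.background_luminance
        clipped = (out < lo) | (out > hi)
        clip_rate = float(np.mean(clipped))
        out = np.clip(out, lo, hi)
    meta = dict(img.meta)
    meta.update(
        {
            "noise": dataclasses.asdict(spec),
            "noise_sd_contrast": sd_contrast,
            "clip_rate": clip_rate,
        }
    )
    return StimulusImage(
        pixels=out,
        pixels_per_degree=img.pixels_per_degree,
        eccentricity_deg=img.eccentricity_deg,
        background_luminance=img.background_luminance,
        meta=meta,
    )


def save_stimulus(img: StimulusImage, path: str | Path) -> tuple[Path, Path]:
    """Write a stimulus as a portable greymap plus a JSON parameter sidecar.

    Luminance ``[0, 2 L_bg]`` maps to grey levels ``[0, 255]``.  The PGM is
    the plain (ASCII, P2) variant so stimuli stay diffable text.
    """
    path = Path(path)
    pgm_path = path.with_suffix(".pgm")
    json_path = path.with_suffix(".json")
    hi = 2.0 * img.background_luminance
    grey = np.clip(np.round(img.pixels / hi * 255.0), 0, 255).astype(int)
    n = grey.shape[0]
    with open(pgm_path, "w") as fh:
        fh.write(f"P2\n{n} {n}\n255\n")
        for row in grey:
            fh.write(" ".join(str(v) for v in row) + "\n")
    sidecar = {
        "pixels_per_degree": img.pixels_per_degree,
        "eccentricity_deg": img.eccentricity_deg,
        "background_luminance": img.background_luminance,
        "meta": img.meta,
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return pgm_path, json_path


def load_stimulus(path: str | Path) -> StimulusImage:
    """Read back a stimulus written by :func:`save_stimulus` (8-bit grey)."""
    path = Path(path)
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    with open(path.with_suffix(".pgm")) as fh:
        magic = fh.readline().strip()
        if magic != "P2":
            raise ValueError(f"not a plain PGM file: {magic!r}")
        dims = fh.readline().split()
        maxval = float(fh.readline())
        vals = np.loadtxt(fh)
    grey = np.asarray(vals, dtype=float).reshape(int(dims[1]), int(dims[0]))
    hi = 2.0 * sidecar["background_luminance"]
    return StimulusImage(
        pixels=grey / maxval * hi,
        pixels_per_degree=sidecar["pixels_per_degree"],
        eccentricity_deg=sidecar["eccentricity_deg"],
        background_luminance=sidecar["background_luminance"],
        meta=sidecar.get("meta", {}),
    )
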