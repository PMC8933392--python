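"""Beer-Lambert stain math for brightfield H-DAB images.

Brightfield absorbance is additive in optical-density (OD) space:
``OD_c = -log10(I_c / I0_c)`` per RGB channel ``c``, where ``I0`` is the
unstained background level. Each stain contributes OD along a fixed unit
vector in RGB-OD space, so a pixel's OD is a nonnegative linear combination
of the stain vectors and per-stain concentrations are recovered by inverting
the 3x3 stain matrix (Ruifrok-Johnston colour deconvolution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Standard H-DAB optical-density vectors (unnormalised, RGB order).
HEMATOXYLIN_RGB_OD = (0.650, 0.704, 0.286)
DAB_RGB_OD = (0.269, 0.568, 0.778)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("stain vector must be nonzero")
    return v / n


@dataclass(frozen=True)
class StainVectorSet:
    """Unit OD vectors for hematoxylin, DAB and the residual channel.

    The residual defaults to the normalized cross product of the two stain
    vectors, completing an invertible 3x3 basis.
    """

    hematoxylin: np.ndarray = field(default=HEMATOXYLIN_RGB_OD)
    dab: np.ndarray = field(default=DAB_RGB_OD)
    residual: np.ndarray | None = None

    def __post_init__(self):
        object.__setattr__(self, "hematoxylin", _unit(self.hematoxylin))
        object.__setattr__(self, "dab", _unit(self.dab))
        if self.residual is None:
            res = np.cross(self.hematoxylin, self.dab)
        else:
            res = np.asarray(self.residual, dtype=float)
        object.__setattr__(self, "residual", _unit(res))
        if not np.isfinite(np.linalg.cond(self.matrix)) or np.linalg.cond(self.matrix) > 1e12:
            raise ValidationError("stain matrix is singular or ill-conditioned")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with one stain vector per row (hema, dab, residual)."""
        return np.stack([self.hematoxylin, self.dab, self.residual])


def rgb_to_od(rgb, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Convert 8-bit RGB pixels to optical density per channel.

    ``OD_c = -log10(max(pixel_c, 1) / background_c)``, clipped at zero.
    The 1-floor guards against log(0) at fully absorbing pixels.
    """
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValidationError("background must be positive per channel")
    pixels = np.maximum(np.asarray(rgb, dtype=float), 1.0)
    od = -np.log10(pixels / background)
    return np.clip(od, 0.0, None)


def od_to_rgb(od, background=(255.0, 255.0, 255.0), quantize: bool = True) -> np.ndarray:
    """Invert :func:`rgb_to_od` via transmittance ``I = I0 * 10**(-OD)``.

    With ``quantize`` the result is rounded to uint8 (what a camera records);
    without it the float inverse is exact, which tests of the round trip use.
    """
    background = np.asarray(background, dtype=float)
    if np.any(background <= 0):
        raise ValidationError("background must be positive per channel")
    rgb = background * np.power(10.0, -np.asarray(od, dtype=float))
    if quantize:
        return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return rgb


def deconvolve_stains(od_image, vectors: StainVectorSet | None = None, clip: bool = True):
    """Unmix an OD image into (hematoxylin, DAB, residual) concentration maps.

    Solves ``OD = conc @ M`` per pixel with ``M`` the stain matrix; negative
    concentrations (noise pushing a pixel outside the stain cone) are clipped
    to zero unless ``clip`` is False.
    """
    vectors = vectors or StainVectorSet()
    od = np.asarray(od_image, dtype=float)
    conc = od @ np.linalg.inv(vectors.matrix)
    if clip:
        conc = np.clip(conc, 0.0, None)
    return conc[..., 0], conc[..., 1], conc[..., 2]


def reconstruct_od(hema, dab, residual, vectors: StainVectorSet | None = None) -> np.ndarray:
    """Recompose an OD image from concentration maps (deconvolution inverse)."""
    vectors = vectors or StainVectorSet()
    conc = np.stack([np.asarray(hema, float), np.asarray(dab, float), np.asarray(residual, float)], axis=-1)
    return conc @ vectors.matrix
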