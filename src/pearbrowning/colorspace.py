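"""sRGB ⇄ CIE L*a*b* conversion for 8-bit rasters.

The conversion runs sRGB → linear RGB → CIE XYZ → L*a*b*, with the Lab stage
referenced to a configurable white point.  The default white is D65 under the
CIE 1964 10° supplementary observer, the appropriate choice for large natural
surfaces such as fruit slices; the 2° observer white is available for
comparison.  All maps are element-wise and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "WhitePoint",
    "D65_10",
    "D65_2",
    "srgb_to_lab",
    "lab_to_srgb",
    "read_rgb",
    "write_rgb",
]


@dataclass(frozen=True)
class WhitePoint:
    """Tristimulus values of the reference white, with Yn normalised to 100."""

    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if not (self.Xn > 0 and self.Yn > 0 and self.Zn > 0):
            raise ValueError("white point tristimulus values must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn], dtype=float)


#: D65 illuminant, CIE 1964 10° supplementary observer (default).
D65_10 = WhitePoint(94.811, 100.000, 107.304)
#: D65 illuminant, CIE 1931 2° standard observer.
D65_2 = WhitePoint(95.047, 100.000, 108.883)

# sRGB (IEC 61966-2-1) linear-RGB ⇄ XYZ matrices, D65 primaries, Y in [0, 1].
_RGB2XYZ = np.array(
    [
        [0.4123908, 0.35758434, 0.18048079],
        [0.21263901, 0.71516868, 0.07219232],
        [0.01933082, 0.11919478, 0.95053215],
    ]
)
_XYZ2RGB = np.linalg.inv(_RGB2XYZ)

# The XYZ values the matrix assigns to sRGB reference white (the D65/2° white
# as encoded by the primaries); the Bradford transform adapts from this white
# to the configured Lab reference white so that (255,255,255) always lands on
# the Lab achromatic axis regardless of the observer chosen.
_SRGB_WHITE = _RGB2XYZ.sum(axis=1)

_BRADFORD = np.array(
    [
        [0.8951, 0.2664, -0.1614],
        [-0.7502, 1.7135, 0.0367],
        [0.0389, -0.0685, 1.0296],
    ]
)

_DELTA = 6.0 / 29.0  # Lab linear-segment threshold


def _adaptation(white: WhitePoint) -> np.ndarray:
    """Bradford chromatic-adaptation matrix from the sRGB encoding white to
    the configured reference white (both with Y normalised to 1)."""
    cone_src = _BRADFORD @ _SRGB_WHITE
    cone_dst = _BRADFORD @ (white.as_array() / white.Yn)
    return np.linalg.inv(_BRADFORD) @ np.diag(cone_dst / cone_src) @ _BRADFORD


def _validate_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError(
            f"expected an H×W×3 raster, got shape {img.shape}"
            + (" (alpha channels are not supported)" if img.ndim == 3 else "")
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have at least one pixel")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("sRGB channel values must lie in [0, 255]")
    return img


def _srgb_decode(u: np.ndarray) -> np.ndarray:
    """8-bit sRGB companded values → linear light in [0, 1]."""
    u = u / 255.0
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def _srgb_encode(lin: np.ndarray) -> np.ndarray:
    """Linear light → companded sRGB (unclipped; out-of-gamut values exceed [0, 1]).

    Negative linear values are extended through the linear segment so that
    out-of-gamut magnitudes survive for clip accounting.
    """
    lin = np.asarray(lin, dtype=float)
    hi = 1.055 * np.clip(lin, 0.0, None) ** (1.0 / 2.4) - 0.055
    return np.where(lin <= 0.0031308, 12.92 * lin, hi)


def _f(t: np.ndarray) -> np.ndarray:
    """CIE Lab companding: cube root above (6/29)³, linear segment below."""
    t = np.asarray(t, dtype=float)
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _f_inv(ft: np.ndarray) -> np.ndarray:
    ft = np.asarray(ft, dtype=float)
    return np.where(ft > _DELTA, ft**3, 3 * _DELTA**2 * (ft - 4.0 / 29.0))


def srgb_to_lab(img: np.ndarray, white: WhitePoint = D65_10) -> np.ndarray:
    """Convert an 8-bit sRGB raster (H×W×3, values in [0, 255]) to CIE L*a*b*.

    Returns a float64 H×W×3 raster with channels (L*, a*, b*); L* lies in
    [0, 100] for any valid sRGB input.
    """
    img = _validate_rgb(img)
    lin = _srgb_decode(img.astype(float))
    xyz = lin @ _RGB2XYZ.T @ _adaptation(white).T * 100.0
    fxyz = _f(xyz / white.as_array())
    lab = np.empty_like(fxyz)
    lab[..., 0] = 116.0 * fxyz[..., 1] - 16.0
    lab[..., 1] = 500.0 * (fxyz[..., 0] - fxyz[..., 1])
    lab[..., 2] = 200.0 * (fxyz[..., 1] - fxyz[..., 2])
    return lab


def lab_to_srgb(
    lab: np.ndarray, white: WhitePoint = D65_10, *, return_clip_count: bool = False
):
    """Convert CIE L*a*b* back to an 8-bit sRGB raster.

    Out-of-gamut pixels are clipped to [0, 255].  With ``return_clip_count``
    the number of pixels clipped by more than half a quantisation step (i.e.
    genuinely out of gamut, not mere rounding) is returned alongside.
    """
    lab = np.asarray(lab, dtype=float)
    if lab.ndim != 3 or lab.shape[-1] != 3:
        raise ValueError(f"expected an H×W×3 Lab raster, got shape {lab.shape}")
    if lab[..., 0].min() < -1e-6 or lab[..., 0].max() > 100 + 1e-6:
        raise ValueError("L* must lie in [0, 100]")
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_f_inv(fx), _f_inv(fy), _f_inv(fz)], axis=-1) * white.as_array()
    lin = xyz / 100.0 @ np.linalg.inv(_adaptation(white)).T @ _XYZ2RGB.T
    u = _srgb_encode(lin) * 255.0
    clipped = np.any((u < -0.5) | (u > 255.5), axis=-1)
    out = np.clip(np.rint(u), 0, 255).astype(np.uint8)
    if return_clip_count:
        return out, int(clipped.sum())
    return out


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an 8-bit 3-channel PNG/TIFF raster; alpha channels are rejected."""
    img = iio.imread(path)
    if img.ndim == 3 and img.shape[-1] == 4:
        raise ValueError(f"{path}: alpha channel present; expected a plain RGB raster")
    if img.ndim != 3 or img.shape[-1] != 3 or img.dtype != np.uint8:
        raise ValueError(
            f"{path}: expected an 8-bit H×W×3 raster, got {img.dtype} {img.shape}"
        )
    return img


def write_rgb(path: str | Path, img: np.ndarray) -> None:
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim != 3 or img.shape[-1] != 3:
        raise ValueError("write_rgb expects an 8-bit H×W×3 raster")
    iio.imwrite(path, img)
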