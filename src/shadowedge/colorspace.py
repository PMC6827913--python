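"""Cone-opponent color representation of edge-patch images.

Images move through three representations:

1. gamma-encoded monitor RGB in [0, 1] (what a raster file stores),
2. LMS cone excitations (long-, medium-, short-wavelength-sensitive
   photoreceptor responses), obtained through a monitor calibration,
3. a pixel-normalized color-opponent space with a luminance channel
   ``Lum = L + M`` and two chromatic channels

   ``LM   = (L - alpha*M) / (L + M)``            ('red-green')
   ``S_op = (2S - beta*(L+M)) / (2S + beta*(L+M))``  ('blue-yellow')

   where ``alpha`` and ``beta`` are monitor-specific constants chosen so
   that an achromatic pixel has both chromatic channels equal to zero.

All arrays are H x W x 3 float ndarrays; channel order is (L, M, S) for
cone images and (Lum, LM, S_op) for opponent images.  The chromatic
channels are normalized per pixel, so they are invariant to a common
scaling of all three cone excitations — the property that makes them
useful for separating illumination from material edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_ALPHA",
    "DEFAULT_BETA",
    "XYZ_TO_LMS",
    "ColorCalibration",
    "CalibrationError",
    "build_calibration",
    "gamma_correct",
    "gamma_encode",
    "rgb_to_lms",
    "lms_to_rgb",
    "lms_to_opponent",
    "opponent_to_lms",
    "project_luminance_only",
    "circular_mask_weights",
    "apply_circular_mask",
]

#: Default 'red-green' balance constant (achromatic pixels have L = alpha*M).
DEFAULT_ALPHA = 1.33
#: Default 'blue-yellow' opponency constant (achromatic pixels have 2S = beta*(L+M)).
DEFAULT_BETA = 0.14

#: Smith-Pokorny cone fundamentals expressed as a linear map from
#: Judd-revised CIE XYZ tristimulus values to LMS cone excitations.
#: V(lambda)-normalized so that L + M equals luminance Y.
XYZ_TO_LMS = np.array(
    [
        [0.15514, 0.54312, -0.03286],
        [-0.15514, 0.45684, 0.03286],
        [0.0, 0.0, 0.01608],
    ]
)


class CalibrationError(ValueError):
    """Raised when monitor primaries cannot define an invertible RGB->LMS map."""


@dataclass(frozen=True)
class ColorCalibration:
    """Monitor calibration: linear RGB->LMS map plus opponent-space constants.

    Parameters
    ----------
    rgb_to_lms
        Invertible 3x3 matrix taking *linear* (gamma-corrected) RGB to LMS.
    gamma
        Per-channel power-law exponent of the display, or a scalar applied
        to all three channels.
    alpha, beta
        Opponent-space balance constants (see module docstring).
    primaries_xyY
        Optional 3x3 array of the (x, y, Y) chromaticity/luminance triplets
        of the R, G, B phosphors that the matrix was derived from.
    """

    rgb_to_lms: np.ndarray
    gamma: np.ndarray = field(default_factory=lambda: np.full(3, 2.2))
    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    primaries_xyY: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.rgb_to_lms, dtype=float)
        if m.shape != (3, 3):
            raise CalibrationError("rgb_to_lms must be 3x3")
        if not np.all(np.isfinite(m)) or np.linalg.cond(m) > 1e12:
            raise CalibrationError("rgb_to_lms is singular or ill-conditioned")
        g = np.broadcast_to(np.asarray(self.gamma, dtype=float), (3,)).copy()
        if np.any(g <= 0):
            raise CalibrationError("gamma must be positive")
        if self.alpha <= 0 or self.beta <= 0:
            raise CalibrationError("alpha and beta must be positive")
        object.__setattr__(self, "rgb_to_lms", m)
        object.__setattr__(self, "gamma", g)

    @property
    def lms_to_rgb(self) -> np.ndarray:
        return np.linalg.inv(self.rgb_to_lms)


def build_calibration(
    primaries_xyY,
    xyz_to_lms: np.ndarray = XYZ_TO_LMS,
    gamma=2.2,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
) -> ColorCalibration:
    """Build a calibration from measured phosphor chromaticities.

    Each primary's (x, y, Y) triplet is converted to XYZ tristimulus
    values (X = xY/y, Z = (1-x-y)Y/y); the three XYZ columns form the
    linear RGB->XYZ matrix, which is then mapped to LMS through the
    packaged cone-fundamental matrix.

    Raises
    ------
    CalibrationError
        If any primary has y <= 0 or Y <= 0, or the chromaticities are
        collinear (singular matrix).
    """
    prim = np.asarray(primaries_xyY, dtype=float)
    if prim.shape != (3, 3):
        raise CalibrationError("primaries_xyY must be three (x, y, Y) triplets")
    x, y, Y = prim[:, 0], prim[:, 1], prim[:, 2]
    if np.any(y <= 0) or np.any(Y <= 0):
        raise CalibrationError("primaries must have y > 0 and Y > 0")
    X = x * Y / y
    Z = (1.0 - x - y) * Y / y
    rgb_to_xyz = np.stack([X, Y, Z])  # columns are the R, G, B primaries
    if abs(np.linalg.det(rgb_to_xyz)) < 1e-12 * np.abs(rgb_to_xyz).max() ** 3:
        raise CalibrationError("collinear primaries: RGB->XYZ matrix is singular")
    return ColorCalibration(
        rgb_to_lms=np.asarray(xyz_to_lms) @ rgb_to_xyz,
        gamma=gamma,
        alpha=alpha,
        beta=beta,
        primaries_xyY=prim,
    )


def _gamma_array(calibration_or_gamma) -> np.ndarray:
    if isinstance(calibration_or_gamma, ColorCalibration):
        return calibration_or_gamma.gamma
    return np.broadcast_to(np.asarray(calibration_or_gamma, dtype=float), (3,))


def gamma_correct(raw_rgb: np.ndarray, calibration_or_gamma) -> np.ndarray:
    """Linearize gamma-encoded RGB with a per-channel power law.

    Maps 0 -> 0 and 1 -> 1 monotonically; raises ``ValueError`` on values
    outside [0, 1].
    """
    raw = np.asarray(raw_rgb, dtype=float)
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("gamma_correct expects raw RGB in [0, 1]")
    return raw ** _gamma_array(calibration_or_gamma)


def gamma_encode(linear_rgb: np.ndarray, calibration_or_gamma) -> np.ndarray:
    """Inverse of :func:`gamma_correct` (linear RGB -> monitor drive values)."""
    lin = np.asarray(linear_rgb, dtype=float)
    if np.any(lin < 0) or np.any(lin > 1):
        raise ValueError("gamma_encode expects linear RGB in [0, 1]")
    return lin ** (1.0 / _gamma_array(calibration_or_gamma))


def rgb_to_lms(linear_rgb: np.ndarray, calibration: ColorCalibration) -> np.ndarray:
    """Apply the calibration matrix to linear RGB pixels."""
    return np.asarray(linear_rgb, dtype=float) @ calibration.rgb_to_lms.T


def lms_to_rgb(lms: np.ndarray, calibration: ColorCalibration) -> np.ndarray:
    return np.asarray(lms, dtype=float) @ calibration.lms_to_rgb.T


def lms_to_opponent(
    lms: np.ndarray, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Transform LMS cone excitations into the (Lum, LM, S_op) opponent space.

    Pixels with zero denominator (black pixels) get chromatic channels set
    to 0, the achromatic reference value.

    Raises
    ------
    ValueError
        If any cone excitation is negative.
    """
    x = np.asarray(lms, dtype=float)
    if np.any(x < 0):
        raise ValueError("LMS excitations must be nonnegative")
    L, M, S = x[..., 0], x[..., 1], x[..., 2]
    lum = L + M
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(lum > 0, (L - alpha * M) / np.where(lum > 0, lum, 1.0), 0.0)
        denom = 2.0 * S + beta * lum
        s_op = np.where(denom > 0, (2.0 * S - beta * lum) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.stack([lum, lm, s_op], axis=-1)


def opponent_to_lms(
    opponent: np.ndarray, alpha: float = DEFAULT_ALPHA, beta: float = DEFAULT_BETA
) -> np.ndarray:
    """Exact algebraic inverse of :func:`lms_to_opponent`.

    ``M = Lum*(1 - LM)/(1 + alpha)``, ``L = Lum - M``,
    ``S = beta*Lum*(1 + S_op) / (2*(1 - S_op))``.

    Raises
    ------
    ValueError
        If any pixel has ``S_op == 1`` with positive luminance (the inverse
        is singular there).
    """
    x = np.asarray(opponent, dtype=float)
    lum, lm, s_op = x[..., 0], x[..., 1], x[..., 2]
    if np.any((s_op >= 1.0) & (lum > 0)):
        raise ValueError("S_op = 1 with Lum > 0: singular pixel, cannot invert")
    M = lum * (1.0 - lm) / (1.0 + alpha)
    L = lum - M
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(lum > 0, beta * lum * (1.0 + s_op) / (2.0 * (1.0 - s_op)), 0.0)
    return np.stack([L, M, S], axis=-1)


def project_luminance_only(opponent: np.ndarray) -> np.ndarray:
    """Project every pixel onto the luminance axis.

    The Lum channel is preserved bit-exactly; both chromatic channels are
    set to 0 (the achromatic reference).  This removes the color content of
    an image without converting it into luminance, and is idempotent.
    """
    out = np.array(opponent, dtype=float, copy=True)
    out[..., 1] = 0.0
    out[..., 2] = 0.0
    return out


def circular_mask_weights(
    n: int, kernel_size: int = 12, kernel_sd: float = 30.0
) -> np.ndarray:
    """Blending weights for the circular stimulus aperture.

    A disk of the image diameter (radius n/2, centered on the pixel grid)
    is convolved with a normalized truncated Gaussian kernel of the given
    size and standard deviation.  With the default parameters the kernel is
    heavily truncated (sd far larger than its support), i.e. nearly a 12x12
    box — the profile is dominated by the kernel's footprint, not its shape.

    The disk is evaluated analytically at the half-integer offsets of the
    even-sized kernel, which keeps the weight field exactly symmetric about
    the image center.
    """
    n = int(n)
    radius = n / 2.0
    center = (n - 1) / 2.0
    offsets = np.arange(kernel_size) - (kernel_size - 1) / 2.0
    du, dv = np.meshgrid(offsets, offsets, indexing="ij")
    kernel = np.exp(-(du**2 + dv**2) / (2.0 * kernel_sd**2))
    kernel /= kernel.sum()
    ii, jj = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
    weights = np.zeros((n, n))
    for a in range(kernel_size):
        for b in range(kernel_size):
            inside = (ii + du[a, b] - center) ** 2 + (jj + dv[a, b] - center) ** 2 <= radius**2
            weights += kernel[a, b] * inside
    return np.clip(weights, 0.0, 1.0)


def apply_circular_mask(
    image: np.ndarray,
    background,
    kernel_size: int = 12,
    kernel_sd: float = 30.0,
) -> np.ndarray:
    """Blend a square image into a background through the circular aperture.

    ``output = w*image + (1-w)*background`` with the weights of
    :func:`circular_mask_weights`.  ``background`` may be a scalar or a
    per-channel value.  Raises ``ValueError`` for non-square images.
    """
    img = np.asarray(image, dtype=float)
    if img.shape[0] != img.shape[1]:
        raise ValueError("circular mask requires a square image")
    w = circular_mask_weights(img.shape[0], kernel_size, kernel_sd)
    bg = np.asarray(background, dtype=float)
    if img.ndim == 3:
        w = w[..., None]
        bg = np.broadcast_to(bg, (img.shape[-1],))
    return w * img + (1.0 - w) * bg
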