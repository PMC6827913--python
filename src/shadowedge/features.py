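"""Edge-patch region partition and the six image properties.

An edge patch (opponent-space raster with a horizontal edge through its
center) is split into three row bands: ``L1`` above, the central band
``R`` (10 rows by default) containing the transition, and ``L2`` below.
From the band statistics six scalar properties are computed:

====================  =======================================================
``C_Lum``             Michelson contrast  |Lum1 - Lum2| / (Lum1 + Lum2)
``m_Lum``             mean luminance      (Lum1 + Lum2) / 2
``sigma_Lum``         contrast difference |sd(L1) - sd(L2)|
``rho_Lum``           edge slope: mean per-row change of the 1-D luminance
                      profile across R
``d_LM``              'red-green' difference   |LM1 - LM2|
``d_Sop``             'blue-yellow' difference |S_op1 - S_op2|
====================  =======================================================

Luminance properties are computed on the min-max normalized Lum channel;
the chromatic channels are already normalized per pixel and are used as
is.  Patches are oriented (flipped vertically if needed) so that the
upper band is the brighter one, which makes every property invariant to
vertical flips of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate

__all__ = [
    "FEATURE_NAMES",
    "LUMINANCE_FEATURES",
    "CHROMATIC_FEATURES",
    "DegeneratePatchError",
    "RegionPartition",
    "FeatureVector",
    "normalize_luminance",
    "orient_patch",
    "partition",
    "michelson_contrast",
    "mean_luminance",
    "contrast_difference",
    "edge_profile",
    "edge_slope",
    "chromatic_differences",
    "extract_features",
    "feature_table",
    "rotate_to_horizontal",
]

LUMINANCE_FEATURES = ("C_Lum", "m_Lum", "sigma_Lum", "rho_Lum")
CHROMATIC_FEATURES = ("d_LM", "d_Sop")
FEATURE_NAMES = LUMINANCE_FEATURES + CHROMATIC_FEATURES


class DegeneratePatchError(ValueError):
    """Raised for patches whose luminance channel carries no edge (constant)."""


@dataclass(frozen=True)
class RegionPartition:
    """The L1 / R / L2 row decomposition of a patch with band statistics.

    Region means and standard deviations are taken over all (valid) pixels
    of each band.  ``sd`` uses the population convention (divide by N).
    """

    rows_L1: slice
    rows_R: slice
    rows_L2: slice
    r_rows: int
    lum1: float
    lum2: float
    sd1: float
    sd2: float
    lm1: float
    lm2: float
    sop1: float
    sop2: float


@dataclass(frozen=True)
class FeatureVector:
    C_Lum: float
    m_Lum: float
    sigma_Lum: float
    rho_Lum: float
    d_LM: float
    d_Sop: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def normalize_luminance(patch: np.ndarray) -> np.ndarray:
    """Min-max rescale the Lum channel to [0, 1]; chromatic channels untouched.

    Raises
    ------
    DegeneratePatchError
        If the luminance channel is constant (no edge to normalize).
    """
    p = np.array(patch, dtype=float, copy=True)
    lum = p[..., 0]
    lo, hi = lum.min(), lum.max()
    # near-constant counts as constant: rescaling float dust to [0, 1] would
    # manufacture an edge out of rounding error
    if hi - lo <= 1e-10 * max(1.0, abs(hi)):
        raise DegeneratePatchError("constant luminance channel: degenerate patch")
    p[..., 0] = (lum - lo) / (hi - lo)
    return p


def _band_slices(height: int, r_rows: int) -> tuple[slice, slice, slice]:
    if r_rows < 2:
        raise ValueError("r_rows must be >= 2")
    if height <= r_rows:
        raise ValueError("patch height must exceed r_rows")
    start = height // 2 - r_rows // 2
    stop = height // 2 + (r_rows + 1) // 2
    return slice(0, start), slice(start, stop), slice(stop, height)


def orient_patch(patch: np.ndarray, r_rows: int = 10) -> np.ndarray:
    """Flip the patch vertically iff the lower band is brighter than the upper.

    Guarantees mean Lum(L1) >= mean Lum(L2); exact ties are left unflipped.
    """
    p = np.asarray(patch, dtype=float)
    s1, _, s2 = _band_slices(p.shape[0], r_rows)
    if p[s1, ..., 0].mean() < p[s2, ..., 0].mean():
        return p[::-1].copy()
    return p


def partition(
    patch: np.ndarray, r_rows: int = 10, valid: np.ndarray | None = None
) -> RegionPartition:
    """Partition a patch into L1 / R / L2 and compute band statistics.

    ``R`` is the ``r_rows`` central rows (rows ``H//2 - r_rows//2`` through
    ``H//2 + ceil(r_rows/2) - 1``); L1 is everything above, L2 everything
    below.  ``valid`` optionally masks out background pixels (e.g. after a
    circular aperture) from the statistics.
    """
    p = np.asarray(patch, dtype=float)
    s1, sr, s2 = _band_slices(p.shape[0], r_rows)

    def stats(sl):
        band = p[sl]
        if valid is not None:
            band = band[valid[sl]]
            if band.size == 0:
                raise DegeneratePatchError("region fully masked out")
        else:
            band = band.reshape(-1, p.shape[-1])
        lum = band[:, 0]
        return lum.mean(), lum.std(), band[:, 1].mean(), band[:, 2].mean()

    lum1, sd1, lm1, sop1 = stats(s1)
    lum2, sd2, lm2, sop2 = stats(s2)
    return RegionPartition(
        rows_L1=s1, rows_R=sr, rows_L2=s2, r_rows=r_rows,
        lum1=lum1, lum2=lum2, sd1=sd1, sd2=sd2,
        lm1=lm1, lm2=lm2, sop1=sop1, sop2=sop2,
    )


def michelson_contrast(p: RegionPartition) -> float:
    """``|Lum1 - Lum2| / (Lum1 + Lum2)``; 0 for an all-black patch."""
    total = p.lum1 + p.lum2
    if total <= 0:
        return 0.0
    return abs(p.lum1 - p.lum2) / total


def mean_luminance(p: RegionPartition) -> float:
    return (p.lum1 + p.lum2) / 2.0


def contrast_difference(p: RegionPartition) -> float:
    return abs(p.sd1 - p.sd2)


def edge_profile(patch: np.ndarray) -> np.ndarray:
    """1-D edge profile: mean normalized luminance of each patch row."""
    return np.asarray(patch, dtype=float)[..., 0].mean(axis=1)


def edge_slope(p: RegionPartition, profile: np.ndarray) -> float:
    """Mean per-row luminance change across the central band R.

    ``(profile[last row of R] - profile[first row of R]) / (r_rows - 1)``;
    with the default 10-row band the divisor is 9.  Reported signed: after
    orientation it is systematically <= 0 for clean edges.
    """
    first = p.rows_R.start
    last = p.rows_R.stop - 1
    return (profile[last] - profile[first]) / (p.r_rows - 1)


def chromatic_differences(p: RegionPartition) -> tuple[float, float]:
    """('red-green', 'blue-yellow') absolute mean-opponency differences."""
    return abs(p.lm1 - p.lm2), abs(p.sop1 - p.sop2)


def extract_features(
    patch: np.ndarray, r_rows: int = 10, valid: np.ndarray | None = None
) -> FeatureVector:
    """Normalize, orient, partition, and compute all six properties.

    Raises :class:`DegeneratePatchError` for constant-luminance patches.
    """
    p = normalize_luminance(patch)
    s1, _, s2 = _band_slices(p.shape[0], r_rows)
    if valid is not None:
        m1 = p[s1, ..., 0][valid[s1]].mean()
        m2 = p[s2, ..., 0][valid[s2]].mean()
        if m1 < m2:
            p = p[::-1]
            valid = valid[::-1]
    else:
        p = orient_patch(p, r_rows)
    part = partition(p, r_rows, valid=valid)
    prof = edge_profile(p)
    d_lm, d_sop = chromatic_differences(part)
    return FeatureVector(
        C_Lum=michelson_contrast(part),
        m_Lum=mean_luminance(part),
        sigma_Lum=contrast_difference(part),
        rho_Lum=edge_slope(part, prof),
        d_LM=d_lm,
        d_Sop=d_sop,
    )


def feature_table(patches, r_rows: int = 10):
    """Feature CSV table for a sequence of :class:`~shadowedge.synth.EdgePatch`.

    Returns a pandas DataFrame with one row per patch: patch_id, category,
    size_class, condition and the six property columns.
    """
    import pandas as pd

    rows = []
    for patch in patches:
        fv = extract_features(patch.image, r_rows=r_rows)
        rows.append(
            {
                "patch_id": patch.patch_id,
                "category": patch.category,
                "size_class": patch.size_class,
                "condition": patch.condition,
                **{name: getattr(fv, name) for name in FEATURE_NAMES},
            }
        )
    return pd.DataFrame(rows)


def rotate_to_horizontal(image: np.ndarray, edge_endpoints) -> np.ndarray:
    """Rotate an image so a hand-marked edge is horizontal and centered.

    ``edge_endpoints`` are two (row, col) points on the edge.  The image is
    rotated with bilinear interpolation about the edge midpoint and cropped
    to the largest axis-aligned square inscribed in the rotated frame,
    centered on the midpoint (clamped to stay inside the image).

    Raises ``ValueError`` for coincident endpoints.
    """
    (r1, c1), (r2, c2) = edge_endpoints
    dr, dc = r2 - r1, c2 - c1
    if dr == 0 and dc == 0:
        raise ValueError("edge endpoints must be distinct")
    theta = np.arctan2(dr, dc)
    # fold into (-pi/2, pi/2]: an edge has no direction
    if theta > np.pi / 2:
        theta -= np.pi
    elif theta <= -np.pi / 2:
        theta += np.pi
    mid_r, mid_c = (r1 + r2) / 2.0, (c1 + c2) / 2.0
    img = np.asarray(image, dtype=float)
    # skimage's positive angle turns image content counter-clockwise in display
    # coordinates (row axis pointing down), which maps an edge at angle theta
    # (in array coordinates) onto the horizontal
    rotated = _sk_rotate(
        img, np.degrees(theta), center=(mid_c, mid_r), order=1, mode="constant", cval=0.0
    )
    h, w = img.shape[:2]
    n = min(h, w)
    side = int(np.floor(n / (abs(np.cos(theta)) + abs(np.sin(theta)))))
    side -= side % 2  # even side keeps the edge on the crop midline
    half = side // 2
    top = int(round(mid_r)) - half
    left = int(round(mid_c)) - half
    top = max(0, min(top, h - side))
    left = max(0, min(left, w - side))
    return rotated[top : top + side, left : left + side]
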