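"""Raster I/O for edge patches: PNG/TIFF rasters with JSON sidecars.

A patch on disk is a gamma-encoded RGB raster (16-bit TIFF or 8-bit
PNG, by file extension) plus a ``.json`` sidecar carrying the category label, size class, condition, the scale
factor applied to fit the patch into the display gamut, and a reference
to the calibration used.  Loading inverts the chain (decode gamma ->
LMS -> opponent), so a saved/loaded patch matches the original up to
16-bit quantization and any out-of-gamut clipping.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import colorspace

__all__ = ["save_patch", "load_patch", "write_manifest", "read_manifest"]

def _bit_depth(path: Path) -> int:
    # 16-bit RGB is only portable through TIFF; PNG falls back to 8 bits
    return 16 if path.suffix.lower() in (".tif", ".tiff") else 8


def save_patch(path, patch, calibration: colorspace.ColorCalibration) -> dict:
    """Write an :class:`~shadowedge.synth.EdgePatch` as a raster + sidecar.

    The opponent image is converted to LMS, mapped through the inverse
    calibration to linear RGB, scaled into [0, 1] (scale recorded in the
    sidecar; negative out-of-gamut values are clipped to 0), gamma
    encoded and quantized (16-bit TIFF or 8-bit PNG by extension).
    """
    path = Path(path)
    lms = colorspace.opponent_to_lms(patch.image, calibration.alpha, calibration.beta)
    rgb = colorspace.lms_to_rgb(lms, calibration)
    clipped_frac = float(np.mean(rgb < 0))
    rgb = np.clip(rgb, 0.0, None)
    peak = rgb.max()
    scale = 1.0 / peak if peak > 0 else 1.0
    encoded = colorspace.gamma_encode(rgb * scale, calibration)
    bits = _bit_depth(path)
    vmax = 2**bits - 1
    raster = np.round(encoded * vmax).astype(np.uint16 if bits == 16 else np.uint8)
    iio.imwrite(path, raster)
    sidecar = {
        "category": patch.category,
        "size_class": patch.size_class,
        "condition": patch.condition,
        "patch_id": patch.patch_id,
        "seed": list(patch.seed),
        "scale": scale,
        "clipped_fraction": clipped_frac,
        "encoding": "gamma",
        "bit_depth": bits,
        "alpha": calibration.alpha,
        "beta": calibration.beta,
        "gamma": calibration.gamma.tolist(),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return sidecar


def load_patch(path, calibration: colorspace.ColorCalibration):
    """Read a raster + sidecar back into an :class:`~shadowedge.synth.EdgePatch`."""
    from .synth import EdgePatch

    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    vmax = 2 ** sidecar.get("bit_depth", _bit_depth(path)) - 1
    raster = iio.imread(path).astype(float) / vmax
    linear = colorspace.gamma_correct(raster, calibration)
    lms = colorspace.rgb_to_lms(linear / sidecar.get("scale", 1.0), calibration)
    lms = np.clip(lms, 0.0, None)  # quantization can leave tiny negatives
    opp = colorspace.lms_to_opponent(lms, calibration.alpha, calibration.beta)
    if sidecar.get("condition") == "Lum":
        opp = colorspace.project_luminance_only(opp)
    return EdgePatch(
        image=opp,
        category=sidecar["category"],
        size_class=sidecar["size_class"],
        condition=sidecar["condition"],
        patch_id=sidecar["patch_id"],
        seed=tuple(sidecar.get("seed", ())),
    )


def write_manifest(path, patches, filenames) -> None:
    """Dataset manifest CSV: path, category, size_class, condition, seed."""
    import pandas as pd

    pd.DataFrame(
        {
            "path": [str(f) for f in filenames],
            "category": [p.category for p in patches],
            "size_class": [p.size_class for p in patches],
            "condition": [p.condition for p in patches],
            "seed": ["-".join(map(str, p.seed)) for p in patches],
        }
    ).to_csv(path, index=False)


def read_manifest(path):
    import pandas as pd

    return pd.read_csv(path)
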