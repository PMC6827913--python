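"""Synthetic shadow / material edge-patch generator and simulated observers.

Patches emulate the statistical structure that separates illumination
from material edges in natural scenes:

* a **shadow** patch is a single textured surface under an illumination
  step — the lit and shadowed halves differ by channel-wise attenuation
  factors (k_L, k_M, k_S) with a *wide* penumbra.  The defaults keep
  k_L = k_M (a shadow leaves the L/M balance untouched) and k_S > k_L
  (the ambient light reaching the shadow is relatively blue, shifting
  S/(L+M)), encoding the "color-is-material" asymmetry.
* a **material** patch is two different surfaces under spatially uniform
  illumination — the reflectance step changes all three cone channels,
  including L/M, with a *sharp* transition.

Each patch is built in LMS as reflectance x illumination, multiplied by
a smoothed log-normal texture field, and converted to the cone-opponent
representation.  The transition is a Gaussian-CDF profile centered on
the patch midline, so every patch carries a horizontal, centered edge.

Generation is deterministic: each patch's RNG is seeded from
(master seed, size, category, index), so datasets are order-independent
and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from . import colorspace
from .lda import LDAModel, decision_score

__all__ = [
    "SIZE_CLASSES",
    "GeneratorParams",
    "EdgePatch",
    "SyntheticDataset",
    "generate_patch",
    "generate_dataset",
    "simulate_observer",
]

SIZE_CLASSES = {72: "small", 144: "medium", 288: "large"}
CATEGORIES = ("shadow", "other")


@dataclass(frozen=True)
class GeneratorParams:
    """Study conditions for the synthetic edge-patch population.

    Parameters
    ----------
    sizes
        Patch side lengths in pixels (small/medium/large).
    reflectance_mean, reflectance_sd
        Log-scale mean and sd of the per-channel log-normal surface
        reflectance draws (unitless cone-excitation scale).
    texture_sd
        Typical log-amplitude of the within-surface multiplicative texture
        field.
    texture_amp_sd
        Log-scale sd of the texture amplitude, both across surfaces (each
        surface draws its own overall amplitude) and within a surface (a
        slowly varying amplitude field makes texture patchy).  Without
        this diversity the two halves of a shadow patch would share one
        exact amplitude, handing the classifier an unrealistically clean
        texture-consistency cue.
    texture_amp_corr_frac
        Correlation length of the within-surface amplitude field, as a
        fraction of the patch side.
    chroma_texture_frac
        Amplitude of the independent per-channel (chromatic) component of
        the texture, as a fraction of the local amplitude; the remainder
        is a shared achromatic field.
    texture_corr_len
        Gaussian smoothing length (pixels) of the texture fields.
    shadow_attenuation
        (k_L, k_M, k_S) illumination factors of a typical shadowed half,
        each in (0, 1); defaults keep k_L = k_M and k_S > k_L.
    shadow_depth_sd
        Log-scale sd of the per-patch shadow depth: each shadow raises the
        attenuation triplet to the power ``exp(N(0, shadow_depth_sd))``,
        which varies shadow darkness while preserving k_L = k_M and
        k_S > k_L exactly.
    penumbra_sd_shadow, penumbra_sd_material
        Gaussian-CDF transition widths (pixels): wide for shadows, sharp
        for reflectance edges.
    penumbra_jitter_sd
        Log-scale sd of the per-patch multiplicative jitter on the
        transition width.
    illuminant
        LMS triplet of the direct light.
    alpha, beta
        Opponent-space constants used when converting to (Lum, LM, S_op).
    """

    sizes: tuple[int, ...] = (72, 144, 288)
    reflectance_mean: float = float(np.log(0.35))
    reflectance_sd: float = 0.5
    texture_sd: float = 0.15
    texture_amp_sd: float = 0.5
    texture_amp_corr_frac: float = 0.35
    chroma_texture_frac: float = 0.2
    texture_corr_len: float = 4.0
    shadow_attenuation: tuple[float, float, float] = (0.45, 0.45, 0.60)
    shadow_depth_sd: float = 0.8
    penumbra_sd_shadow: float = 6.0
    penumbra_sd_material: float = 0.8
    penumbra_jitter_sd: float = 0.4
    illuminant: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alpha: float = colorspace.DEFAULT_ALPHA
    beta: float = colorspace.DEFAULT_BETA

    def __post_init__(self):
        k = np.asarray(self.shadow_attenuation, dtype=float)
        if np.any(k <= 0) or np.any(k >= 1):
            raise ValueError("shadow attenuation factors must lie in (0, 1)")
        if self.texture_sd < 0 or self.penumbra_sd_shadow < 0 or self.penumbra_sd_material < 0:
            raise ValueError("texture_sd and penumbra scales must be >= 0")


@dataclass(frozen=True)
class EdgePatch:
    """A labeled opponent-space edge patch with full provenance."""

    image: np.ndarray  # H x W x 3 opponent (Lum, LM, S_op)
    category: str  # "shadow" | "other"
    size_class: str  # "small" | "medium" | "large"
    condition: str  # "Col" | "Lum"
    patch_id: str
    seed: tuple = ()


@dataclass(frozen=True)
class SyntheticDataset:
    patches: tuple[EdgePatch, ...]
    params: GeneratorParams
    seed: int

    def subset(self, condition: str | None = None, size_class: str | None = None):
        sel = [
            p for p in self.patches
            if (condition is None or p.condition == condition)
            and (size_class is None or p.size_class == size_class)
        ]
        return tuple(sel)


def _draw_base_reflectance(params: GeneratorParams, rng) -> np.ndarray:
    """One surface's (L, M, S) reflectance triplet.

    L and M are independent log-normals; S is tied to L + M so that the
    population is centered on the achromatic point of the opponent space
    (2S = beta*(L+M)), with its own log-normal spread.
    """
    lm = np.exp(rng.normal(params.reflectance_mean, params.reflectance_sd, size=2))
    s = 0.5 * params.beta * lm.sum() * np.exp(rng.normal(0.0, params.reflectance_sd))
    return np.array([lm[0], lm[1], s])


def _smooth_unit(f, corr_len, rng_unused=None):
    f = gaussian_filter(f, corr_len, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def _texture_field(shape, params: GeneratorParams, rng) -> np.ndarray:
    """One surface's H x W x 3 multiplicative log-normal texture.

    The local log-amplitude is ``texture_sd`` scaled by a per-surface
    log-normal draw and a slowly varying within-surface field (patchy
    texture); on top of that, a shared achromatic field plus small
    independent per-channel fields give the three cone channels
    correlated but not identical fluctuations.
    """
    if params.texture_sd == 0:
        return np.ones(shape + (3,))
    amp = params.texture_sd
    if params.texture_amp_sd > 0:
        amp = amp * np.exp(rng.normal(0.0, params.texture_amp_sd)) * np.exp(
            params.texture_amp_sd
            * _smooth_unit(rng.standard_normal(shape), params.texture_amp_corr_frac * shape[0])
        )
    achrom = _smooth_unit(rng.standard_normal(shape), params.texture_corr_len)
    frac = params.chroma_texture_frac
    fields = []
    for _ in range(3):
        chrom = _smooth_unit(rng.standard_normal(shape), params.texture_corr_len)
        fields.append(np.exp(amp * (achrom + frac * chrom)))
    return np.stack(fields, axis=-1)


def _transition(height: int, sd: float) -> np.ndarray:
    """Column vector running 0 (top) -> 1 (bottom), midpoint on the patch midline."""
    y = np.arange(height, dtype=float) - (height - 1) / 2.0
    if sd == 0:
        return (y > 0).astype(float)[:, None]
    return norm.cdf(y / sd)[:, None]


def generate_patch(category: str, size: int, params: GeneratorParams, rng) -> np.ndarray:
    """Generate one LMS edge patch (H x W x 3) of the given category.

    Shadow: one reflectance field, illumination stepping from the full
    illuminant (top) to the attenuated illuminant (bottom) across a wide
    penumbra.  Material ("other"): two reflectance fields blended across a
    sharp transition, uniform illumination.
    """
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}")
    if size not in params.sizes:
        raise ValueError(f"size {size} not in params.sizes {params.sizes}")
    shape = (size, size)
    E = np.asarray(params.illuminant, dtype=float)

    def jitter(sd):
        return np.exp(rng.normal(0.0, sd)) if sd > 0 else 1.0

    if category == "shadow":
        base = _draw_base_reflectance(params, rng)
        tex = _texture_field(shape, params, rng)
        depth = jitter(params.shadow_depth_sd)
        t = _transition(size, params.penumbra_sd_shadow * jitter(params.penumbra_jitter_sd))[..., None]
        k = np.asarray(params.shadow_attenuation, dtype=float) ** depth
        illum = E * (1.0 - t * (1.0 - k))  # top lit, bottom shadowed
        refl = base * tex
    else:
        base_top = _draw_base_reflectance(params, rng)
        base_bottom = _draw_base_reflectance(params, rng)
        tex_top = _texture_field(shape, params, rng)
        tex_bottom = _texture_field(shape, params, rng)
        t = _transition(size, params.penumbra_sd_material * jitter(params.penumbra_jitter_sd))[..., None]
        illum = E
        refl = (1.0 - t) * base_top * tex_top + t * base_bottom * tex_bottom
    return refl * illum


def generate_opponent_patch(
    category: str, size: int, params: GeneratorParams, rng
) -> np.ndarray:
    return colorspace.lms_to_opponent(
        generate_patch(category, size, params, rng), params.alpha, params.beta
    )


def _patch_rng(master_seed: int, size: int, cat_idx: int, index: int):
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), int(size), int(cat_idx), int(index)])
    )


def generate_dataset(
    n_per_class_per_size: int, params: GeneratorParams | None = None, seed: int = 0
) -> SyntheticDataset:
    """Balanced labeled dataset, half color and half luminance-only.

    For every size and category ``2 * n_per_class_per_size`` patches are
    generated; a random disjoint half keeps its color content ("Col"), the
    other half is projected onto the luminance axis ("Lum"), mirroring a
    design where no stimulus appears in both conditions.  Per-patch RNGs
    are derived from (seed, size, category, index), so each patch is
    reproducible independently of the rest of the dataset.
    """
    if n_per_class_per_size < 1:
        raise ValueError("n_per_class_per_size must be >= 1")
    params = params or GeneratorParams()
    patches = []
    assign_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0FFEE]))
    for size in params.sizes:
        size_class = SIZE_CLASSES.get(size, f"{size}px")
        for cat_idx, category in enumerate(CATEGORIES):
            n_total = 2 * n_per_class_per_size
            lum_half = assign_rng.permutation(n_total) < n_per_class_per_size
            for i in range(n_total):
                rng = _patch_rng(seed, size, cat_idx, i)
                img = generate_opponent_patch(category, size, params, rng)
                condition = "Lum" if lum_half[i] else "Col"
                if condition == "Lum":
                    img = colorspace.project_luminance_only(img)
                patches.append(
                    EdgePatch(
                        image=img, category=category, size_class=size_class,
                        condition=condition,
                        patch_id=f"{category}-{size}-{i:03d}",
                        seed=(seed, size, cat_idx, i),
                    )
                )
    return SyntheticDataset(patches=tuple(patches), params=params, seed=seed)


def simulate_observer(
    dataset,
    model: LDAModel,
    internal_noise_sd: float = 0.0,
    rng=None,
    observer_id: str = "sim-01",
    feature_frame=None,
) -> "pd.DataFrame":
    """Simulate a single-interval forced-choice observer from an LDA model.

    For each patch the model's decision score is perturbed by Gaussian
    internal noise; the response is "other" iff the noisy score exceeds
    the model's criterion (score > 0).  Returns trial records in the
    psychophysics CSV schema (observer_id, block, condition, size_class,
    true_category, response).

    ``feature_frame`` may supply a precomputed feature table (as from
    :func:`shadowedge.features.feature_table`) to avoid re-extraction.
    """
    import pandas as pd

    from .features import feature_table

    patches = dataset.patches if hasattr(dataset, "patches") else tuple(dataset)
    if feature_frame is None:
        feature_frame = feature_table(patches)
    missing = [f for f in model.feature_names if f not in feature_frame.columns]
    if missing:
        raise ValueError(f"model features not present in feature table: {missing}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X = feature_frame[list(model.feature_names)].to_numpy()
    scores = decision_score(model, X)
    if internal_noise_sd > 0:
        scores = scores + rng.normal(0.0, internal_noise_sd, size=len(scores))
    responses = np.where(scores > 0, "other", "shadow")
    return pd.DataFrame(
        {
            "observer_id": observer_id,
            "block": feature_frame["condition"] + "-" + feature_frame["size_class"],
            "condition": feature_frame["condition"],
            "size_class": feature_frame["size_class"],
            "true_category": feature_frame["category"],
            "response": responses,
        }
    )
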