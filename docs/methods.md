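# Methods

This note documents the models, conventions and design choices behind
`shadowedge`, in the order data flows through the package.

## Color representation

Raster RGB is linearized by a per-channel power law (default exponent 2.2 for
all channels; real displays should supply measured values — the exponent is a
calibration field, not a constant). Linear RGB maps to LMS through a 3×3
matrix built from the monitor phosphors' (x, y, Y) chromaticities: each
primary's tristimulus vector (X = xY/y, Y, Z = (1−x−y)Y/y) forms a column of
RGB→XYZ, which is composed with a packaged Judd-XYZ → Smith–Pokorny-LMS
matrix. That cone matrix is V(λ)-normalized, so L + M equals luminance Y; a
user-supplied explicit `rgb_to_lms` overrides the xyY path. Collinear
chromaticities or non-positive y/Y raise `CalibrationError`.

The opponent transform is

- `Lum = L + M`
- `LM = (L − αM)/(L + M)`, α = 1.33
- `S_op = (2S − β(L+M))/(2S + β(L+M))`, β = 0.14

α and β place the achromatic point at (LM, S_op) = (0, 0). Both chromatic
channels are *pixel-local* ratios, in keeping with cone adaptation being a
local process, and are invariant to scaling all cone excitations by a common
factor. Zero-denominator pixels (black, or 2S + β·Lum = 0) get chromatic
values 0 by convention — the achromatic reference — rather than NaN. The
inverse transform is exact algebra (`M = Lum(1−LM)/(1+α)`, `L = Lum − M`,
`S = βLum(1+S_op)/(2(1−S_op))`) and is used to render opponent images back
to RGB for file output; `S_op = 1` at positive luminance is singular and
rejected.

Luminance-only stimuli are produced by projection: the Lum channel is kept
bit-exactly and the chromatic channels are set to 0. This removes color
content; it does not convert color into luminance.

The circular stimulus aperture is a disk of the image diameter convolved
with a normalized truncated Gaussian kernel, default size 12×12 and sd 30
pixels. With sd far larger than the support this kernel is nearly a box
filter; it is implemented literally as specified, with both parameters
exposed (a plausible alternative reading, sd 3.0, can be passed directly).
The disk is evaluated analytically at the even kernel's half-integer
offsets, keeping the weight field exactly symmetric; blending is
`w·image + (1−w)·background`, leaving the patch center untouched and the
corners at background.

## Synthetic edge patches

The generator emulates the statistical asymmetry between illumination and
material edges rather than rendering scenes. Every patch is built in LMS as
`reflectance × illumination × texture` and converted to opponent space;
the transition is a Gaussian-CDF profile centered on the patch midline, so
each patch carries a horizontal centered edge (hand-marking and rotation are
unnecessary for synthetic data; a rotation utility exists for real images).

- **Surfaces.** A surface's L and M reflectances are independent log-normals
  (log-mean log 0.35, log-sd 0.5); S is tied to L+M at the achromatic point
  with its own log-normal spread, so surface chromaticities scatter around
  neutral in both opponent channels.
- **Shadow patches** are one surface under an illumination step. The
  shadowed half is lit by attenuated light with channel factors
  (k_L, k_M, k_S) = (0.45, 0.45, 0.60) raised to a per-patch depth exponent
  `exp(N(0, 0.8))`. k_L = k_M exactly, so the L/M channel is untouched by a
  shadow at any depth; k_S > k_L encodes the relative blueness of ambient
  light in shadows, shifting S/(L+M). The penumbra is wide (sd 6 px,
  log-jittered by 0.4).
- **Material patches** are two independently drawn surfaces under uniform
  illumination, blended across a sharp transition (sd 0.8 px, same jitter).
  The reflectance step moves all three channels, including L/M.
- **Texture** is a multiplicative log-normal field: a shared achromatic
  component plus small independent per-channel components (chromatic
  fraction 0.2), smoothed over 4 px. Its amplitude (typical log-sd 0.15) is
  itself diverse — drawn per surface and modulated by a slowly varying
  within-surface field (log-sd 0.5, correlation length 0.35·H). Without
  that diversity the two halves of a shadow patch share one exact amplitude
  and the classifier inherits a deterministic texture-consistency cue that
  natural texture does not provide; early homogeneous drafts of the
  generator made luminance cues near-ceiling for that reason.

The depth and amplitude diversity parameters were fixed once, when the
generator produced a population whose machine-observer behavior sits in the
qualitative regime the psychophysics literature reports (luminance-only d′
around 1.5, a clear chromatic benefit carried by L/M rather than S/(L+M)),
and have not been revisited. Because no quantitative statistics of any real
edge database are targeted, passing tests demonstrate internal consistency
of the pipeline and the qualitative illumination/material asymmetry — not
agreement with any particular natural-image corpus. Features of real data
deliberately not modeled: curved or occluding edges, highlights, multiple
edges per patch, surround context, and spectrally exact illuminants.

Datasets are balanced: for each size and category, 2n patches are generated
and a random disjoint half is projected to luminance-only, mirroring designs
where no stimulus appears in both conditions. Per-patch RNGs derive from
(seed, size, category, index), so generation is deterministic and
order-independent.

## Image properties

Luminance is min–max normalized to [0, 1] per patch (chromatic channels are
already pixel-normalized and remain untouched). A patch whose luminance
range is below 1e-10 (relative) is degenerate and raises an error rather
than amplifying rounding noise into a fake edge. Patches are flipped
vertically if needed so the upper band is brighter; ties stay unflipped.
The central band R is the `r_rows` (default 10) rows straddling the midline
(rows ⌊H/2⌋−⌊r/2⌋ … ⌊H/2⌋+⌈r/2⌉−1); band statistics are over all pixels of
a band, with population-convention (divide-by-N) standard deviations, and
background pixels can be excluded via a validity mask for aperture-masked
images. The edge slope ρ_Lum = (profile[last R row] − profile[first R row])
/(r_rows − 1) is kept signed; after orientation it is ≤ 0 for clean edges,
and since the classifier is affine-invariant the sign convention cannot
affect d′.

## Machine observers

The discriminant is fitted from class means and the pooled covariance
(scatter matrices over n₀+n₁−2), with a ridge of `1e-8·trace(Σ)/k` on the
diagonal for conditioning — and an absolute floor when the trace is zero, so
that identically constant features (the chromatic channels of luminance-only
stimuli) receive weight 0 instead of crashing the solve. The decision score
is the log-likelihood ratio `w·s + c`; positive scores predict "other"
(material). Evaluation defaults to resubstitution, with stratified-free
k-fold (default 10) refitting available; reports always name the protocol.
Equal priors are assumed throughout (balanced designs).

Confusion matrices convert to pH = P(predict other | other) and
pFA = P(predict other | shadow); whenever either rate would be 0 or 1, the
log-linear correction (add 0.5 to each count, 1 to each denominator) is
applied to both rates and flagged. This gives a finite-n ceiling on
measurable d′ and is shared verbatim with the human analysis.

The parametric bootstrap resamples from the *fitted* per-class Gaussians
(class means, pooled covariance), refits and re-evaluates on each of
n_boot = 1000 replicates, and reports the 2.5th–97.5th percentile interval.
Note the pooled-Gaussian model deliberately understates the separation of
strongly non-Gaussian features (e.g. the near-point-mass shadow
distribution of Δ_L/M), so intervals can sit below the in-sample point
estimate; that is a property of the parametric reading, not a bug.

Feature ranking fits one single-feature classifier per property and sorts
by d′ (ties broken by name). Incremental curves add luminance properties in
ranked order and evaluate each color variant (none, +Δ_L/M, +Δ_S/(L+M),
+both) at every count. The count-based d′ of nested models is monotone only
up to the granularity of individual samples switching sides; the fitted
Mahalanobis separation is exactly monotone.

## Psychophysics

Trial tables are validated CSVs (observer, block, condition Col/Lum, size
small/medium/large, true category, response; case-folded enums). d′ =
z(pH) − z(pFA) and the equal-variance criterion c = −½(z(pH)+z(pFA)) are
computed per (observer, condition, size) cell; c > 0 means a conservative
tendency toward "shadow". The log-linear correction was chosen over 1/(2N)
clipping and is flagged wherever applied. Group summaries are means ± SEM
across observers plus a paired Col−Lum difference with a percentile
bootstrap over observers; no omnibus test is computed — inference is
descriptive. Simulated observers share a fitted discriminant and add
Gaussian internal noise to its score, producing trials in the same schema,
so the pipeline can be validated end to end: with zero noise the simulated
group's d′ equals the model's exactly.

## Problem sizes and determinism

Default experiment scale is 50 patches per class per size (sizes 72, 144,
288 px) and 1000 bootstrap replicates — about half a minute end to end.
Tests use reduced scales chosen as the smallest sizes at which each
property is unambiguous (e.g. coverage checks at 100 outer × 300 inner
replicates, determinism at 6 patches/class). All randomness flows from
explicit seeds through `numpy.random.Generator`; identical configuration
and seed reproduce every output table byte-for-byte.

## Known limitations

- The xyY-based calibration reconstructs the RGB→LMS map from chromaticity
  coordinates, not measured spectra; metameric errors are possible.
- The generator's shadow model is channel-wise (von-Kries-like) attenuation,
  not spectral rendering; it encodes the direction of natural shadow color
  shifts, not their magnitude distribution.
- Resubstitution d′ is optimistic at small n; cross-validated evaluation is
  provided but not the default.
- File round trips quantize to 8/16 bits and rescale into the display gamut
  (scale recorded in the sidecar), so absolute luminance is preserved only
  up to that factor; contrast-based properties are unaffected.
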