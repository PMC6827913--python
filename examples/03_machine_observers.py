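"""Machine observers: does color information improve edge classification?

Generates the default synthetic dataset (50 patches/class/size), then
fits Fisher linear discriminants on the luminance properties alone and
with each chromatic difference added, reporting confusion-matrix d'
with 95% parametric-bootstrap intervals (color condition, all sizes
pooled).  Mirrors the incremental color-augmentation analysis.
"""

from shadowedge import GeneratorParams, features, lda, synth

dataset = synth.generate_dataset(50, GeneratorParams(), seed=1)
table = features.feature_table(dataset.subset(condition="Col"))
y = table["category"].to_numpy()
lum = list(features.LUMINANCE_FEATURES)

print("individual feature ranking (d' of single-feature classifiers):")
ranking = lda.rank_features(
    table[list(features.FEATURE_NAMES)].to_numpy(), y, features.FEATURE_NAMES
)
print(ranking.to_string(index=False))

print("\nclassifier d' with 95% parametric-bootstrap intervals (n_boot=500):")
subsets = {
    "luminance only": lum,
    "+ d_LM": lum + ["d_LM"],
    "+ d_Sop": lum + ["d_Sop"],
    "+ both": lum + ["d_LM", "d_Sop"],
}
for i, (name, cols) in enumerate(subsets.items()):
    ci = lda.parametric_bootstrap(table[cols].to_numpy(), y, n_boot=500, seed=10 + i)
    print(f"  {name:<16} d' = {ci.point_dprime:5.2f}  [{ci.lo:5.2f}, {ci.hi:5.2f}]")

print(
    "\nAdding the red-green difference (d_LM) raises d' well beyond the\n"
    "luminance-only interval; the blue-yellow difference (d_Sop) adds\n"
    "little, because the S/(L+M) channel shifts at shadow borders too\n"
    "and is therefore a much less reliable material cue."
)
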