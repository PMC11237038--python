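"""Baseline dissimilarity matrices from color-space models.

Builds RGB-Euclidean and CIELAB-CIEDE2000 dissimilarity matrices for a
small palette of hex-coded colors and compares the two models with
supervised RSA.
"""

from gwalign import ColorSet, lab_dissimilarity, normalize, rgb_dissimilarity, rsa_spearman

palette = [
    "#FF0000", "#FF8000", "#FFFF00", "#80FF00", "#00FF00", "#00FF80",
    "#00FFFF", "#0080FF", "#0000FF", "#8000FF", "#FF00FF", "#FF0080",
    "#808080", "#FFFFFF", "#000000", "#804000",
]
colors = ColorSet.from_hex(palette)

rgb = normalize(rgb_dissimilarity(colors))
lab = normalize(lab_dissimilarity(colors))

print(f"{len(colors)} colors")
print(f"max raw RGB distance: {rgb_dissimilarity(colors).values.max():.1f}")
print(f"max raw CIEDE2000 difference: {lab_dissimilarity(colors).values.max():.1f}")
print(f"RSA (Spearman) between RGB and LAB models: {rsa_spearman(rgb, lab):.2f}")
# The two color spaces rank color pairs similarly but not identically:
# CIEDE2000 weights lightness/chroma/hue perceptually, while RGB treats the
# three channels as plain coordinates.
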