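"""Compute both trafficking indices on synthetic co-culture images.

TIS (segmentation-based) averages the red/green intensity ratio over pixels
inside both the segmented tumour and the segmented immune region.  TIC
(classification-based) trains a 4-class k-means pixel classifier
(background / tumour / immune / colour-saturated) and reports the fraction
of tumour-surrounded pixels that are immune.  Both indices rise with the
true infiltration fraction even though every tumour pixel carries
red-channel bleed-through.
"""

import numpy as np

from spherotrack import (
    SyntheticParams,
    assign_roles,
    classify_pixels,
    compute_tic,
    compute_tis,
    generate_coculture_image,
    kmeans_train,
    split_channels,
)
from spherotrack.tic import sample_pixels

fractions = [0.0, 0.2, 0.4]

# train one classifier on a pooled pixel sample across conditions
rng = np.random.default_rng(7)
train = []
for i, f in enumerate(fractions):
    img, _ = generate_coculture_image(
        SyntheticParams(infiltration_fraction=f, seed=900 + i)
    )
    red, green = split_channels(img)
    train.append(sample_pixels(red, green, 10_000, rng))
clf = assign_roles(kmeans_train(np.concatenate(train), k=4, seed=7))
print("classifier centroids (red, green) -> role:")
for c, role in zip(clf.centroids, clf.roles):
    print(f"  ({c[0]:6.1f}, {c[1]:6.1f}) -> {role}")

print(f"\n{'true_infiltration':>17} {'TIS':>7} {'TIC':>7}")
for i, f in enumerate(fractions):
    img, truth = generate_coculture_image(
        SyntheticParams(infiltration_fraction=f, seed=50 + i)
    )
    red, green = split_channels(img)
    tis = compute_tis(red, green).tis
    tic = compute_tic(classify_pixels(clf, red, green)).tic
    print(f"{truth.true_infiltration_fraction:>17.2f} {tis:>7.3f} {tic:>7.3f}")

print("\nAt infiltration 0 TIS equals the bleed-through ratio (red/green of "
      "tumour pixels) and TIC is 0; both increase as more immune cells sit "
      "inside the spheroid.")
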