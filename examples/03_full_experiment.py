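"""Run the batch pipeline over a whole synthetic experiment.

Writes a small two-group experiment to disk (PNG images + layout), trains
the pixel classifier on it, analyses every image, and prints the tidy
per-image record table plus the per-group mean +/- SEM summary the pipeline
hands off to downstream statistics.
"""

import tempfile

from spherotrack import (
    SyntheticParams,
    analyze_experiment,
    assign_roles,
    build_training_sample,
    kmeans_train,
    write_synthetic_experiment,
)

with tempfile.TemporaryDirectory() as tmp:
    layout, truths = write_synthetic_experiment(
        tmp,
        groups=["untreated", "cortisol"],
        times_h=[24, 48, 72, 96],
        base_params=SyntheticParams(image_size=128, spheroid_radius=28,
                                    n_immune_cells=20, immune_cell_radius=2),
        growth_factors={24: 1.0, 48: 1.3, 72: 1.6, 96: 1.9},
        # cortisol suppresses infiltration in this simulated experiment
        infiltration_by_group={"untreated": 0.4, "cortisol": 0.1},
        seed=13,
    )
    sample = build_training_sample(layout, pixels_per_image=5000, seed=13)
    clf = assign_roles(kmeans_train(sample, k=4, seed=13))
    df, summary = analyze_experiment(layout, clf)

print("per-image records:")
print(df.drop(columns=["tic_excluded_border", "degenerate_flags"])
        .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nper-group summary (mean, SEM):")
print(summary[["group", "time_h", "tis_mean", "tic_mean"]]
      .to_string(index=False, float_format=lambda x: f"{x:.3f}"))
print("\nWith one image per cell the SEM columns are NaN; with replicates "
      "they quantify within-group spread. The suppressed-infiltration group "
      "shows lower TIS and TIC at every time point.")
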