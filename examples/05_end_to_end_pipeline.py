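"""Run the complete diagnosis pipeline on synthetic images.

One master seed drives everything: stratified 80-20 split, auto-encoder
feature extraction, wrapper-mode ACO selection of 20 of the 32 latent
features, and a KNN classifier on the held-out test partition.  A second
pass contrasts the selected subset against all features and a random
subset sharing the same split.
"""

from antcad import (
    ACOConfig,
    ClassifierSpec,
    PipelineConfig,
    SyntheticImageSpec,
    compare_selection,
    make_images,
    run_pipeline,
)

records = make_images(SyntheticImageSpec(n_per_class=30, noise_sd=10.0, seed=0))
config = PipelineConfig(
    extractor="autoencoder",
    ae={"hidden_dim": 32, "epochs": 60},
    aco=ACOConfig(deposit_mode="wrapper", n_ants=15, n_iterations=10, subset_size=20, seed=0),
    classifier=ClassifierSpec(family="knn"),
    seed=7,
)

report = run_pipeline(config, records=records)
m = report["metrics"]
print(f"selected {len(report['selected_features'])} of 32 latent features")
print(f"test metrics: ACC {m['ACC']:.3f}  F1 {m['F1']:.3f}  MCC {m['MCC']:.3f}")

comparison = compare_selection(config, records=records)
print("\nwith/without selection (shared split and classifier):")
for name, row in comparison["rows"].items():
    print(f"  {name:>14}: ACC {row['ACC']:.3f}  ({row['n_features']} features)")
print("\n-> the selected subset matches the full feature set at 60% of the")
print("   dimensionality.  On this cleanly separable image set even a random")
print("   subset can tie; example 02 shows the contrast when most features")
print("   are noise.")
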