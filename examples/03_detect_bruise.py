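"""Two-stage PCA detection of an invisible bruise in one cube.

Stage 1 segments the fruit from background and calyx (PCA on all pixel
spectra, PC1 image normalised to [0,1], greyscale closing, Otsu threshold,
opening, largest component).  Stage 2 projects the fruit pixels — smoothed
(Savitzky-Golay 5,2) and scatter-corrected (SNV) — onto a damage PCA fitted
on two bruised fruit per day, Otsu-thresholds the selected PC image and
keeps candidate regions that are big and round enough to be a real bruise.
"""

from kakispec import SceneSpec, generate_cube, make_templates, segment_damage, segment_fruit
from kakispec.pipeline import synthetic_scene_config, train_damage_pca_from_cubes
from kakispec.synthetic import iterate_dataset

config = synthetic_scene_config(seed=0)

# fit the damage PCA once on a small training sample: two bruised fruit/day
training = [(cube, None)
            for _, state, cube, _ in iterate_dataset(2, seed=100)
            if state != "intact"]
model = train_damage_pca_from_cubes(training, config)
print(f"damage PCA: {model.n_components} components, "
      f"explained variance {', '.join(f'{v:.1%}' for v in model.evr[:4])}, ...")

# detect on a fresh day-2 fruit
cube, masks = generate_cube(SceneSpec(seed=42), make_templates(), day=2)
fruit = segment_fruit(cube)
result = segment_damage(cube, fruit, model, config.damage_pca,
                        config.region_filter)

print(f"\nfruit mask: {fruit.sum()} pixels")
print(f"verdict: {result.verdict}")
for region in result.regions:
    print(f"  region: area {region.area} px, "
          f"circularity {region.circularity:.2f}, "
          f"centroid ({region.centroid[0]:.0f}, {region.centroid[1]:.0f})")
gt = masks["bruise"]
iou = (result.damage_mask & gt).sum() / (result.damage_mask | gt).sum()
print(f"overlap with ground-truth bruise (IoU): {iou:.2f}")
print("mean damage spectrum (first 5 bands): "
      + ", ".join(f"{v:.3f}" for v in result.mean_damage_spectrum[:5]))
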