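# kakispec

Hyperspectral detection and aging of invisible mechanical damage in
persimmon (*Diospyros kaki*) fruit.

Mechanical impacts during harvesting and packing cause flesh browning in
deastringed 'Rojo Brillante' persimmon that is often invisible at the
surface — the consumer discovers it only on peeling. `kakispec` implements a
two-stage chemometric pipeline over 60-band reflectance cubes
(450–1040 nm, 10 nm steps) that detects these hidden bruises and estimates
how many days ago the damage occurred:

1. **Reflectance calibration.** Raw counts become relative reflectance via
   the white/dark reference correction
   ρ(x,y,λ) = ρ_ref · (R − R_dark) / (R_white − R_dark), with ρ_ref = 0.99
   for a 99% calibration tile.
2. **Fruit segmentation.** PCA over all pixel spectra; the PC1 score image
   (which carries the scene contrast) is min–max normalised to [0, 1],
   greyscale-closed, binarised with Otsu's threshold and opened; the largest
   4-connected component of the NIR-bright class is the fruit, excluding
   background and calyx leaves.
3. **Damage segmentation.** Fruit-pixel spectra are Savitzky–Golay smoothed
   (5-point window, 2nd-order) and SNV-normalised, then projected onto a
   damage PCA fitted once on a small training set of bruised fruit (two per
   day). One PC score image is Otsu-thresholded; the minority class is the
   bruise candidate, and regions too small, too elongated
   (circularity 4πA/P² below threshold) or hugging the fruit rim are
   discarded as edge artefacts. A fruit is *damaged* iff a region survives.
4. **Damage aging (PLS-DA).** Each detected bruise contributes its mean raw
   reflectance spectrum. After a Savitzky–Golay derivative (3-point,
   2nd-order), SNV and mean centring, a PLS2 regression against dummy-coded
   day labels {0, 1, 2, 3} classifies the bruise age by argmax; the number
   of latent variables is picked by stratified 10-fold cross-validated
   misclassification on a seeded two-thirds calibration split.

Because no public image set accompanies the method, the package ships a
first-class synthetic scene generator: fruit ellipse on dark background,
star-shaped calyx, radial illumination falloff, Gaussian sensor noise, and a
bruise whose radius grows with day and whose spectrum follows the measured
orderings (darker than intact tissue at 450–660 nm and increasingly so with
day; brighter at the 670 nm chlorophyll band; deepest 970 nm water
absorption just after impact, drying afterwards). Every stage is tested
against this generator's ground truth.

## Worked example

```sh
python examples/03_detect_bruise.py
```

```
damage PCA: 8 components, explained variance 44.3%, 18.2%, 6.0%, 1.3%, ...

fruit mask: 5241 pixels
verdict: damaged
  region: area 441 px, circularity 0.86, centroid (72, 73)
overlap with ground-truth bruise (IoU): 1.00
mean damage spectrum (first 5 bands): 0.110, 0.111, 0.110, 0.110, 0.111
```

The damage PCA was fitted on eight training fruit; on a fresh day-2 fruit
the detector finds one compact region of 441 pixels (circularity 0.86 —
nearly a disc, as an impact bruise should be) that coincides exactly with
the simulated bruise. Its mean spectrum — low in the blue because browning
pigments absorb there — is what the aging classifier consumes. Running
`examples/04_age_damage.py` continues with 80 bruised fruit:

```
detected damaged: 74/80 bruised fruit
latent variables selected by CV: 2
calibration accuracy: 100.0%
cross-validation accuracy: 100.0%
held-out test accuracy: 100.0%
```

Two latent variables suffice on the synthetic scenes (the day signal spans
a low-dimensional spectral subspace); the held-out confusion matrix is
diagonal. `examples/01_simulate_scene.py` and
`examples/02_calibrate_reflectance.py` demonstrate the generator and the
calibration arithmetic.

## Command line

The same stages are available as a thin CLI:

```sh
kakispec simulate  --n-per-class 10 --seed 1 --out data/
kakispec train-pca --manifest data/manifest.csv --per-day 2 --out model.npz
kakispec detect    --manifest data/manifest.csv --model model.npz --out det/
kakispec age       --results det/ --manifest data/manifest.csv --out aged/
```

`detect` writes per-image verdict JSONs, damage-mask PNGs, overlays (damage
in blue) and a per-state summary CSV; `age` writes
calibration/cross-validation/test confusion matrices and overlays recoloured
by predicted day (magenta 0 d, green 1 d, red 2 d, blue 3 d).

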