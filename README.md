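# glut4quant

Layer-resolved quantification of GLUT4 subcellular distribution in
confocal images of single skeletal-muscle fibre cross-sections.

## The problem

Insulin-stimulated glucose uptake into skeletal muscle works by
translocation of the glucose transporter GLUT4 from intracellular storage
vesicles to the plasma membrane. Immunofluorescence microscopy of
single-fibre cross-sections — dystrophin marking the membrane, GLUT4, and
MHC1 marking type I fibres — lets this be measured spatially: how much
GLUT4 sits in the membrane band versus the layers beneath it, how it is
packaged into small (< 1 µm) versus large (> 1 µm) clusters, and how this
distribution shifts over an insulin-infusion time course. This package is
for researchers running that assay: it turns a directory of 3-channel
TIFFs plus a study design table into per-fibre measurements and
mixed-model statistics, and ships a synthetic fibre generator with full
ground truth so every stage is validated by parameter recovery.

## Method

Per image (one fibre per field):

1. **Membrane midline** — an active contour (snake) seeded on the
   Otsu-thresholded dystrophin ring converges to the ridge of the ring,
   i.e. the membrane midline.
2. **Layers** — the exact signed Euclidean distance map `d` from the
   midline defines a 3 px membrane band (|d| ≤ 1.5 px) and five
   concentric 1 µm layers L1..L5 inside it, plus the deeper interior.
3. **Spots** — GLUT4 clusters are 8-connected components above a single
   per-participant Otsu threshold (pooled over all of that participant's
   fibre pixels). Size class uses the area-equivalent diameter
   2·√(area/π): large iff > 1 µm. Each spot is assigned the layer
   containing its centroid.
4. **Intensity & colocalization** — mean raw GLUT4 intensity per layer
   and over the fibre; colocalization is the pixel-wise Pearson
   correlation r(GLUT4, dystrophin) over the fibre region.
5. **Statistics** — per-fibre rows enter Gaussian linear mixed models
   with a subject random intercept (REML); counts on the log1p scale;
   post-hoc pairwise timepoint contrasts are marginal-mean contrasts with
   Bonferroni adjustment.

`docs/methods.md` covers the model assumptions, parameter defaults and
numerical choices in detail.

## Worked example

Simulate one fibre, run the full measurement stack on it, and compare
with the planted truth:

```python
import numpy as np
from glut4quant import (EffectSpec, Condition, PipelineConfig,
                        generate_fibre_phantom, render_image)
from glut4quant.pipeline import segment_image
from glut4quant.quantification import participant_threshold, measure_fibre

spec = EffectSpec()
rng = np.random.default_rng(0)
phantom = generate_fibre_phantom(spec, Condition("trained", "lipid", 0, "I"), rng)
image = render_image(phantom, spec, rng, image_id="demo")

contour, layers = segment_image(image, PipelineConfig())
threshold = participant_threshold([image.channel("glut4")],
                                  [layers.fibre_mask | layers.pm_mask])
measurement, spots = measure_fibre(image, layers, threshold)

print(f"planted spots: {len(phantom.planted_spots)}  detected: {len(spots)}")
print(f"Otsu threshold: {threshold:.0f}")
print(f"PCC(GLUT4, dystrophin) = {measurement.pcc:.3f}")
print(f"PM counts: {measurement.spot_counts['PM']}")
print(f"mean intensity  PM: {measurement.layer_intensities['PM']:.0f}  "
      f"L1: {measurement.layer_intensities['L1']:.0f}  "
      f"L5: {measurement.layer_intensities['L5']:.0f}")
```

Output:

```
planted spots: 56  detected: 56
Otsu threshold: 1606
PCC(GLUT4, dystrophin) = 0.499
PM counts: {'small': 27, 'large': 1}
mean intensity  PM: 1245  L1: 500  L5: 354
```

All 56 planted clusters are recovered; the colocalization matches the
phantom's planted target (0.50 for a trained fibre at baseline); 27 of 28
membrane spots are small, reflecting the planted 99% small composition in
trained fibres; and GLUT4 intensity is highest in the membrane band and
decays inward, as built into the scene.

## Command line

```bash
glut4 simulate --config sim.yaml --seed 1 --out study/      # images + design + truth
glut4 run-all --images study/images --design study/design.csv --out results/
# or stage by stage: glut4 segment / quantify / analyze
```

`run-all` writes `measurements.csv` (one row per fibre), `spots.csv`,
`statuses.csv` (per-image ok / segmentation-failed / excluded-border),
`contrasts.csv`, summary tables, and a config snapshot that regenerates
the run exactly. Runs are deterministic under a fixed seed.

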