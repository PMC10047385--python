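# ezar — EZ At-Risk mapping and GA-progression analytics for SD-OCT

`ezar` is a toolkit for quantifying early photoreceptor damage in
nonexudative age-related macular degeneration (AMD) from spectral-domain
OCT volumes. Its core biomarker is the **EZ At-Risk** region: en-face
A-scan columns whose ellipsoid-zone-to-RPE (EZ–RPE) thickness has thinned
to **≤ 10 µm** but that lie **outside geographic atrophy (GA)** — tissue
that has not yet atrophied but is at elevated risk of doing so. GA itself
is detected at the segmentation level as confluence of the EZ, RPE and
Bruch's-membrane (BM) surfaces: both the EZ–RPE and the RPE–BM thickness
collapse to 0 µm.

The package is aimed at retinal-imaging researchers who want to

- derive GA / EZ At-Risk / attenuation maps from multi-layer OCT
  segmentations with explicit, testable rules,
- extract eye-level quantitative biomarkers (percentage areas and
  central-subfield thicknesses),
- train and evaluate a desk-scale encoder–decoder segmentation model of
  the EZ At-Risk band, including an automatic-retraining round that
  duplicates poorly segmented training examples, and
- model 5-year progression to sub-foveal GA with a cross-validated
  random forest over six OCT biomarkers.

Because clinical OCT datasets are rarely shareable, `ezar` ships a seeded
synthetic-volume generator (drusen, EZ attenuation patches, GA lesions
with choroidal hypertransmission, speckle) so every stage of the pipeline
is exercisable end-to-end from a single integer seed.

## The rules and models

With per-column surface rows `r(ONL) ≤ r(EZ) ≤ r(RPE) ≤ r(BM)` (pixels,
converted to µm by the axial scale), and per-column thicknesses
`t_EZ-RPE` and `t_RPE-BM`:

| Quantity | Rule |
|---|---|
| GA column | `t_EZ-RPE = 0` **and** `t_RPE-BM = 0` |
| EZ At-Risk column | `t_EZ-RPE ≤ 10 µm` and not GA |
| Partial EZ attenuation | `t_EZ-RPE < 20 µm` (superset of total) |
| Total EZ–RPE / RPE–BM attenuation | thickness `= 0 µm` |
| sub-foveal GA (sfGA) | any GA column on the foveal B-scan |
| fovea-threatening GA | any GA column within the 0.5 mm central subfield |

Percentage areas use all A-scan columns of the en-face field as the
denominator. For model training, at-risk columns are rasterised into a
10-pixel vertical band centered on the EZ line of each B-scan.

The segmentation model is a U-shaped convolutional encoder–decoder
(kernel width 5, pixel-wise sigmoid output) trained with binary
cross-entropy and an RMSprop-style optimizer (learning rate 1e-4 at full
scale), batch size 40, 200 samples per epoch, early stopping after 7
epochs without validation improvement. After the first round, 100
training examples are profiled for Dice/F-scores; those strictly below
the 30th percentile are duplicated and training continues with identical
settings. The full-scale preset has ≈ 2 × 10⁷ parameters at 256 × 256 px;
the tested desk preset (< 5 × 10⁵ parameters at 64 × 64 px) runs on one
CPU. The network and its training loop are implemented in numpy with
analytic backpropagation — no GPU or deep-learning framework is needed.

Progression analytics mirror the clinical study design: Pearson
correlation of baseline EZ At-Risk area with 5-year GA growth, a Welch
t-test between growing and stable eyes, and a random forest with
stratified 10-fold cross-validation predicting conversion to
sfGA/fovea-threatening GA from six biomarkers, with out-of-fold
permutation feature importance.

## Worked example

```python
import numpy as np
from ezar import (PhenotypeParams, ScanGeometry, compute_record,
                  generate_labeled_volume)

geometry = ScanGeometry(n_bscans=32, n_ascans=128, n_depth=128,
                        lateral_scale=6000 / 128, bscan_spacing=6000 / 32,
                        fovea_bscan=16, fovea_ascan=64)
volume, surfaces, truth = generate_labeled_volume(
    geometry, PhenotypeParams(), seed=1)
record = compute_record(surfaces, geometry, eye_id="demo")
print(f"EZ At-Risk area:        {record.pct_ez_at_risk:.2f}%")
print(f"partial EZ attenuation: {record.pct_partial_ez_atten:.2f}%")
print(f"total EZ-RPE atten.:    {record.pct_total_ez_rpe_atten:.2f}%")
print(f"GA area:                {record.ga_area:.3f} mm^2, sfGA={record.sfga}")
```

prints

```
EZ At-Risk area:        3.52%
partial EZ attenuation: 10.18%
total EZ-RPE atten.:    2.10%
GA area:                0.668 mm^2, sfGA=False
```

i.e. this synthetic eye carries a 0.67 mm² extrafoveal GA lesion, 2.1 %
of its macular columns have already lost the EZ band completely, and a
further 3.5 % of pre-atrophic tissue (thinned to ≤ 10 µm but outside GA)
is flagged at risk.

A command-line interface wraps the same pipeline:

```bash
ezar simulate --n-eyes 4 --seed 0 --out scratch/eyes
ezar derive --surfaces scratch/eyes/eye000/surfaces.csv \
            --geometry scratch/eyes/eye000/volume/geometry.json \
            --out scratch/derived
ezar biomarkers --manifest scratch/eyes/manifest.csv --out features.csv
ezar train --manifest scratch/eyes/manifest.csv --seed 0 --out scratch/run
ezar evaluate --manifest scratch/eyes/manifest.csv --run-dir scratch/run \
              --out scratch/report.json
ezar predict-progression --n-eyes 120 --seed 0 --out scratch/progression.json
```

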