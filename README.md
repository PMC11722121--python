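# octamorph

Quantitative en face OCTA morphometry and cohort statistics for studies of
peripheral retinal non-perfusion (PNP) in diabetic macular edema.

Clinical OCTA protocols acquire a burst of 8–10 consecutive 3 × 3 mm en
face angiograms of the macula; averaging them improves the signal-to-noise
ratio before vessels are segmented and measured. This package implements
that whole computation as a tested, reusable library:

* **Image chain** — device quality gating (signal strength index > 50 or
  quality score > 8), intensity-inhomogeneity correction, a
  translation → affine → elastic registration cascade, intensity
  normalization, and mean/max averaging; multiscale ridge segmentation,
  1-px skeletonization, a vessel graph with Horton–Strahler ordering
  (orders 2–4 = arterioles/venules), perfusion density PD and skeleton
  vessel density VD (both excluding arteriole/venule pixels), mean vessel
  calibre, box-counting fractal dimension, and two tortuosity indices —
  the arc-chord ratio `L_arc / L_chord` and a composite
  angle-variation/inflection index that is 0 for straight centerlines.
* **FAZ morphometry** — the foveal avascular zone is segmented as the
  avascular component at the fovea after morphological closing; area,
  perimeter, moment eccentricity, axis ratio, acircularity
  `P / (2·sqrt(pi·A))` and min/max Feret diameters are reported, with
  ocular magnification corrected by the modified Littmann–Bennett relation
  `q = 0.01306 · (axial length − 1.82 mm)` (linear metrics scale by
  `q_eye / q_device`, areas by its square).
* **Statistics chain** — iterative random-forest imputation for mixed-type
  tables, univariate screening (Welch t / exact Fisher with full r × c
  enumeration) at α = 10 %, mixed-model re-testing with a patient random
  intercept (Gaussian via REML; logistic and multinomial via adaptive
  Gauss–Hermite maximum likelihood), correlation pruning (|r| > 0.9),
  maximal-model backward elimination on AIC with a final Wald significance
  filter, and leave-one-out cross-validated ROC AUC with a DeLong
  confidence interval.
* **Synthetic data** — vascular phantoms (bifurcating arteriole/venule
  trees, a capillary lattice, an elliptical FAZ bounded by a terminal
  capillary ring) with exact ground truth for every centerline, width,
  Strahler order and tortuosity; noisy frame bursts with known motion; and
  48-eye / 33-patient cohort tables with realistic group differences,
  within-patient correlation and controlled missingness.

## Worked example

```python
from octamorph.pipeline import PipelineConfig, process_eye
from octamorph.synth import PhantomSpec, generate_frame_stack, \
    generate_vessel_phantom

image, truth = generate_vessel_phantom(PhantomSpec(seed=4))
stack = generate_frame_stack(image, n_frames=4, motion_sd=1.5,
                             noise_sd=0.04, seed=2, speckle_sd=0.1)
config = PipelineConfig(registration_stages=("translation", "affine"))
record = process_eye(stack, config, axial_length_mm=23.4)
print(round(record.vascular["perfusion_density"], 3),
      round(record.vascular["vessel_density"], 3),
      round(record.faz["faz_area_mm2"], 3),
      round(record.faz["faz_eccentricity"], 3))
```

prints

```
0.371 0.094 0.328 0.675
```

i.e. 37 % of the non-arteriolar field carries flow signal, the skeleton
covers 9.4 % of it, and the magnification-corrected FAZ covers 0.328 mm²
with eccentricity 0.68 — all in the range reported for edematous maculae.
The uncorrected FAZ area recovered from this phantom is 0.345 mm² against
a generating ellipse of 0.355 mm².

A command-line interface wraps the same chains:

```sh
octamorph fixtures --kind cohort --seed 1 --out fixtures
octamorph stats --cohort fixtures/cohort_seed1.csv --seed 1 --out results.json
```

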