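# bowmetrics

Synthetic ultra-high-resolution corneal OCT pipeline for central
Bowman's-layer thickness (BT).

Bowman's layer is the thin (~15 µm) acellular collagen sheet between
the corneal epithelium and stroma. Measuring its central thickness in
vivo requires axial resolution near 1.7 µm (PSF FWHM in tissue) and a
segmentation chain that can track a faint posterior boundary. This
package implements that chain end-to-end on simulated data with known
ground truth, for researchers developing or validating anterior-segment
OCT layer analysis:

1. **phantom_sim** — layered-cornea B-scan stacks (interface impulses ⊗
   Gaussian PSF, multiplicative speckle, per-frame axial jitter) and
   synthetic cohorts of healthy (HC), keratoconus (KC) and corneal
   dystrophy (CD) subjects with realistic BT/ET/CCT/Kmax structure.
2. **preprocess** — signal screening, axial-only cross-correlation
   alignment with sub-pixel refinement, frame averaging.
3. **graphseg** — iterative minimum-cost path extraction by dynamic
   programming under a |Δz| ≤ 2 px/column smoothness constraint, with
   path blocking, a deterministic interface-labelling policy and a 1–5
   quality grade.
4. **thickness** — optical→geometric conversion (÷ n_G = 1.387),
   quasi-point BT/ET over a centred 450 µm window, per-eye aggregation
   with quality weighting (scores 3/4/5 → weights 1/2/3; < 3 excluded).
5. **cohort_stats** — group summaries, ANOVA + Tukey HSD, OLS of BT on
   CCT, and a GLM testing whether the BT/CCT ratio depends on
   diagnosis, age, sex, Kmax or epithelial thickness.

The scientific core: per column, BT(x) = (z_posterior − z_anterior) ·
Δz_optical / n_G, averaged over the 450 µm window; cohort-level, the
interest is the BT~CCT association (R² ≈ 0.18 pooled) and the
near-constant BT/CCT ratio (~3 %) across diagnoses.

## Worked example

```python
import numpy as np
from bowmetrics import PhantomSpec, generate_stack, process_capture

spec = PhantomSpec(bowman_thickness_um=15.0, seed=3)   # default noise
stack, truth = generate_stack(spec)                    # 16 frames, 440x500 px
meas, seg = process_capture(stack)                     # average→segment→measure
print(f"score={seg.quality_score} BT={meas.bt_um:.2f} um "
      f"(true {truth.spec.bowman_thickness_um}) ET={meas.et_um:.2f} um")
```

prints

```
score=4 BT=15.07 um (true 15.0) ET=52.71 um
```

i.e. the capture was graded "good" (weight 2 in per-eye averaging), the
measured quasi-point Bowman thickness is within 0.1 µm of the phantom's
ground truth, and the epithelial thickness matches its configured
52.72 µm. A full synthetic study is one call:

```python
from bowmetrics import PipelineConfig, run_pipeline
result = run_pipeline(PipelineConfig(seed=1))
print(result.report.group_summary["KC"]["bt_um"]["mean"])  # 14.10 um at n=24
print(result.report.bt_cct["r_squared"])                   # 0.28 at n=62
```

The same stages are exposed on the command line:

```bash
bowmetrics simulate stack --out sim --seed 4
bowmetrics preprocess --in sim/stack.tiff --out avg.tiff --report pre.json
bowmetrics segment --in avg.tiff --out seg.json
bowmetrics measure --seg seg.json --meta avg.json --out meas.csv
bowmetrics run --out study/ --seed 1          # whole cohort end-to-end
```

Stacks are multi-page 16-bit TIFFs with JSON sidecars (spacings, seed,
ground-truth boundary arrays); tables are CSV; every output carries the
hash of the resolved configuration, and identical config + seed gives
byte-identical results.

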