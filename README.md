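# fourchamber

Biometry of the fetal four-chamber echocardiographic view from multi-label
segmentation masks.

Two measurements dominate screening of this plane: the **cardiac axis
(CAx)** — the angle between the long axis of the interventricular septum and
the thoracic anteroposterior axis — and the **cardiothoracic ratio (CTR)** —
the ratio of heart area to thoracic area. Both are normally read by hand
with calipers and vary substantially between sonographers of different
experience. When a segmentation model (or an annotator) produces a 15-label
mask of the plane, these measurements can be computed automatically and
reproducibly; this package provides that measurement layer, plus the
evaluation and validation statistics around it, for researchers comparing
automated readings with human raters.

It contains no segmentation model. Inputs are 2-D label maps (indexed PNG or
NIfTI) over the standard 15-label scheme: the four chambers, both septa,
both ventricular walls, both lungs, descending aorta, spine, ribs, and the
heart/thorax area outlines.

## Method

* **CAx** — the septum mask is thinned to a skeleton, side branches are
  pruned by keeping the longest geodesic path, and a total-least-squares
  line through the skeleton gives the septal long axis. The anteroposterior
  axis is the line through the spine and thorax mass centers. The reported
  angle is `arccos(|d₁·d₂|) ∈ [0°, 90°]`.
* **CTR** — with `E_c = F(m_c)` and `E_t = F(m_t)` the ellipses fitted to
  the outer contours of the heart and thorax masks by a direct
  least-squares conic fit, `CTR = A(E_c)/A(E_t)` where `A = π·a·b` for
  semi-axes a, b.
* **Segmentation scores** — per-class Dice `2|x∩y|/(|x|+|y|)` and IoU
  `|X∩Y|/|X∪Y|`, averaged over scored classes into mDice/mIoU.
* **Agreement** — Shapiro–Wilk on paired differences routes to a paired
  t-test (P > 0.05) or Wilcoxon signed-rank; Bland–Altman bias with 95%
  limits of agreement `bias ± 1.96·SD`; ICC(2,1) (two-way random effects,
  absolute agreement) with an F-based 95% CI.
* **Phantom** — a synthetic fetal thorax (nested ellipses, septal band at a
  prescribed angle, posterior spine, lungs, chambers, walls, ribs) with
  exactly known CAx and CTR, for validating the pipeline without clinical
  data.

Details, parameter defaults and limitations: [docs/methods.md](docs/methods.md).

## Worked example

```python
import numpy as np
from fourchamber import (PhantomSpec, generate_phantom, measure_cax, measure_ctr,
                         degrade_prediction, evaluate,
                         PairedMeasurements, agreement_report)

# a 512x512 phantom with known ground truth: CAx 30 deg, CTR 0.30
out = generate_phantom(PhantomSpec.from_targets(30.0, 0.30, seed=1))
cax = measure_cax(out.bundle)
ctr = measure_ctr(out.bundle)
print(f"CAx  = {cax.angle_deg:.2f} deg   (true 30.00)")
print(f"CTR  = {ctr.ratio:.4f}      (true {out.true_ctr:.4f})")

# score a degraded copy of the phantom as if it were a model prediction
pred = degrade_prediction(out.anatomy_map, dilation_px=1, seed=2)
s = evaluate(pred, out.anatomy_map)
print(f"mDice = {100*s.mdice:.2f}%  mIoU = {100*s.miou:.2f}%  over {s.n_classes_scored} classes")

# rater-vs-model agreement on 100 synthetic paired readings
rng = np.random.default_rng(7)
model = rng.normal(32.0, 8.0, 100)
rater = model + rng.normal(1.2, 4.0, 100)
rep = agreement_report(PairedMeasurements(rater=rater, model=model))
print(f"bias = {rep.bias:.2f}  LoA = ({rep.loa[0]:.2f}, {rep.loa[1]:.2f})")
print(f"ICC(2,1) = {rep.icc:.3f}  95% CI = ({rep.icc_ci[0]:.3f}, {rep.icc_ci[1]:.3f})")
print(f"normality_p = {rep.normality_p:.3f} -> {rep.test_used}, P = {rep.test_p:.3f}")
```

Output:

```
CAx  = 30.23 deg   (true 30.00)
CTR  = 0.2985      (true 0.3000)
mDice = 92.04%  mIoU = 86.10%  over 13 classes
bias = 0.84  LoA = (-6.00, 7.67)
ICC(2,1) = 0.887  95% CI = (0.834, 0.923)
normality_p = 0.964 -> paired_t, P = 0.018
```

The measured CAx is within 0.23° of the constructed truth and the CTR
within 0.5% relative; the degraded prediction loses ~8 Dice points; the
synthetic raters show a small positive bias (they read ~0.8° higher than
the model), limits of agreement of about ±7°, and good absolute agreement
(ICC 0.89) — the same shape of summary one would produce when comparing a
segmentation model's readings against sonographers.

## Command line

```bash
fourchamber phantom  --n 32 --seed 7 --size 512 --cax 10:80:10 --ctr 0.15:0.45:0.10 --out data/
fourchamber measure  --input data/ --out measurements.csv
fourchamber evaluate --pred preds/ --truth data/ --out scores.csv     # per-label Dice/IoU in %
fourchamber agree    --input paired.csv --out report.json --plot ba.png
```

Batches continue past unmeasurable cases; per-case warnings go to stderr
and into the output CSV.

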