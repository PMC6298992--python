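# cvigrade

Severity grading of **chronic venous insufficiency (CVI)** from ordinary
photographs of the lower limb.

CVI presents with visible skin findings whose type and location track
disease severity: reticular veins and telangiectasia in mild disease,
varicose veins in moderate disease, pigmentation, edema and venous
ulcers — typically near the ankle — in severe disease. `cvigrade`
implements a two-level semantic pipeline for vascular-surgery image
audits and triage tools:

1. **Patch concepts.** The photograph (canonical 250 × 700 crop,
   gray-world color normalized, leg foreground masked) is divided into
   regular grids at three scales (15, 25, 50 px). Every patch is
   described by a 352-dim feature bank (uniform LBP, MPEG-7 edge
   histogram, GLCM statistics, dense SIFT mean/variance, gradient mean,
   RGB+YCbCr channel statistics, neighbor context, grid position) and
   mapped by a one-vs-one quadratic-kernel SVM to one of five concepts:
   normal skin (1), reticular vein/telangiectasia (2), varicose veins
   (3), pigmentation/edema (4), vein ulcers (5).
2. **Scene severity.** Concept labels are pooled into
   concept-occurrence vectors (COVs) — normalized 5-bin histograms —
   for the whole image and for the upper and lower halves, at each
   scale. The concatenation over 3 scales × 3 regions × 5 concepts is a
   45-dim representation from which a linear one-vs-one SVM grades the
   image mild / moderate / severe.

Between the two levels sits a **fuzzy-entropy feature selector**: each
representation feature is fuzzified into three triangular sets, set
probabilities are estimated from mean memberships (minimum t-norm for
joints), and a greedy forward search maximizes

```
J(f) = I(f;C) − (1/|S|) Σ_s I(f;s) + (1/|S|) Σ_s I(f;s|C)
       + β · (2/(|S|(|S|−1))) · Σ_{s<s'} [I(f;(s,s')|C) − I(f;(s,s'))]
```

— relevance minus unconditional redundancy plus class-conditional
redundancy plus a second-order interaction term (β = 0.5). Evaluation
uses the confusion-matrix formulas `acc = Σ x_ii / N`,
`kappa = (N Σ x_ii − Σ x_i+ x_+i)/(N² − Σ x_i+ x_+i)`, macro-averaged
F1, and per-class rank-based AUC, under a repeated (default 20×)
stratified 2/3–1/3 protocol with per-repeat feature selection.

A seeded synthetic-data module draws leg-shaped foregrounds with
painted lesion textures per concept and exact patch-level ground truth,
so the whole pipeline is testable without any clinical data.

## Worked example

```python
import numpy as np
from cvigrade.pipeline import PipelineConfig, run_end_to_end
from cvigrade.synthetic import SynthSpec, generate_dataset

data = generate_dataset(SynthSpec(n_per_class=30, seed=1))
config = PipelineConfig(seed=1, n_repeats=20)
result = run_end_to_end(
    [d.image for d in data],
    [d.scene_label for d in data],
    {s: [d.patch_labels[s] for d in data] for s in (15, 25, 50)},
    config,
)
print(result.representations.shape)
print({s: round(a, 3) for s, a in result.concept_patch_accuracy.items()})
print(round(result.combined["accuracy_mean"], 3),
      round(result.combined["kappa_mean"], 4))
```

prints (a few minutes of compute):

```
(90, 45)
{15: 0.967, 25: 0.963, 50: 0.964}
0.975 0.9625
```

i.e. the 90 synthetic images yield 45-dim representations, the per-scale
concept SVMs label ~96 % of all grid patches correctly, and the
20-repeat scene protocol reaches 97.5 % mean severity accuracy with a
Cohen's kappa of 0.96 on held-out thirds.

The same chain is scriptable stage by stage:

```sh
cvigrade synth --config config.yaml --workdir run/
cvigrade extract-features --config config.yaml --workdir run/
cvigrade train-concept   --config config.yaml --workdir run/
cvigrade represent       --config config.yaml --workdir run/
cvigrade select          --config config.yaml --workdir run/
cvigrade train-scene     --config config.yaml --workdir run/
cvigrade evaluate        --config config.yaml --workdir run/
cvigrade classify        --config config.yaml --workdir run/ photo.png --mask mask.png
```

Real data enters through a manifest CSV (`image_path, mask_path,
scene_label`) plus per-scale patch-label CSVs in the same format the
synthetic writer emits.

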