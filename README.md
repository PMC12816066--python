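# igscore

A tested, reusable implementation of the **immunologic gingival (IG) score**
pipeline: from chromogenic H-DAB immunohistochemistry images of five
immune-cell markers — CD3 (T cells), CD20 (B cells), CD138 (plasma cells),
CD68 (macrophages), CD66b (neutrophils) — to per-marker quantification
(% positive cells, cells/mm²), semi-quantitative 0–3 grades with
three-observer consensus, the 0–15 IG total, and cohort-level statistical
validation (Mann–Whitney U / Fisher's exact group tests, Spearman
correlation banding, ROC cut-off selection).

It is aimed at translational periodontitis researchers who want a
standardized, reproducible way to characterize gingival immune-cell
infiltrates, and at methodologists who want every stage of such a score to
be testable. Because gingival biopsy cohorts are hard to share, the package
includes a first-class synthetic-data module that generates seed-reproducible
cohorts (covariates, ground-truth infiltration, rendered H-DAB tiles with
every planted cell recorded) with the statistical structure of an
11-healthy vs 11-periodontitis study, so the full pipeline runs and is
validated with no downloads.

## The score

Each marker *m* is graded g_m ∈ {0, 1, 2, 3} (no / mild / moderate / severe
infiltrate) in the area of interest with the most intense staining, by three
blinded observers; the consensus grade is the one at least two observers
agree on (a three-way split is flagged for re-examination). The total

    IG = Σ_m g_m  ∈ [0, 15]

classifies a patient as periodontitis-like when IG ≥ cut-off. The cut-off is
chosen from the ROC over integer thresholds as the smallest maximizer of
Youden's J = sensitivity + specificity − 1, limiting false negatives.
Quantitatively, positive cells are counted after Beer–Lambert optical-density
transformation and H-DAB stain deconvolution; a cell is DAB-positive when its
mean DAB optical density over a 2 µm disc exceeds 0.3. CD138 quantification
excludes the epithelium (the antibody stains epithelial cells).

## Worked example

```python
import dataclasses
import numpy as np
from igscore import *
from igscore.config import CohortConfig, small_image_params

cfg = dataclasses.replace(CohortConfig(seed=1), image_params=small_image_params())
cohort = generate_cohort(cfg)

healthy = [p.ig_total for p in cohort if p.group == "healthy"]
perio = [p.ig_total for p in cohort if p.group == "periodontitis"]
print("healthy:", summarize_group(healthy).format())
print("perio  :", summarize_group(perio).format())
u, p = mann_whitney_u(healthy, perio)
print(f"Mann-Whitney U={u:.1f}, p={p:.2e}")

labels = [int(pt.group == "periodontitis") for pt in cohort]
res = roc([pt.ig_total for pt in cohort], labels)
c = select_cutoff(res)
i = int(np.flatnonzero(res.thresholds == c)[0])
print(f"AUC={res.auc:.3f}, cut-off={c}, "
      f"sens={100*res.sensitivity[i]:.1f}%, spec={100*res.specificity[i]:.1f}%")

slide = render_slide(cohort[12], "CD3", cfg, np.random.default_rng(5))
q = quantify_slide(slide)
print(f"{q.patient_id} CD3: area={q.analyzed_area:.3f} mm2, {q.n_cells} cells, "
      f"{q.n_positive} DAB+ ({q.pct_positive:.1f}%), {q.density_positive:.0f}/mm2")
```

prints

```
healthy: 1 (1–2)–1.4545
perio  : 10 (7–10.5)–8.2727
Mann-Whitney U=10.0, p=9.44e-04
AUC=0.917, cut-off=4, sens=90.9%, spec=100.0%
P02 CD3: area=0.147 mm2, 333 cells, 25 DAB+ (7.5%), 170/mm2
```

The group summaries are `median (Q1–Q3)–mean`: simulated healthy controls
sit near IG = 1 while periodontitis patients sit near 10, the groups
separate at p < 0.001, and the Youden rule selects cut-off 4 (one
periodontitis patient in this draw has a pauci-immune, healthy-like
infiltrate, hence the 90.9% sensitivity). The quantified CD3 tile recovers
170 positive cells/mm² against a planted ground truth of 151/mm² (grade 1).

## Command line

```sh
igscore simulate --config config.yaml --out fixture/ --seed 1   # cohort + slides + manifest
igscore quantify --slides fixture/ --out quant.csv              # stain → detections → counts
igscore grade    --quant quant.csv --out scores.csv             # densities → grades → IG totals
igscore stats    --scores scores.csv --cohort fixture/cohort.csv --out stats/
igscore run-all  --out run/ --seed 1                            # all four stages
```

Every run writes a manifest with the seed and a config hash; identical seeds
reproduce identical outputs.

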