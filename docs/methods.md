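# Methods

## The immunologic gingival (IG) score

The IG score summarizes immune-cell infiltration in a gingival biopsy from
five chromogenic immunohistochemical stains: CD3 (T cells), CD20 (B cells),
CD138 (plasma cells), CD68 (macrophages) and CD66b (neutrophils). Each
marker is graded semi-quantitatively on a 4-point scale (0 = no infiltrate,
1 = mild, 2 = moderate, 3 = severe) in the area of the section with the most
intense staining; the IG total is the sum of the five grades, range 0–15.
Grading is done by three independent observers blinded to periodontal
status; the final per-marker grade is the one at least two observers agree
on, and a three-way disagreement triggers re-examination. In this package
the human re-read is replaced by the median of the three grades, and the
event is always recorded in a `reexamined` flag so downstream statistics can
exclude or sensitivity-test those sections. A patient is classified
disease-positive when the IG total reaches a cut-off; the boundary counts as
positive, which minimizes false negatives.

## Synthetic cohorts

No real cohort is distributed, so `igscore.synthetic` generates one with the
statistical structure of the study conditions: 11 healthy controls vs 11
stage III/IV periodontitis patients (sizes configurable).

**Grades.** Per-marker grades are drawn from per-group × per-marker
probability vectors over 0–3, calibrated so that the simulated summaries
match the reported ones: healthy markers are typically grade 0 except CD68
(typically 1), giving a healthy IG median of 1; periodontitis markers are
typically grade 2 (CD138 with a tighter spread), giving a periodontitis IG
median of ≈ 9. A configurable `pauci_fraction` (default 1/11) of
periodontitis patients draws grades from the healthy distributions,
modelling the pauci-immune infiltrate profile seen in a minority of
patients; this also widens the periodontitis spread toward the reported
interquartile range. Because the five markers are drawn independently within
a patient, the simulated IG-total IQRs are still somewhat narrower than the
reported ones (real inter-marker correlation is not modelled); medians are
matched.

**Densities.** Each grade maps to a ground-truth positive-cell density band
(defaults: grade 0 → [0, 25), 1 → [25, 200), 2 → [200, 800),
3 → [800, 2000) cells/mm²); the true density is uniform within the band.
The atlas behind the visual grades carries no numeric anchors, so these
bands are an artifact calibration, exposed in `CohortConfig`. The grading
thresholds default to the band edges, so noise-free pipelines are
self-consistent by construction.

**Covariates.** Ages are uniform within the reported per-group IQRs; probing
pocket depth and attachment loss are discrete mm distributions matched to
the reported median/quartiles/mean; total bacterial load is log-normal with
median and IQR-matched sigma per group. Binary covariates (gender, smoking,
*P. gingivalis* presence, stage 4) are assigned by exact composition —
round(p × n) patients, randomly permuted — so the default cohort reproduces
the reported 9/2 vs 4/7 gender split, 1-of-11 vs 10-of-11 pathogen
prevalence, etc., exactly. *P. gingivalis* load is drawn as a per-patient
ratio of the total-bacteria amount (logit-normal, median 33%, IQR 14–54%),
which guarantees pg ≤ total and reproduces the ratio row directly; the
ratio is reported as a percentage.

**Observers.** Each simulated observer reports the true grade with
probability 1 − ε and otherwise deviates ±1 (direction 50/50, clamped to
[0, 3]). The default ε = 0.18 makes ≈ 1.5–2% of marker-sections produce
three distinct grades, matching the observed ~2% re-examination rate; at
middle truths the three-distinct probability is 6(1−ε)(ε/2)².

**Slides.** A tile is gingiva seen en face: a wavy epithelial band along the
top edge, connective tissue below, with a junction band (default 150 µm) of
connective tissue adjacent to the epithelium. Positive cells are planted by
marker-specific spatial kernels — CD3/CD20/CD66b concentrate in the junction
band (default 75% affinity), CD68 is uniform in connective tissue, CD138
concentrates beyond the band — and counterstain-only nuclei fill the tissue
to a total density of 2500 cells/mm². The planted positive count is
round(true density × tissue area). Rendering follows a two-stain
Beer–Lambert model: each nucleus deposits a hematoxylin disc (amplitude
0.5–0.9 OD), positives additionally a DAB disc (0.6–1.0 OD), converted to
RGB through the standard H-DAB stain vectors with additive intensity noise
(σ = 1% of full scale). For CD138 a diffuse DAB wash (0.4 OD) covers the
epithelium, emulating the antibody's epithelial cross-reactivity — this is
what makes the epithelium-exclusion rule consequential and testable. Not
modelled: scanner optics and compression, tissue folds, stain batch
variation, non-circular nuclei, 3-D sectioning effects; pipeline accuracies
measured on these tiles are therefore upper bounds for real slides.

Default tiles are 2000 × 2000 px at 0.5 µm/px (1 mm²). The test fixture and
examples use 384 × 384 px at 1.0 µm/px (0.147 mm²) — the pipeline is
identical at any tile size, and the small geometry keeps the full
110-section fixture fast to regenerate.

## Quantitative image analysis

`igscore.stain` re-implements the digital quantification pathway:

1. **Optical density.** OD_c = −log₁₀((I_c + ε)/I0_c) per channel, ε = 0.5
   guarding zero intensities, clipped at 0.
2. **Deconvolution.** Per-pixel linear solve of OD = cᵀM with unit stain
   vectors (rows hematoxylin, DAB, and their normalized cross product as
   residual; Ruifrok–Johnston H-DAB values by default, overridable).
   Negative concentrations are clipped to zero and the RMS reconstruction
   residual is reported.
3. **Nucleus detection.** Gaussian smoothing of the hematoxylin channel
   (σ = 0.5 × minimum radius), foreground threshold 0.15, watershed seeded
   by Euclidean-distance-transform peaks (minimum seed separation 2 µm),
   components filtered to [16, 400] µm². The distance transform, rather
   than the smoothed intensity, seeds the watershed because planted nuclei
   vary in staining amplitude but are round; this splits touching nuclei
   more reliably. Residual under-segmentation at high density biases
   absolute counts low by roughly 10–25% on crowded tiles, but the bias is
   monotone (rank correlation with planted density ≈ 1) and cancels in the
   positive *fraction*, which is the quantity the percentage endpoints use.
4. **DAB classification.** A detection is positive iff the mean DAB
   concentration over a 2-µm disc at its centroid exceeds 0.3 OD. A single
   threshold suffices because the score needs only positive/negative, not
   1+/2+/3+ tiers.
5. **Quantification.** Analyzed area = mask pixels × pixel-size² (mm²),
   with the epithelium subtracted for CD138; detections outside the mask
   are dropped; outputs are counts, % positive and positive cells/mm².
   Quantifying with exclusion is exactly equivalent to quantifying on the
   pre-subtracted mask.

Coordinates are row-major with origin top-left; areas are full pixel counts;
µm/px must be supplied (no metadata sniffing).

## Area of interest and density grading

For quantitative grading, `select_aoi` scans every fully-inside position of
a square window (default 500 µm side) with an exact integral-image count and
returns the densest window, ties broken toward the smallest (row, col). The
whole-section visual impression of "most intense staining" has no unique
computational equivalent; the windowed maximum is the documented surrogate.
Density maps to a grade by left-closed intervals (density = cut-point takes
the higher grade), so grades are monotone non-decreasing in density.

## Cohort statistics

Group differences use the two-sided Mann–Whitney U test (exact permutation
null when both arms have ≤ 12 observations and no ties, tie-corrected
normal approximation otherwise) for quantitative variables and Fisher's
exact test (two-sided by the probability-mass rule, conditional MLE odds
ratio) for binary ones; both delegate to scipy with these conventions and
are verified against full-enumeration oracles in the tests. Correlations
use Spearman's rho (t-approximation p) with strength bands on |rho|:
< 0.4 slight, 0.4–0.59 moderate, 0.6–0.79 strong, ≥ 0.8 very strong, and
stars at 0.05/0.01/0.001/0.0001. p-values are unadjusted by default, as in
the original analysis; Benjamini–Hochberg is opt-in. Group summaries are
median (Q1–Q3)–mean with linearly interpolated quartiles (numpy method
names accepted). The ROC sweeps the integer cut-offs 0–16 with
score ≥ cut-off ⇒ positive (IG totals are integers, so non-integer
thresholds add nothing); AUC is the trapezoid over (1 − specificity,
sensitivity) in decreasing-cut-off order; the selected cut-off is the
smallest maximizer of Youden's J, which limits false negatives when several
cut-offs tie.

Under the default calibration, 200 simulated 22-patient cohorts yield a
modal selected cut-off of 4: healthy totals cluster at ≤ 3 with the
occasional higher outlier, periodontitis totals at ≥ 6 with the occasional
pauci-immune outlier, so the tied optimal band typically starts at 4 and
the smallest-tie rule picks it. `scripts/acceptance.py` recomputes this
end to end.

## Numerical and design choices

- One seeded RNG per run (`numpy.random.default_rng`); per-slide and
  per-cohort streams are spawned from a `SeedSequence`, so determinism holds
  within this implementation but bit-identity across libraries/platforms is
  not promised.
- Fixture manifests hash array and table *contents* (not container files),
  so re-runs with the same seed produce identical manifest hashes regardless
  of container-format metadata.
- Degenerate inputs fail loudly: empty masks, zero analyzed area, zero
  margins, constant vectors and single-class ROC inputs raise typed errors
  rather than returning NaN.
- `pct_positive` is defined as 0 for slides with no detected cells (the
  invariant ratio applies when n_cells > 0).

## Known limitations

- Inter-marker correlation within a patient is not modelled (beyond the
  pauci-immune mixture), so simulated IG-total dispersion is conservative.
- Detection accuracy is validated against synthetic truth only; the
  defaults (σ factor, thresholds, area bounds) are calibration choices, not
  measured properties of any real scanner or stain batch.
- Covariates are drawn independently of grades within each group, so
  covariate–score correlations in pooled cohorts are group-driven.
- No AUC confidence intervals and no adjusted/multivariable analyses.
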