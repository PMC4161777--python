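# Methods

## The assay being modelled

A cytospin slide carries ~250,000 PBMCs; patient material is screened at
500,000 PBMCs per patient. Candidate tumour cells are found by
pan-cytokeratin (CK8/18/19) immunofluorescence and confirmed as CTCs by
cytomorphology: size larger than white blood cells and a high
nuclear-to-cytoplasmic (N:C) ratio. A second staining panel (CK + CD45)
excludes haematopoietic cells with ectopic cytokeratin. Confirmed CTCs are
phenotyped by ALDH1 expression level and TWIST subcellular localization, and
patients from two clinical settings (early, pre-adjuvant vs metastatic,
pre-first-line) are compared.

The criteria are qualitative in the source assay; this package makes each one
an explicit, configurable rule and documents its default.

## Segmentation and CTC calling

- Nuclei: Otsu threshold on the smoothed DAPI channel, connected components
  ≥ `min_nucleus_area` (20 px²), touching nuclei split by watershed seeded at
  peaks of the smoothed distance transform (minimum peak separation 5 px). A
  field whose Otsu foreground exceeds 30% of pixels is treated as
  nucleus-free: nuclei are sparse on a cytospin, so such a threshold has only
  split the noise floor.
- Cell body: CK-positive pixels connected to the nucleus, truncated 12 px
  from the nucleus boundary; CK positivity is background mean + 5·sd over
  non-nucleus pixels. CK-negative cells default to the nucleus dilated by
  2 px (PBMCs have scant cytoplasm).
- Coordinates are 0-based (row, col); segmentations are label images; border
  cells are kept but flagged (`on_border`) — CTCs are too rare to discard.
- CTC rule defaults: "larger than WBCs" = equivalent diameter ≥ 1.25 × the
  median equivalent diameter of CK-negative cells on the same field
  (estimated per image; an error demands ≥ 20 CK-negative cells or an
  explicit fallback constant); "high N:C" = nucleus area / cell area ≥ 0.5.
  Both margins are conventions of this implementation, chosen to sit well
  between the simulated PBMC (~12 px measured diameter, N:C ≈ 0.45) and
  tumour (~19 px, N:C ≈ 0.6–0.67) populations, and both are config-exposed.

## ALDH1 exposure-time calibration

The screening platform reports marker strength as the exposure time needed to
detect signal: brighter ⇒ shorter. All published calibration values are
multiples of 5, so the grid step 5 is treated as a model invariant. The
platform's intensity→exposure transform is not public; this package uses

    exposure = quantize₅(clip(c / (I + ε), 5, max_exposure)),  c = 60,000

with `I` the background-subtracted mean intensity over the cell interior
(the cell mask eroded by 2 px — edge pixels are partial-volume contaminated
and would bias the mean downward by ~10%, enough to cross a class boundary).
Any strictly decreasing map reproducing the calibration grid would do; this
one is simple and invertible, and the synthetic renderer uses its inverse so
that calibration is round-trippable by construction. ALDH1 is measured over
the whole cell (nucleus + cytoplasm) because the assay reports a single
per-cell level with no compartment distinction.

Cut-offs come from `derive_cutoffs` on labelled control-cell measurements
(500 cells per class in the shipped configuration): class boundaries are the
observed range endpoints, with per-class median ± SE retained. Overlapping
class ranges abort the calibration. Defaults reproduce the published
positive-control line: high ≤ 25, low 30–55, negative ≥ 60 (medians
15/45/70). Grid values in the gaps (26–29, 56–59) are unreachable after
quantization and raise an error — they signal a mis-calibrated model, not a
data condition.

## TWIST localization

A compartment is TWIST-positive when ≥ 30% of its pixels exceed background
mean + 5·sd. The localization rule is asymmetric by design: nuclear wins
whenever nuclear signal is present (nuclear localization is what makes a
transcription factor functional), `cyt` requires signal exclusively in the
cytoplasm, and `neg` means neither compartment fires. An empty cytoplasm mask
is a legitimate degenerate case (cytoplasmic-not-detected), not an error.

## Phenotypes and cohort statistics

ALDH1 {high} vs {low, neg} and TWIST {nuc} vs {cyt, neg} collapse to a 4-way
taxonomy: high_nuc, high_cytneg, lowneg_nuc, lowneg_cytneg. Aggregation
follows the assay's reporting conventions: detection rate over all patients;
everything else over detected patients only; "exclusive" means every CTC of
the patient carries the category; pooled CTC-level percentages and unweighted
means of per-patient percentages are reported side by side. Percentages are
rounded to one decimal only at reporting time; internal arithmetic is
unrounded.

Tests: chi-square with continuity correction (Yates, |O−E|−0.5 floored at
zero, so a perfectly null table gives χ² = 0) on 2×2 patient-frequency
tables; Mann-Whitney on per-patient percentage distributions (exact null
distribution for small untied samples, normal approximation with tie
correction otherwise — the method used is recorded in the result); Spearman
rank correlation with midrank ties on pooled per-CTC binary indicators,
which are reconstructed exactly from the phenotype counts. CTC-negative
patients are excluded from Mann-Whitney by default (config-switchable). No
multiple-testing correction is applied by default, matching the assay's
reporting; `compare_cohorts(..., bh_correction=True)` adds
Benjamini–Hochberg-adjusted columns.

## Synthetic data

The generator emulates what the pipeline must cope with, not optics:

- Cells are flat discs with soft edges (DAPI and CK are Gaussian-smoothed,
  σ = 0.8 px); nucleus radius = cell radius × √(N:C). PBMC nuclei
  8 ± 0.7 px diameter with a 1 px cytoplasm rim; tumour cells 18 ± 1 px with
  N:C 0.7 — preserving the "larger than WBC, high N:C" ordering at a nominal
  1 px = 1 µm without claiming real magnification. Marker channels (ALDH1,
  TWIST) are rendered flat and unsmoothed so compartment means equal the
  rendered values exactly.
- ALDH1 on tumour cells: a target exposure drawn uniformly from the grid of
  the cell's true class, pushed through the inverse calibration map. TWIST:
  rendered in the nucleus (plus 60% amplitude in the cytoplasm, exercising
  the co-localization rule) for `nuc` cells, cytoplasm only for `cyt`, absent
  for `neg`. PBMCs are CK-negative with diffuse non-zero ALDH1/TWIST
  background (N(600, 200) / N(500, 200) intensity), as real PBMCs show.
- Camera model: constant offset 100, additive Gaussian noise σ = 60, 16-bit
  clipping. Default field: 1024×1024 px, 800 PBMCs (tests use 384–512 px
  fields with 120–200 PBMCs); a physical slide's 250,000 cells are
  represented as many fields. Cells are placed by rejection sampling with a
  4 px minimum edge gap — overlap and occlusion are deliberately absent, so
  segmentation counts are exact by construction and count tests are sharp.
- Randomness: one seed sequence per image, spawned into per-cell streams, so
  a fixed seed is bit-reproducible and appending a spiked cell does not
  reshuffle existing cells.
- Spike-in experiments use a multiplicative stage-loss model (each cell
  survives each processing stage independently); cohort tables draw
  detection Bernoulli(rate), then a zero-truncated Poisson CTC count, split
  multinomially by phenotype. The default conditions are the two clinical
  settings' published detection rates (16.3% / 50%), mean burdens (31/13 and
  91/25 CTCs per detected patient) and pooled phenotype mixes.

What passing tests on this material does **not** show: robustness to
overlapping or apoptotic cells, staining gradients, autofluorescence,
bleed-through, focus drift, or CK-positive debris. The simulator is a
correctness harness for the decision rules and statistics, not an image
realism benchmark.

## Numerical choices and degenerate inputs

- Quantization rounds half away from zero to the nearest grid step; clipping
  runs to `max_exposure` (zero intensity ⇒ maximum exposure, i.e. negative).
- Background subtraction clamps at zero before exposure conversion; negative
  mean intensities are impossible by construction.
- A blank DAPI channel yields an empty cell table, not an error; an empty
  nucleus mask anywhere else is an error.
- Equivalent diameter is that of a circle with the cell's pixel area;
  rasterization makes small-radius ratios slightly below their analytic
  values (tests allow ±0.03 on N:C).
- Chi-square requires strictly positive margins; `compare_cohorts` reports
  NaN for categories absent from both cohorts rather than failing the run.

## Known limitations

- Sensitivity on synthetic fields is ~98%, not 100%: a dim nucleus can
  under-segment against Otsu's global threshold and drop the measured N:C
  below 0.5. Accepted as the cost of a parameter-free nucleus threshold.
- The published per-patient table contains two internal inconsistencies (a
  percentage pair inconsistent with its own printed counts, and one
  truncated-not-rounded percentage); recomputation from counts is treated as
  authoritative in both cases.
- The exposure map constant c is a convention shared between renderer and
  calibration; real instruments would require calibrating c against labelled
  intensities, which the API supports via `derive_cutoffs(..., scale=...)`.
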