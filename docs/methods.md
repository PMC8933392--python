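# Methods

`histogate` re-implements, as a tested pipeline, the biomarker-quantification
computations behind percent-positive p16^INK4A^ immunohistochemistry (IHC)
scoring and cyclic-immunofluorescence (CyCIF) intensity gating. This note
documents the models, their assumptions, the defaults, and what the synthetic
data do and do not establish.

## Brightfield stain model

A hematoxylin/DAB (H-DAB) brightfield pixel is modelled by Beer–Lambert
absorption: per RGB channel `c`,

    OD_c = −log10(I_c / I0_c),

with `I0` the unstained background (default 255 per channel). Stain amounts
add linearly in OD space along fixed unit vectors; per-stain concentrations
are recovered by inverting the 3×3 stain matrix (Ruifrok–Johnston colour
deconvolution). The default vectors are the standard H-DAB pair,
hematoxylin ≈ (0.650, 0.704, 0.286) and DAB ≈ (0.269, 0.568, 0.778)
(normalized), with the residual channel set to their normalized cross
product. Stain vectors are configurable; estimating them from the image
(Macenko-style) is out of scope. Negative concentrations produced by noise
are clipped to zero after unmixing; the unclipped transform is exactly
invertible and the round-trip error on random concentration fields is below
1e−6 OD (in practice ~1e−16).

## IHC scoring

Nuclei are detected on the hematoxylin concentration map as pixels above a
uniform OD threshold (default 0.3), cleaned by a 3×3 morphological opening,
labelled as connected components, optionally split by a watershed on the
distance transform (markers = local maxima at `watershed_min_distance`,
default 5 px), and filtered by a minimum area (default 20 px). For each
nucleus the mean DAB OD is measured over the nucleus and over a cytoplasmic
annulus (default width 3 px) that excludes pixels of any nucleus. A cell is
DAB-positive when either compartment mean exceeds the DAB threshold
(default 0.3, strict `>`; ties fall negative — one consistent convention for
every threshold in the package). The thresholds are interpreted in OD units
throughout.

Percent positive = 100 × DAB-positive cells / hematoxylin cells per region
of interest (ROI); a section is summarized as mean ± sample SD (n−1
denominator) over its ROIs (three expected; fewer triggers a warning, ROIs
with zero hematoxylin cells are flagged and excluded, and a single usable
ROI reports SD 0 with a flag).

## DAB-threshold calibration

The DAB threshold is selected against manual counts by Bland–Altman
analysis. For each candidate threshold the automated DAB-positive count per
test image is compared to the across-observer mean manual count. With
differences d_i = manual_i − automated_i:

* bias = mean(d), sd_diff = sample SD(d);
* limits of agreement = bias ± 1.96·sd_diff;
* 95% CI of the bias = bias ± t_{0.975, n−1}·sd_diff/√n.

Both interval types are computed and labelled explicitly, because they
answer different questions and reports in the literature do not always say
which one they print. The selected threshold minimizes |bias|; ties break
toward the larger (more conservative) threshold. Differences are computed on
counts by default; a percent-positive mode is available. Internally the
per-cell OD measurements are made once per image and each candidate
threshold is re-applied to the stored measurements — numerically identical
to re-scoring per candidate, since detection depends only on the hematoxylin
threshold. Inter-observer concordance is reported as pairwise Pearson r
(two-sided t-distributed p).

## CyCIF normalization and mixture gating

Raw mean fluorescence intensities are normalized across samples per marker:
`x → log10(x + 1)`, then an additive per-sample shift aligns each sample's
median to the pooled median. The transform is order-preserving within a
sample, stored, and exactly invertible, so gates set on the normalized scale
map back to raw intensities per sample. A sample whose intensities are all
zero for a marker is flagged and given shift 0.

Median alignment assumes the median is a stable location estimate, which
holds when the two components are unbalanced (the median sits inside the
majority mode). For a near-50/50 mixture the median falls in the low-density
valley between modes and the estimated shifts become noisy; this is a known
limitation of the normalization choice, not of the mixture fit.

Per marker, a two-component univariate Gaussian mixture is fitted by EM on
the pooled normalized values (per-sample fitting is available behind a
flag). Initialization splits the sorted data at a quantile — the median
first, then seeded random quantiles in [0.25, 0.75] over 5 restarts — and
the best final log-likelihood wins. The E-step runs in log space;
convergence is a log-likelihood gain below 1e−8 or 500 iterations; a
variance floor of 1e−6 prevents component collapse; components are reported
with μ1 < μ2. The log-likelihood trace is retained and checked non-decreasing
in tests, and the fit is cross-checked against an independent EM
implementation (scikit-learn) on the same data.

The positive threshold is the **peak of the positive component**, i.e. μ2
(the peak of a Gaussian density is its mean), mapped to the raw scale as
`10^(μ2 − shift) − 1` per sample. Cells are positive iff their normalized
value strictly exceeds μ2. Gating at the positive component's peak rather
than at the inter-component valley places roughly half of the positive
component below the gate by construction; the package implements this rule
exactly and does not correct it, so called-positive fractions approximate
half the mixing weight of the positive component when components are well
separated.

## Cell typing and condition summaries

Tumor cells are identified by cytokeratin > 2.5 on the normalized scale;
tumor cells are then flagged per marker by strict thresholds: Lamin B1 > 3.3,
cleaved caspase-3 > 1.9, pH2Ax > 2.9, p16 > 2.8, p-RB > 2.7, PCNA > 3.3.
The Lamin B1 and cleaved caspase-3 rules are treated as independent (the
listing's comma is read as two rules, matching the pattern of the other
thresholds); a conjunction mode is available for sensitivity analysis.
Marker flags are NA for non-tumor cells. Per-section positive fractions
among tumor cells are aggregated per condition as mean ± sample SD and
compared pairwise with two-sided unpaired t-tests (Student's by default,
Welch behind a flag); a condition with fewer than two sections is flagged
not-computable.

## Cohort classification

A sample is 'positive' when its percent-positive value strictly exceeds the
cutoff (default 30%), otherwise 'deficient'. The strict rule assigns exactly
30% to deficient, keeping one consistent convention (the source convention
writes positivity as >30% and deficiency as <30%, leaving the boundary
unassigned). CDKN2A copy number is carried as annotation only — no
classification logic uses it. The cohort summary reports deficient counts
and proportion, per-source (PDX vs patient) mean ± SD, Pearson r with p over
matched pairs (≥3 pairs required; fewer is flagged), and a two-sided
unpaired Student's t-test between the matched arms (a paired option exists
for sensitivity analysis).

## Synthetic data

The generators provide ground truth for every stage and define the test
conditions:

* **IHC fields** — non-overlapping nuclear disks (radius ~ N(6, 1²) px,
  clipped at 2) placed by rejection sampling in a 512×512 field with enough
  clearance that cytoplasmic annuli (width 3 px) never touch another cell.
  Stained nuclei carry hematoxylin OD 0.6; DAB-positive cells carry DAB OD
  (default 0.6) in the nucleus, or in the annulus for cytoplasm-only cells.
  Gaussian noise (SD 0.01 OD) is added in OD space, the image is converted
  to transmittance and quantized to 8-bit RGB against a 255 background.
  By default exactly round(fraction·n) cells are positive (exact-assignment
  mode), so image-level truth is noiseless; i.i.d. Bernoulli assignment is a
  flag. Placement failure after a bounded retry budget raises an explicit
  error.
* **Intensity tables** — per marker, log10 intensity is a two-Gaussian
  mixture (defaults: means 1 and 3, SD 0.1) plus an additive per-sample
  shift, exponentiated to the raw scale. Component labels are returned.
* **Observer counts** — each observer's count is
  max(0, round(truth + bias + N(0, dispersion))).

What the synthetics deliberately omit: tissue autofluorescence, stromal and
tumor spatial architecture, overlapping/touching nuclei, stain-intensity
heterogeneity within a cell, imaging-cycle registration error, and
non-Gaussian intensity tails. Passing tests therefore demonstrate that the
computations are implemented correctly and recover known truth under the
stated model — not that the pipeline segments real tissue robustly; on real
images the detection step (deliberately the simplest pipeline honouring the
uniform hematoxylin threshold) would face merged nuclei, chromatin texture
and background that these fields do not contain.

## Numerical choices and degenerate inputs

* All threshold comparisons are strict; ties fall negative.
* Percent positive with zero hematoxylin cells raises an explicit
  undefined-score error (an ROI inside a section is excluded with a flag
  instead).
* Pearson correlation on constant vectors and mixture fits on constant data
  raise zero-variance errors; mixture fits need n ≥ 20.
* A non-converged mixture fit is returned with `converged=False` and must be
  explicitly forced before gating.
* `rgb_to_od` floors pixels at 1 to avoid log(0); OD is clipped at 0.
* Test tolerance budgets for image-based checks include ±0.02 OD for 8-bit
  quantization.

## Problem sizes

Default verification sizes: 200 cells per ROI and 3 ROIs per section for
scoring recovery; 8 test images × 120 cells for calibration; n = 4000 for
mixture-recovery and typing checks; a 21-section cohort (120 cells per ROI)
for classification. These sizes give Monte-Carlo error comfortably inside
the stated tolerances (e.g. scoring recovery is exact up to detection error
under exact-assignment mode) while keeping a full run to seconds.
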