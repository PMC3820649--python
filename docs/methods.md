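# Methods

## Model

The package treats a fibrotic lung as a two-phase medium on a voxel grid.
Each lung voxel is either aerated parenchyma or consolidated (fibrotic)
tissue; HU values are drawn independently from the corresponding Gaussian
component and clamped to the 12-bit CT range [−1024, 3071]. For a lung
with consolidation fraction *f* the tail probability of the HU histogram
is the mixture tail

    P(HU ≥ T) = f Φ((μ_c − T)/σ_c) + (1 − f) Φ((μ_a − T)/σ_a),

so V_T (percent volume at or above threshold T) and all HU percentiles
have closed-form expectations. The model deliberately ignores spatial
correlation of noise, partial-volume voxels at interfaces, airways and
vessels, beam hardening, scatter and reconstruction kernels: it reproduces
the *histogram* of a fibrotic lung, which is all the densitometric
readouts consume. Passing tests therefore validate the analysis code and
its statistical behaviour, not the realism of any individual image; on
real scans, segmentation quality and partial-volume effects will add
variance the phantom does not exhibit.

## Default calibration

| parameter | default | meaning |
|---|---|---|
| μ_a, σ_a | −500, 100 HU | aerated murine lung parenchyma |
| μ_c, σ_c | +100, 100 HU | consolidated/fibrotic tissue (soft-tissue range) |
| stage table f(week) | 0→0.00, 8→0.03, 12→0.08, 16→0.50, 20→0.95 | consolidation fraction of the irradiated lung |
| grid, spacing | 128×128×96, 0.25 mm isotropic | mouse-scale thorax (spacing configurable) |
| n_patch_seeds | 5 | number of consolidation blobs |
| fibrosis threshold | −200 HU | V₋₂₀₀ reported always |
| PF call cuts | histology ≥ 12, V₋₂₀₀ ≥ 10% | dual criterion, both required |

The component spreads are chosen so that at f = 0.5 the mixture is exactly
symmetric about −200 HU. That single choice pins down the whole landmark
trajectory analytically: HU₅₀ = −500 and V₋₂₀₀ = 0.13% in normal lung
(f = 0), V₋₂₀₀ = 8.1% at f = 0.08, HU₅₀ = −200 with V₋₂₀₀ = 50.0% at
f = 0.5, and near-total opacification (V₋₂₀₀ ≈ 95%) at f = 0.95. A
narrower aerated component (e.g. σ_a = 80) would leave a density gap
around −200 HU in which the sample median is ill-conditioned — it can sit
tens of HU below the threshold even when V₋₂₀₀ is exactly 50% — so the
symmetric calibration is preferred for stability as well as for hitting
the landmarks. With ≥ 10⁵ lung voxels, the sampling standard error of
HU₅₀ at f = 0.5 is ≈ 3 HU and of V₋₂₀₀ is ≈ 0.15 percentage points.

## Consolidation morphology

Patches are grown from `n_patch_seeds` uniformly sampled seed voxels by
randomized 6-connected region growth, one voxel at a time, stopping at
exactly ⌈f·N⌉ voxels (N = target-lung voxel count). The exact count is a
hard invariant — it makes the empirical mixture weight deterministic and
the mixture-tail oracle sharp. If growth exhausts a connected component
before reaching the target (impossible for the ellipsoidal default lungs,
possible for user-supplied masks), a fresh seed is drawn from the
remaining lung. Connectivity and seed placement are the simplest choices
that produce patchy, reproducible morphology; no claim of biological patch
shape is made.

## Densitometry conventions

- **Threshold sense**: V_T counts voxels with HU **≥** T (at-or-above).
  For continuous HU the difference from a strict inequality is a set of
  measure zero; for quantized data it is sub-voxel.
- **Percent volume** is count-based. All voxels of one scan share one
  physical volume, so counting and physical-volume integration agree
  exactly under uniform spacing; for anisotropic spacing the single shared
  voxel volume still makes them identical.
- **Percentiles** use linear interpolation between order statistics
  (`numpy.percentile` default), deterministic and median-consistent.
- The default density-curve grid spans −1000 to +200 HU in 10 HU steps.

## Histology and cohort tables

Slide grades 0–4 (Roman I–IV mapped to 1–4) over exactly three slides give
the 12-point per-animal score; group summaries report mean ± SEM with the
n−1 sample SD (SEM reported as 0 for n = 1). The generator links grade to
stage as grade = clamp(round(4f + N(0, σ_h)), 0, 4) with σ_h = 0.5 by
default — a monotone severity link reaching the ceiling at full
consolidation; the grade–CT relation is a modeling choice, not an
empirical calibration. Survival is a per-study Bernoulli death per animal
(death week uniform over the study when it occurs). Assay timecourses are
per-day replicates around a configurable mean trajectory with 10%
coefficient of variation; defaults emulate ligand/receptor expression
rising ~3-fold over 28 days after lung injury.

## Inference

"Student's t-test" is implemented literally as the pooled-variance
unpaired two-tailed test (df = n₁ + n₂ − 2), with Welch's variant behind a
flag. Zero pooled variance raises an explicit error rather than returning
an infinite statistic. Timecourse significance flags compare each day's
replicates against day 0 at α = 0.05 with no multiple-testing correction
across days (deliberate, documented). Drug arms are compared only against
their matched vehicle arm, never pooled vehicles. Animals dead before the
endpoint are excluded from endpoint fibrosis means and surface only in the
mortality percentage. The PF call is the conjunction of the histology cut
(default: the full 12-point ceiling) and the CT cut (default V₋₂₀₀ ≥ 10%,
the smallest round cut separating the normal < 5% and 12-week < 10% ranges
from overtly fibrotic lungs); both cuts are configurable.

## Numerical and degenerate-input choices

- Phantoms are bit-reproducible for a fixed config: one `numpy`
  Generator seeded from `rng_seed` drives seeding, growth and rendering in
  a fixed order.
- Empty-mask selections, absent labels, grid/spacing mismatches, f outside
  [0, 1], out-of-range grades, and non-positive vehicle means all raise
  typed errors rather than propagating NaN.
- Volumes are float32 on disk (NIfTI-1); masks uint8 with labels {0, 1, 2}.
  DICOM import applies per-slice rescale slope/intercept and rejects
  non-CT modalities.
- Phantom lungs are pure parenchyma by construction: no hilar structures
  are modeled, so the "whole lung" mask has no exclusion ambiguity.

## Problem sizes

The default phantom grid (128×128×96, ~1.1×10⁵ voxels per lung) is used
for all landmark and mixture-recovery checks; structural and pipeline
tests use a 64×48×48 grid (~10⁴ voxels per lung) for speed. The full test
suite runs in well under a minute on one CPU.

## Known limitations

- No spatial noise correlation or partial-volume modeling; empirical V_T
  variance on real scans will exceed the binomial bound used in tests.
- The grade–consolidation link is assumed, not fitted; attenuation
  percentages computed on synthetic cohorts inherit it.
- Survival is a per-study Bernoulli, not a hazard model; Kaplan–Meier/Cox
  analyses are out of scope.
- Automatic lung segmentation is out of scope: masks are inputs or
  phantom-generated.
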