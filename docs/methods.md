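# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `nirgrid`, in the spirit of the methods documentation of
mature statistical packages.

## 1. Data model

A `SpectraBlock` holds scan-level absorbance spectra on a shared wavenumber
axis (cm⁻¹, conventionally descending), with per-scan `sample_id`,
`replicate_id` and `class_label`. Invariants enforced at construction: a
strictly monotone axis, a uniform step within each contiguous segment
(tolerance 1e-9 cm⁻¹), no missing intensities, and a single class label per
sample. Files are wide delimited text (comma default, tab accepted), one
scan per row, wavenumbers as numeric column headers; values are written with
17 significant digits so write→read round-trips are exact for metadata and
below 1e-12 for intensities. Missing values are rejected, not imputed.

## 2. Pre-processing operators

Operators run in a fixed flow: (1) wavenumber reduction into closed-interval
segments, (2) smoothing if at position 2, (3) MSC, (4) detrending, (5)
derivative, (6) smoothing if at position 6, then binning — all per segment —
then segment concatenation, replicate averaging, and centering. A strategy
applies smoothing at most once.

- **Savitzky–Golay smoothing** (`order` 2, `frame` 3 default): delegated to
  `scipy.signal.savgol_filter` with `mode="interp"`, which evaluates the
  polynomial of the nearest full window at the edges. With the default
  setting the filter is exactly the identity (a parabola through three
  points interpolates them); other frames are supported for completeness.
- **MSC**: per-spectrum OLS fit `x ≈ a + b·ref`, output `(x − a)/b`. The
  default reference is the column-wise mean of all scans in the block being
  corrected. A slope `|b| < 1e-12` (e.g. against a constant reference) is a
  hard error naming the scan. Note the default reference uses *all* scans,
  including future test samples — faithful to common chemometrics practice
  but technically leaking across CV folds; `CVConfig(fold_safe_msc=True)`
  recomputes the reference from outer-training scans only
  (`msc_references_from_samples`) and is the recommended setting for honest
  error estimates on real data. The default remains the practice-faithful
  variant.
- **Detrending** (order 2 default): least-squares polynomial in the
  wavenumber coordinate, fitted on a [-1, 1]-rescaled axis for conditioning
  (the fitted subspace is invariant to that rescaling). Residuals have zero
  projection on the polynomial basis; the operator is idempotent.
- **Gap-segment derivative** (gap 11, segment 11 default): finite
  differences of segment means. `gap` is the **center-to-center** distance
  in points between segments; `segment` is the points averaged per segment.
  First order: `(right − left)/(gap·Δ)`, attributed to the midpoint of the
  two segment centers (a half-step axis offset when `gap` is odd). Second
  order: three segments with centers `gap` apart,
  `(left − 2·center + right)/(gap·Δ)²`, attributed to the middle center.
  `Δ` is the signed axis step, so results are true derivatives with respect
  to the wavenumber. This geometry makes "line → constant slope" (first) and
  "affine → zero" (second) hold exactly, which is the defining sanity
  property of the construction. Edge points without a full window are
  dropped and the axis shortened accordingly.
- **Binning**: non-overlapping window means; the trailing partial window is
  discarded (averaging unequal window sizes would distort the tail); the
  binned axis value is the mean wavenumber of the window.
- **Averaging**: `mean` and `median` are column-wise statistics over a
  sample's scans; `median_spectrum` returns the actually measured scan
  minimizing the sum of Euclidean distances to the sample's other scans
  (ties → lowest scan index). The distance-sum minimizer was chosen because
  it always returns a genuinely measured spectrum.
- **Centering**: column mean or median subtraction over the averaged
  (one-per-sample) matrix, or none.

Segments are closed intervals on the stored axis (a column is kept iff
`low ≤ w ≤ high`). Per-segment processing with reassembly only before
averaging avoids derivative/smoothing artifacts across the gap between
segments.

## 3. Strategy grid

`GridConfig` declares option lists per field; enumeration is the Cartesian
product after de-duplication and canonical per-field ordering, minus any
combination violating `PipelineSpec` invariants, in a deterministic
lexicographic order. The shipped `default_grid()` crosses six wavenumber
range choices (11,550–3950; 11,550–6500; 11,000–3950; 9000–3950; 8000–3950;
and the split 11,550–5500 + 5000–3950) with 3 smoothing × 2 MSC × 2 detrend
× 3 derivative × 6 binning × 3 averaging × 3 centering options — 11,664
strategies. The range list is the set certain from published strategy
tables of this kind; no claim is made that it reproduces any particular
historical grid size.

Ranking sorts by mean accuracy (descending); ties break toward fewer active
pre-processing steps (counting smoothing, MSC, detrending, derivative,
binning > 1 and centering ≠ none), then by the lexicographic strategy order,
so equally accurate simpler strategies rank first.

Two-stage screening (stage 1: all strategies at 5 repetitions; stage 2: top
100 at 20 repetitions) is encoded in `screen_strategies`; the 100-finalist
cut is configurable. Per-strategy seeds are derived from (base seed,
SHA-1 strategy hash), so results are independent of evaluation order,
parallelizable in principle, and resumable from the JSON-lines cache.

## 4. PCA-LDA and nested cross-validation

**NIPALS PCA** extracts components by power-type iteration with rank-1
deflation; data are centered with the training means. Convergence is
declared when the relative change of the score vector drops below 1e-10,
with a 500-iteration cap per component; capped components are accepted and
flagged in `converged_` (at the cap the loading direction of a
near-degenerate eigenpair may still be off by ~1e-6–1e-5, which is
irrelevant for classification but visible against an SVD). For wide
matrices (p > n) the iteration runs on the Gram matrix `G = X Xᵀ`, which is
algebraically the same iterate sequence at much lower cost; loadings are
recovered as `Xᵀt/‖Xᵀt‖`. Exhausted residuals yield null components.

**LDA** uses the pooled within-class covariance with a diagonal ridge
`1e-8·trace(S)/k` for numerical safety (PCA reduction makes the problem
well-posed; the ridge only guards round-off), equal priors by default so
that a 63-sample class cannot dominate an 11-sample class (empirical priors
are available via `priors="empirical"`), and the largest-discriminant rule
with ties resolved to the lowest class index in sorted order. Classes with
fewer than two training members are a hard error.

**Stratified folds**: per class (sorted order), members are shuffled with
the seeded generator and dealt round-robin over the folds ordered by their
current total size (ties → lowest fold index). This keeps each fold's class
count within one of `n_k/k` *and* the fold totals within one of `n/k`
(e.g. class sizes 31/13/63/33/49/11/12 at k = 5 give folds of 42–43).

**Nested CV**: per repetition `rep`, the outer split uses seed
`base + rep`; per outer fold, an inner stratified CV (folds capped at the
smallest per-class training count, so every inner fold sees every class)
scores each candidate PC count and the count maximizing mean inner accuracy
wins (ties → fewest PCs). One PCA is fitted per inner fold at the largest
candidate and LDA is refitted per truncation of the score matrix — a pure
computational shortcut with identical results to refitting PCA per count,
since NIPALS components are nested by construction. The chosen count is
refitted on the full outer-training set; outer-test predictions accumulate
into a confusion matrix indexed [predicted, true]. The PC search upper
bound is truncated per fold to `min(p, n_train − c − 1)` and — by default
(`cap_pcs_by_class`) — to the smallest per-class training count, with a log
entry; see the chance-floor discussion below for why.
Accuracy is aggregated per repetition (correct/total over all outer folds),
then mean ± std (ddof = 1) over repetitions, never pooled over runs. Conservation laws: each true-class
column of the confusion matrix sums to `n_k × repetitions`, and
`trace/total` equals the mean accuracy to 1e-10.

**Accuracy-to-random**: `r = 100/c` percent and `a/r = a·c/100`; e.g.
`a = 77.00`, `c = 7` gives `r = 14.29` and `a/r = 5.39`; `a = 90`, `c = 2`
gives 1.8. Reported rounded to 2 decimals, computed in full precision.

### Chance floor under class imbalance

With class-uninformative features the expected accuracy of this design is
*not exactly* `100/c` when classes are imbalanced: estimated class means of
small classes are noisier and therefore farther from the origin, the
equal-prior discriminant penalizes them, and predictions skew toward large
classes. Accuracy at chance is `Σ_k p_k q_k` over true frequencies `p` and
prediction frequencies `q`, which exceeds `1/c` when `q` correlates with
`p`. The effect grows with the number of PCs retained, and the inner-CV
selection drifts toward high PC counts at chance because the inner estimate
carries the same bias. Empirically, with the 31/13/63/33/49/11/12 design
and an unconstrained PC search up to 40, the chance floor sits around
16–19% rather than 14.29%. This motivates the default `cap_pcs_by_class`
guard: the PC candidate list is truncated at the smallest per-class
training count, so every class mean is estimated from at least as many
samples as retained dimensions — the same samples-per-split rationale
behind the inner-fold shrinkage. With the guard the measured chance floor
returns to ~13–15%, and on the informative synthetic data the guard costs
no accuracy (the class signal concentrates in the leading components).
Users wanting the unconstrained search can set `cap_pcs_by_class=False`,
but should then interpret small accuracy-over-chance margins on imbalanced
data with care.

## 5. Synthetic spectra generator

The generator produces what the classification engine needs — controllable
class structure under realistic nuisance effects — not radiative-transfer
physics. Defaults emulate a seven-origin study of a ground, freeze-dried
nut matrix: classes of 31/13/63/33/49/11/12 samples (212 total), 3
replicates × 5 scans = 15 scans per sample, axis 11,550 → 3950 cm⁻¹ at
2 cm⁻¹ (3801 points).

Each class template is a smooth scattering baseline plus Gaussian bands:
water bands at 6900 and 5155 cm⁻¹ and chemical (lipid C–H / protein N–H)
bands near 5800, 4750, 4700, 4330 and 4200 cm⁻¹ with widths 70–150 cm⁻¹ and
amplitudes 0.08–0.45 AU. Classes differ by sparse amplitude-offset patterns
on the chemical bands (scale `class_amplitude_offset`, default 0.03 AU), so
the class signal is chemical and survives scatter correction — scatter
alone never separates classes. A scan is

```
b·(template + band jitter) + a + slope·(w − w̄) + water jitter + noise
```

with per-sample draws `a ~ N(0, 0.05)` (additive scatter, AU),
`b ~ U(0.7, 1.3)` (multiplicative scatter), `slope ~ N(0, 4e-6)` (AU/cm⁻¹
baseline drift), band jitter `~ N(0, 0.012)` per chemical band (within-class
chemical variability — without it, within-class variation would be pure
scatter + noise and any nonzero separation would be trivially separable
after MSC and averaging), water jitter `~ N(0, 0.01)` per water band
(residual moisture), and per-scan white noise `N(0, 0.003)`. These scales
were chosen once to place the default-separation classification accuracy in
the realistic mid-80s% regime for a seven-class problem while keeping all
nuisance effects visibly larger than instrument noise.

All randomness is drawn in a fixed order independent of the separation
scale, so `make_separation_ladder` produces specs sharing every random
effect and differing only in class separation; factor 0 makes labels
exactly uninformative.

What the generator does **not** emulate: instrument line shape and detector
noise spectra, wavelength-dependent scatter (its `a`, `b` are constant
across the axis, which is exactly MSC's model — real scatter is only
approximately affine), replicate-level repacking effects (scatter is drawn
per sample, not per replicate), correlated chemical composition across
bands, and class overlap structure beyond sparse band offsets. Passing
tests on synthetic data therefore demonstrate correctness and sane behavior
of the machinery, not field performance on real spectra.

## 6. Problem sizes in the test suite and acceptance script

The test suite favors configurations that exercise the full code path at
the smallest size that makes the property sharp: conservation and
chance-level tests run the full 212-sample design with binning 20 and PC
search 1..10 (the chance value is insensitive to the search cap at this
scale, the runtime very much is); the separable-limit test uses separation
factor 8, where every nuisance scale is dominated; the screening test uses
a 64-strategy grid on a 70-sample block with strong injected scatter, where
the top decile of the ranking must consist of MSC-on strategies; operator
tests run against closed-form or loop-based oracles at vector lengths
40–120. `scripts/acceptance.py` runs the full-size chance-floor experiment
(212 samples, PC search 1..40, binning 20 on the 8000–3950 cm⁻¹ range) as a
20-repetition label-permutation experiment: the labels are re-permuted
every repetition, which makes the repetitions nearly independent draws of
the permutation distribution and the 20-repetition mean a stable chance-
level estimate (holding one label assignment fixed across repetitions
leaves the repetition accuracies strongly correlated, so the mean then
inherits the full single-experiment binomial spread of ±2–3 points). It
completes in a few minutes on one CPU.

## 7. Known limitations

- The MSC default leaks the test set into the reference spectrum (see §2);
  use `fold_safe_msc` for leakage-free estimates (slower: the pipeline is
  re-run per outer fold).
- LDA assumes a shared within-class covariance; no quadratic or regularized
  discriminant variants are provided.
- The chance floor on imbalanced designs is above `100/c` (see §4);
  accuracy-to-random ratios near 1 should be interpreted accordingly.
- Screening is exhaustive by design; no greedy or Bayesian search over the
  grid is provided, and grids beyond ~10⁴ strategies are expensive on one
  core.
- No support for instrument-native binary formats or interpolation onto new
  axes; spectra must arrive as delimited text on a common axis.
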