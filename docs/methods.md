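# Methods

This note documents the generative model, the measurement conventions and
the statistical procedures implemented in `libs_tissue`, together with the
design choices that were genuinely open and the limits of what the
synthetic study conditions can show.

## The measurement model

One laser shot yields one spectrum on a uniform wavelength grid (default
500–850 nm at 0.1 nm; the grid is a config field because instrument grids
vary).  Processing is deliberately minimal and mirrors single-shot LIBS
practice:

1. **Baseline subtraction.**  A constant per-spectrum baseline is
   estimated as the 5th percentile of the intensities at samples outside
   every catalog window and outside the reference-peak region, then
   subtracted (negatives clipped to zero).  A low percentile rather than
   the mean keeps the estimate robust to unmodelled emission in the
   "empty" regions; the estimator is swappable behind
   `preprocess.subtract_baseline`.
2. **Base-peak normalization.**  Intensities are divided by their maximum,
   so the tallest feature equals 1 and any shot-to-shot gain cancels
   exactly (`preprocess` is provably gain-invariant when noise is off).
3. **Peak areas.**  The area of a bin is the *discrete sample sum* of the
   normalized intensity over the closed window — no Δλ factor.  With a
   unit base peak and ~2 nm windows this is the only convention under
   which double-digit AU medians (e.g. nerve Ca ≈ 64) are reachable; AU
   are dimensionless either way.

The bin catalog holds 15 labelled windows (11 Ca-associated CaO/CaOH band
heads, the K doublet at 765.86/770.76 nm, Na at 589.14/819.42 nm), each
`center ± 1 nm`.  The closest centers are 4.90 nm apart, so the default
windows are pairwise disjoint.  Element tags live on the catalog only;
`ca_sum`/`k_sum`/`na_sum` are sums over the tagged bins.  Na is simulated
for completeness but is not a discrimination target (its in-study signal
was compromised by saline cleaning of the specimens).

## The synthetic class model

For each tissue class and element, the *summed* peak area follows a
log-normal — positive support and right skew, consistent with published
IQRs that exceed their medians.  The calibration is closed-form: a
log-normal with parameters (μ, σ) has median `exp(μ)` and
`IQR = 2·exp(μ)·sinh(z₇₅·σ)` with `z₇₅ = Φ⁻¹(0.75) ≈ 0.6745`, so

    μ = ln(median),   σ = asinh(IQR / (2·median)) / z₇₅.

The four study classes use the published (median, IQR) pairs for Ca and K.
Values that are *not* published and are therefore package choices, encoded
once in `data/default_config.yaml`:

| class | Na median (IQR) | rationale |
|---|---|---|
| fibrosis, cell-rich tumor | 6.0 (1.8) AU | qualitatively "high Na" |
| nerve | 1.5 (0.45) AU | low Na |
| tumor stroma | 2.0 (0.6) AU | low-moderate Na |
| healthy-bone reference | Ca 80 (24), K 1.0 (0.3) | high-Ca / low-K anchor |
| tumor reference | Ca 2.0 (0.6), K 7.0 (2.1) | low-Ca / high-K anchor |

The two reference classes are qualitative stand-ins for previously
characterised healthy-bone and bone-infiltrating-tumor spectra; they are
used only to anchor the PCA and never enter the group statistics, the ROC
rows or the metric scales.

**Truncation by winsorization.**  Each draw is clipped at its class
quantile `q = 0.975`.  This serves one purpose: bounding the tallest
emission line below the reference peak so that base-peak normalization
always restores the calibrated scale.  Winsorizing (rather than rejection
truncation) is essential — clipping an upper tail at q > 0.5 leaves the
median *exactly* unchanged, whereas conditional truncation would shift the
median of the most skewed class (tumor-stroma Ca, σ ≈ 0.94) by several
tenths of a percent.  The bound matters because the stroma Ca
0.975-quantile already implies per-bin areas of ~17 AU against a
per-window capacity of ~18 AU at unit amplitude.

**Rendering.**  Each element sum is split across its bins by a weight
vector (uniform by default; configurable), and each bin receives a
Gaussian line at its center with FWHM 3.0 nm — the Ca features are broad
molecular bands, and the width simultaneously keeps peak amplitudes below
the reference peak at the calibrated areas.  Line amplitudes are obtained
by solving the 15×15 *window-response system* `R·a = targets`, where
`R[i,j]` is the discrete sum of a unit line at center j over window i;
this compensates cross-bin tail leakage exactly, so with noise off the
full pipeline recovers the drawn sums to machine precision (tested at
1e−6 relative; K–K leakage alone would otherwise bias `k_sum` by ~0.2%).
On top of the lines: a unit-height reference peak at 800 nm (outside all
windows — the synthetic "base peak"), a constant baseline of 0.02, additive
Gaussian noise with sd 5·10⁻⁵, and a log-normal shot-to-shot gain
(log-sd 0.3) that the normalization removes.  The noise level encodes the
high single-shot signal-to-noise of the instrument class relative to the
base peak; it is also what keeps the 5th-percentile baseline estimator's
small-sample bias (≈1.645·sd per sample, accumulated over the ~220 Ca
window samples) below 0.1% of even the smallest class median — a louder
detector would need a different baseline estimator, not a different
pipeline.

**Randomness.**  A dataset seed is fanned out to one child stream per
tissue class (fixed enum order), so changing one class count never
perturbs another class's spectra.  Within a spectrum the draw order is
fixed: Ca, K, Na sums; noise; gain.  Drawn targets are stored in
`Spectrum.meta` for ground-truth tests.  `sample_features` draws the sums
directly (identical distribution, no rendering) and is used where many
seeds must be swept cheaply.

## Statistical procedures

* **Summaries** use numpy's linear-interpolation quantiles; the rule is
  pinned because IQR values depend on it.
* **Kruskal–Wallis** (via `scipy.stats.kruskal`): mid-ranks, tie
  correction, chi-square reference with df = k−1.  The chi-square
  approximation is adequate at the study's group sizes (≥ 254); an
  all-identical pooled sample returns H = 0, p = 1 rather than an error.
* **Dunn's post hoc** is hand-implemented (no established Python package
  provides it): z from mean-rank differences on the pooled mid-ranks with
  the `Σ(t³−t)` tie correction, two-sided normal p, Bonferroni ×6.
  Bonferroni was chosen as the conventional, conservative companion of
  Dunn's test; the adjustment is isolated in one function.  For k = 2 the
  implementation satisfies z² = H, which the tests exploit as an
  independent cross-check.
* **AUC** uses the rank-sum identity and is always oriented so AUC ≥ 0.5,
  with the orientation reported (`higher-is-positive` /
  `lower-is-positive`).  CIs use DeLong's structural components
  (hand-implemented, validated by a simulation coverage oracle at
  n = 100+100: empirical 95%-CI coverage within [0.92, 0.98]); p-values
  use the tie-corrected normal approximation to the Mann–Whitney null.
* **Youden cutoffs** scan midpoints between adjacent distinct pooled
  values — reproducible and symmetric under direction flips, unlike
  scanning observed values.  Ties in J break toward higher sensitivity,
  then the lower cutoff on the oriented axis.  Positive calls are
  `value ≥ cutoff` (or ≤ under the lower orientation); a constant pooled
  sample has no informative threshold and errors.
* **Metric scales** order the four classes by element median and place
  one Youden cutoff between each *adjacent* pair (upper class forced
  positive) — the only construction under which three cutoffs partition
  the axis.  Boundaries belong to the upper class, mirroring the
  "≥ lo to < hi" reading of the published intervals.  Non-ascending
  cutoffs are an error naming the violating pair; Ca and K scales are
  reported separately, and the package deliberately defines no fusion
  rule for discordant Ca/K calls.
* **PCA** is covariance-based (mean-centred, unscaled) on the 13 Ca/K
  bins: unit-scaling would preclude any element from dominating the
  loadings, which is exactly the effect of interest (on study-condition
  data the top PC2 loading is a K bin while PC1 tracks the Ca spread).
  A standardized mode exists behind a flag.  "Fixation" is implemented as
  inclusion of the reference-class vectors in the fitting set.  Components
  follow a deterministic sign convention (largest-|loading| positive) and
  are validated against a raw SVD oracle.  Rank-1 data is allowed (its
  first variance share is 1); only zero-variance data errors.

## Problem sizes and determinism in the tests

The acceptance-grade checks run the full pipeline once at the study sizes
(3049 spectra, seed 42; a few seconds) and sweep 10–20 seeds at the
feature level for the omnibus-significance and scale-structure claims.
Distributional unit tests use 500–20 000 feature-level draws chosen so
that the sampling error of a median is a small fraction of the 5%
tolerance being asserted.  Hypothesis-based property tests run
derandomized.  Medians of size-n samples of the most skewed classes
(stroma Ca σ ≈ 0.94 at n = 821) carry an inherent ~4% relative sampling
sd — single-seed agreement with the calibrated medians to much better
than that is not statistically meaningful and is not asserted.

## What the generator does and does not emulate

It emulates: the per-class distributions of the element sums (the only
quantities the downstream statistics consume), right-skewed heterogeneity
between shots, shot-to-shot gain, a constant instrument baseline, detector
noise, and cross-bin spectral leakage.

It does not emulate: plasma physics (no Saha/Boltzmann temperatures, no
self-absorption), true per-bin intensity ratios within an element
(uniform split by default — per-bin statistics other than PCA structure
should not be over-interpreted), any correlation between Ca, K and Na
within a shot (no joint information is published; sums are drawn
independently and flagged as such), matrix and water-quenching effects,
or the real instrument's bin grid (only the 15 published wavelengths are
known; the catalog is configurable so further bins can be added).
Passing tests therefore demonstrate that the *procedures* reproduce the
published statistical structure under a faithful marginal calibration —
not that real tissue spectra look like the synthetic ones.

## Known limitations

* Cutoffs and sensitivity/specificity values are tail-shape-sensitive;
  the log-normal tails are an assumption, so the synthetic Youden cutoffs
  match the published ones only in order of magnitude and ordering, and
  are not treated as reproduction targets.
* The Dunn adjustment in the original software is unstated; a step-down
  family would give smaller adjusted p-values than Bonferroni.
* Whether the original base peak was an analyte or reference feature is
  unknowable; the fixed 800 nm reference peak is a synthetic-world
  contract, documented as such.
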