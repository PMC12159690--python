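# Methods

## The normative perturbation model

The package treats a healthy-control cohort as defining a normative
molecular-connectivity model.  Regional SUVr values for control subject
*s* and regions *i, j* are residualized on an intercept plus nuisance
covariates (age in years, sex coded 0/1) by ordinary least squares, and
the reference network is the Pearson correlation matrix of the residual
columns — equivalent, for this design, to the partial correlation given
the covariates.  A single test subject is scored by appending their row
to the control table, refitting the covariate regression on all *n*+1
rows, rebuilding the network, and standardizing the edge-wise change:

    z(i,j) = [PCC_{n+1}(i,j) − PCC_n(i,j)] · (n − 1) / (1 − PCC_n(i,j)²)

with *n* the reference size.  The denominator is the large-*n* standard
deviation of the edge change under the null hypothesis that the subject
is drawn from the control distribution.  Two-tailed standard-normal
p-values follow directly from z.

Assumptions worth stating explicitly:

* The covariate model is linear and global (one slope per region); the
  perturbed network refits it on the *n*+1 sample rather than reusing
  the control coefficients.  Refitting treats the perturbed network as a
  genuine network estimate on the augmented sample, which matches the
  definition of the perturbation; the alternative (frozen reference
  coefficients) changes z by O(1/n) and is not exposed.
* The z denominator uses *n* − 1 regardless of how many covariates were
  regressed out.  A degrees-of-freedom variant (*n* − 1 − *k*) is
  available via `dof_adjust` but off by default, keeping the standard
  formula.
* Edges with |PCC_n| numerically at 1 (within 1e−12) are build-time
  errors, not clamped values: the null standard deviation vanishes there
  and z is unbounded.  Such edges only arise from duplicated or affinely
  dependent region columns.

### Calibration of the z-scores

The z formula standardizes to unit variance, but the null *shape* is not
Gaussian: the change in a sample correlation caused by one added point
is a quadratic form in that point's residuals (the influence function of
the correlation coefficient), giving the symmetric, heavy-tailed
"volcano" distribution with excess kurtosis around 6.  The practical
consequence, which `scripts/acceptance.py` measures directly
(`null_edge_exceedance_*`), is that two-tailed exceedance of held-out
control subjects is close to nominal at α = 0.05 (≈ 0.06–0.07) but about
three times nominal at α = 0.01 (≈ 0.03), and this does not shrink with
the reference size — the heavy tail is contributed by the single added
subject, not by estimation noise.  Edge-level p-values near the extreme
tail should therefore be read as scores rather than calibrated
probabilities.  The extreme-deviation metrics are robust to this choice:
they compare subjects against each other under the same statistic, and
the high threshold τ is far beyond either null.

## Extreme-deviation metrics

Deviation matrices are thresholded strictly: entries with |z| ≤ τ are
zeroed, survivors keep their signed value.  The default τ = 4.13 is kept
as an opaque constant of the analysis convention (a Bonferroni-style
two-tailed cut for thousands of edges lands between 4.1 and 4.4
depending on the exact sidedness and edge count; the package does not
recompute it from *m*).  SED sums |z| over the strict lower triangle and
divides by C = m(m−1)/2; because magnitudes are summed, SED can exceed 1
and is better read as a deviation burden than a proportion.  A
count-based variant (`extreme_edge_fraction`, the fraction of
supra-threshold edges) is provided for the proportion reading.  RED is
the per-subject row mean of the absolute thresholded matrix with divisor
*m* (the zero diagonal included in the divisor, per the metric's printed
definition).  A signed-RED variant exists behind a flag but defaults
off: mixed-sign rows cancel and lose the "burden" interpretation.

## Statistics

Two-group comparisons use the Wilcoxon rank-sum test (exact p when both
groups have ≤ 25 tie-free observations, normal approximation with tie
correction otherwise) with Cohen's d on the plain pooled SD.  Paired
baseline/follow-up comparisons use the one-tailed Wilcoxon signed-rank
test of "follow-up < baseline", dropping zero differences and requiring
at least five informative pairs.  Three-group comparisons use
Kruskal–Wallis with tie correction followed by Dunn's z-tests on pooled
ranks, FDR-adjusted across the three pairs.  All multiplicity correction
is Benjamini–Hochberg.  Region-wise scans run one two-sided rank-sum
test per region and adjust across regions; a region constant across both
groups carries no rank information and is reported at p = 1 rather than
aborting an 83-region scan.  Top-decile selection ranks regions by mean
RED and returns floor(0.10·m) labels, ties broken toward the lower
region index.  For longitudinal designs the intended usage is to fix the
top-decile set on the baseline condition and evaluate those same regions
in the other conditions; re-selection per condition is possible but
conflates region identity with region ranking.

## Classification

Features are either the vectorized strict lower triangle of the raw
(unthresholded) z-matrix — thresholded features are available behind a
flag — or the RED vector.  Evaluation is stratified 5-fold
cross-validation, so each fold trains on 80% and tests on the held-out
20%, with a linear SVM at C = 1.  Feature standardization is available
but **off by default**: deviation z-scores share a calibrated scale by
construction, and estimating thousands of per-edge scale factors from a
few dozen training subjects measurably degrades recovery (in the
package's own synthetic benchmark, balanced accuracy drops from ≈ 0.99
to ≈ 0.82 when per-fold standardization is switched on).  SMOTE (k = 5,
interpolation between minority points and their minority-class
neighbors) is applied inside training folds only; applying it before
splitting would leak synthetic copies of test subjects into training.
Three-class problems use a one-vs-one strategy; the reported AUC is the
macro average over the three pairwise AUCs, each computed from a
pairwise SVM fitted on the fold's training subjects of those two
classes.  The permutation test re-runs the full pipeline on shuffled
labels and reports the add-one p-value
(1 + #{null ≥ observed}) / (1 + n_perm), which is never exactly zero.

## Fingerprinting and stability

Fingerprinting correlates strict-lower-triangle vectors of baseline and
follow-up deviation matrices (Pearson) and matches each baseline subject
to the argmax follow-up; ties break toward the lower index (a
measure-zero event for continuous data).  Stability resampling draws,
for each size in 8, 12, …, 64, twenty control subsets without
replacement, rebuilds the network (same covariate model) and correlates
its strict lower triangle with the full-cohort network's.  The diagonal
is excluded everywhere because it is constant 1 and would inflate the
correlation.  Each (size, repetition) cell uses an independent substream
spawned from the master seed.  Subsets whose covariate design is
degenerate (e.g. a single-sex draw at size 8) are redrawn, as any
covariate-adjusted resampling must.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis consumes,
not the imaging chain that produces it.  Control cohorts are drawn from
a multivariate normal over 83 regions with a heterogeneous three-tier
correlation structure — a tightly coupled 8-region basal-ganglia block
(ρ = 0.85), a 40-region association block (ρ = 0.7), a loosely coupled
remainder (ρ = 0.2), background 0.05 — chosen so the spread of true edge
strengths resembles real molecular covariance matrices; with uniform
low-spread blocks, subsample-vs-full network correlations plateau well
below what real cohorts show, because that correlation is driven by
between-edge variance of the true network.  Region means default to
2.5 (basal-ganglia block) and 1.2 (elsewhere) with SDs at 10% of the
mean, a small age decline (−0.003 SUVr/year around the mid-range age)
and a +0.05 male offset; ages are uniform on 20–65 and sex is a fair
coin.  Non-PSD correlation targets are repaired by eigenvalue clipping
with renormalization and a warning.

Patient groups add a directional perturbation to the control
distribution.  The default mechanism is a mean shift of the affected
block along an eigen-axis of that block's covariance: along the leading
axis to *strengthen* apparent coupling when the subject is appended, or
along the minor axis — the direction most at odds with the dominant
covariance pattern — to *weaken* it.  A shift along the negative leading
axis would not weaken anything: any displacement on the principal axis
reinforces the existing correlations, which is why the weakening
direction is the minor axis.  Both directions scale by the leading-axis
SD so that `magnitude` means the same displacement in either case.  The
default magnitude is 3.25 (≈ 3 SD along the block's main axis, a severe
but clinically plausible molecular lesion) with a per-patient severity
multiplier max(0, N(1, 0.4)) — real cohorts are heterogeneous in
severity, and that heterogeneity is what gives between-subject deviation
metrics their variance.  A correlation-rescaling mode (drawing patients
from a modified covariance) is available as an alternative mechanism.
Longitudinal pairs keep a fraction `stability_rho` of the subject's
noise component, shrink the group-mean disease shift by
`treatment_shrink`, and add fresh noise; individual severity residuals
persist with the stable component, as residual individual pathology
would under treatment.

What the generator does **not** emulate: PET acquisition and
reconstruction noise, spatial autocorrelation between neighboring
regions, non-Gaussian uptake distributions, site or scanner effects,
realistic (non-uniform) age structures, and any specific disease
topography.  Passing tests therefore demonstrate that the pipeline
recovers the structures it is designed to detect under its own
distributional assumptions — they are statements about internal
consistency and statistical calibration, not about sensitivity or
specificity in real cohorts.

## Problem sizes and numerical choices

The validation battery uses 71-control references over 83 regions with
30-patient groups (18 for longitudinal fingerprinting), a 200-control
reference with 500 held-out subjects for null calibration, 500
replicates for the region-wise family-wise error measurement, 1000 label
permutations for the recovery benchmark, and 50 random instances for the
brute-force oracle comparison — sizes at which every quantity is stable
across seeds while the whole suite runs in minutes.  Floats are
serialized with 17 significant digits and parsed with round-trip
precision, so CSV write/read is bit-exact.  Degenerate-edge tolerance is
1e−12 on |PCC|; PSD repair clips eigenvalues at 1e−8.  All stochastic
components accept explicit seeds; library-level randomness (fold
assignment, SMOTE draws, permutations, subsampling) is derived from them
deterministically.

## Known limitations

* Edge p-values are anti-conservative in the far tail (see calibration
  above); inference should rest on the comparative metrics, not on
  individual edge significance.
* The SMOTE placement (inside folds) is the leakage-safe reading; if an
  external analysis applied balancing before cross-validation, its
  printed accuracies would not be comparable.
* τ = 4.13 is a convention, not a function of the atlas; users with very
  different region counts should consider whether the implied edge-wise
  significance level still suits their design.
* The NIfTI extractor assumes a precomputed parametric/summed activity
  image on the same grid as the label image; dynamic-frame handling,
  motion correction and spatial normalization are out of scope.
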