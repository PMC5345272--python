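# Methods

`airwayprot` re-implements, as a tested pipeline, the quantitative analysis
used to separate omalizumab-responder (OR) from non-responder (NOR)
severe-asthma phenotypes from bronchial biopsy data: label-free
spectral-count protein quantitation with the DAVE/DCI indices and log fold
change, post-search PSM filtering with reverse-database FDR, orthogonal-
intercept basement-membrane morphometry, cell-infiltrate densitometry, and
hierarchical clustering gated by the agglomerative coefficient.  This note
records the models, the defaults that matter, and the choices made where
the design was genuinely open.

## Differential quantitation

Scores are label-free consensus scores (summed peptide cross-correlation
evidence per protein).  For a class or protein with condition-average
scores A (baseline, T0) and B (after treatment, T36):

* **DAVE** = 2(B − A)/(A + B), bounded in [−2, +2].  Absence in the sample
  gives −2.0, absence in the baseline +2.0, so the bounds are attained
  exactly and only at absence.  DAVE(0, 0) is defined as 0 (no evidence of
  change) rather than left undefined.  |DAVE| > 0.4 (strict) is the
  conventional significance call.  DAVE is antisymmetric and scale-
  invariant.
* **DCI** = (A + B)(B − A)/2, a magnitude-weighted companion that always
  shares DAVE's sign; it is reported but drives no decision.
* **ln fold change** = ln(T36/T0) per patient on class-summed scores, then
  averaged over the group's patients.  Exact zeros (absent proteins) are
  replaced by a pseudo-score of 1 before the ratio; (0, 0) maps to 0.  The
  replacement value is exposed as `zero_replacement`.  This convention is
  the one that reproduces the bundled panel's published group averages
  (−4.6 for responder periostin, −2.0 for responder keratins, +2.5 for
  non-responder smooth muscle); score units make 1 a natural detection
  floor.

Per-patient class scores are sums over member proteins before group
averaging (a per-protein mean is selectable).  For comparison against
conventionally printed values, DAVE is rounded half-up to 2 decimals and
fold changes to 1 decimal.

A caveat worth stating: the sign of DAVE (computed on group means) and the
sign of the group-mean per-patient fold change can disagree when the true
shift is negligible, because zero replacement lets individual ±ln(x/1)
terms dominate a near-zero mean ratio.  The bundled panel's non-responder
periostin row (37.5 → 36.5; DAVE −0.03, mean ln FC +0.62) is exactly such
a case.  Concordance holds at every significant shift (|DAVE| > 0.4), and
the test suite asserts it in that form.

### Group tests

`compare_groups` applies a normality gate: Shapiro–Wilk on each sample at
α = 0.05; if both pass, a t-test (Welch for unpaired comparisons — robust
to the unequal group variances typical here — paired t otherwise); if
either fails, the Wilcoxon test with exact small-sample p-values (rank-sum
unpaired, signed-rank paired; the exact null is used whenever there are no
ties).  Zero-variance samples cannot be gated and fall to the Wilcoxon
branch with a warning; elementwise-identical samples are degenerate and
return p = 1.  No multiple-testing correction is applied — the analysis
reports a handful of pre-specified class-level comparisons.

## PSM filtering and protein assembly

Search-engine output is filtered with charge-dependent Xcorr thresholds —
strictly greater than 1.5, 2.0, 2.5 for 1+, 2+, 3+ precursors (charges
above 3 use the 3+ threshold) — and peptide probability ≤ 0.001 (lower is
better).  The strict/non-strict reading follows the conventional wording
of these filters.  Filtering is idempotent and order-stable, and raising
any threshold can only shrink the kept set.

The protein **consensus score** is the sum of member-PSM Xcorr values over
unique filtered PSMs; there is no universal roll-up rule for this
quantity, and only the ≥ 10 acceptance cutoff and relative magnitudes
matter downstream, so the rule is configurable.  Decoy (reverse-database)
accessions, identified by a configurable prefix, never contribute to
target consensus scores; the FDR estimate is decoys/targets among kept
PSMs, reported as a percentage and flagged at ≥ 3%.  Zero kept targets
yields 0% with a warning.

Theoretical MW is the sum of average residue masses plus one water
(computed with pyteomics).  The isoelectric point is the root of the
Henderson–Hasselbalch net-charge function under a single declared pKa set
(Lehninger: side chains D 3.65, E 4.25, C 8.18, Y 10.07, H 6.00, K 10.53,
R 12.48; N-terminus 9.69, C-terminus 2.34), found by bisection on [0, 14]
to 1e-4 pH.  The 2D MW/pI map export never clips extreme entries
(< 10 kDa, pI < 4 or > 10).

## Morphometry

RBM thickness uses the orthogonal-intercept method:
τ = (π/4) × arithmetic mean of the intercept lengths.  The π/4 factor
corrects the overestimation caused by sections not cutting the membrane
perpendicularly.  At least 40 intercepts per measurement is the accepted
validity convention; the implementation warns rather than fails below it
so small synthetic cases stay measurable.

`measure_orthogonal_intercepts` works on digitized boundary polylines (µm
coordinates): a square grid (default 100 µm, seeded random origin offset
if desired) is intersected with the epithelium–RBM junction, intersection
points are thinned to a minimum spacing along the membrane (default
20 µm), and at each kept point the segment length to the RBM–subepithelial
junction is measured along the local boundary normal (default) or along
the generating grid line (`direction="grid"`).  On parallel-plate
geometry the normal mode returns the perpendicular separation to 1e-9 µm
regardless of in-plane tilt; the grid mode returns t/cos θ for plates
tilted by θ against a vertical ray.

Biopsy suitability requires ≥ 1.0 mm preserved RBM length **and**
≥ 0.1 mm² subepithelial area (both inclusive); unsuitable specimens are
excluded from patient-level summaries.  Cell densities average the two
blinded operators' counts per sample (arithmetic mean — no reconciliation
rule beyond blinding is part of the protocol), divide by the band area
(the band extends 50 µm under the RBM), and average a patient's samples.

### Synthetic membrane model

The section generator draws intercepts as
t·(4/π)·sec(θ)/E[sec θ], with θ a half-normal obliquity angle of scale
`obliquity_sd` truncated at 1.4 rad.  By construction E[intercept] =
(4/π)·t for every scale, so the π/4-corrected estimator is exactly
unbiased under the model, and the zero-noise limit gives the constant
t·4/π.  `obliquity_sd` is capped at 0.6 rad: beyond that the normalization
could produce intercepts shorter than the true thickness, which is
physically impossible.  Default scale 0.35 rad gives a realistic ~15%
coefficient of variation in intercept lengths.

## Phenotyping and clustering

* **Responder rule**: OR iff RBM thickness strictly decreased between
  baseline and 12 months; "no reduction" (including ties) is NOR.
* **Gal-3 rule**: galectin-3-positive iff the baseline score is nonzero —
  any protein surviving the consensus filter is "present", so
  presence/absence is binary.

Profiles are clustered agglomeratively on Euclidean distances over raw
scores (standardization is available but off by default, since the
published dendrograms are built on raw score values).  Average linkage is
the default — it is the linkage the agglomerative-coefficient methodology
(AGNES) defaults to — with single/complete/Ward selectable.  Patients are
sorted lexicographically before clustering, making results input-order
invariant; remaining ties are resolved by the linkage implementation's
smallest-index convention.

The **agglomerative coefficient** is AC = mean over observations of
1 − h_first/h_final, where h_first is the height at which the observation
first merges and h_final the final merge height.  AC ∈ [0, 1]; a flat
dendrogram (including the two-observation case) has AC = 0, and tight,
well-separated groups push it toward 1.  The implementation computes AC
from its own merge sequence and is cross-checked in the tests against a
direct recomputation from the linkage matrix and against the AGNES
reference implementation (R `cluster::agnes`) to 1e-6.

The 2-cluster cut is compared with phenotype labels; patients sitting in
the cluster dominated by the opposite phenotype are reported as
crossovers.

## Synthetic cohorts

`generate_cohort` emulates the statistical structure of the targeted
cohort: 4 + 4 patients (configurable), 546 distinct proteins across
classes (12 smooth-muscle, 10 keratin, 100 ECM/remodeling-program, 1
periostin, 1 galectin-3, the rest unclassified), responders carrying
positive galectin-3 and an elevated remodeling program at baseline,
non-responders galectin-3-negative.  Treatment dynamics are class-level
group phenomena: one fold factor per class and regime, drawn log-uniformly
from the configured ranges (responder decreases 5–50-fold, non-responder
increases 2–10-fold by default) and shared by the patients following that
regime; galectin-3 follows absence semantics instead (exact 0 at T36
everywhere) and unclassified proteins are stable.  Scores carry
multiplicative log-normal noise (CV 0.15 by default, within the 10–30%
range typical of spectral-count replicates); absent proteins are exact
zeros.  The optional crossover non-responder (the second, mirroring the
cohort's crossover patient) follows responder dynamics at T36 while
staying galectin-3-negative at baseline.

These choices make the generated cohorts behave like the real one: the
2-cut separates the groups at baseline, the crossover patient joins the
responder cluster at T36, dendrograms are well structured (AC > 0.7), and
baseline Gal-3 positivity coincides with cluster membership.  What passing
tests on such cohorts do **not** show: robustness to missing-at-random
protein dropout, batch effects, per-patient fold heterogeneity within a
class, or any raw-spectrum-level artifact — the generator works at the
score level and encodes class-coherent dynamics by construction.

## Problem sizes and numerics

The test suite and the acceptance computations run at desk scale by
design: the bundled-panel indices are closed-form arithmetic on 8
patients; clustering contracts use 8-patient, 546-protein cohorts over
tens of seeds; morphometry recovery uses 200 sections per thickness at
60 intercepts (4 000 for the single high-precision check); PSM properties
use ~1 000-row tables.  pI bisection tolerance is 1e-4 pH; geometric
assertions are at 1e-9 µm on exact configurations.  Rounding for
comparison against conventionally printed values is decimal half-up
(ties away from zero).
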