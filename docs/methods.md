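# Methods

## The instrument and its scoring model

The package analyses a 12-item self-administered screening questionnaire
that separates cluster headache (CH) from migraine, the most common CH
misdiagnosis. The items are: a choice among six images depicting pain
severity, a 0–10 visual-analogue pain scale, verbal pain intensity (mild …
excruciating), nature of pain (throbbing/other, pressure,
stabbing/burning), a pain description ("red hot poker in the eye" vs
"pounding heart in the head/other"), five yes/no questions (restlessness,
excruciating agony, attacks at specific times, strictly unilateral pain,
ipsilateral cranial autonomic symptoms), and treated and untreated attack
duration (≤ 3 h vs > 3 h). Each raw answer maps to an integer code, with
higher codes marking CH-typical features (image f=1, a=2, c=3, b=4, e=5,
d=6; pain scale identity 0–10; intensity 1–5; nature 1–3; description 0/1;
binaries 0/1; durations ≤ 3 h = 1). The total score is the sum of the 12
codes and ranges 3–32; the "no-images" total omits the image item and
ranges 2–26.

Missing data: item-level statistics use pairwise deletion (a record
contributes to an item iff that answer is present); totals require complete
cases (all 12 answers, or all 11 non-image answers for the no-images
total). Raw categories use a strict lowercase vocabulary; anything else is
rejected with the offending item and value named, never silently coded.

## Diagnostic accuracy (2×2 items)

CH is the disease-positive class. For each dichotomous item (the five
binaries plus description and the two durations, positive = the CH-typical
category), the package computes sensitivity, specificity, PPV, NPV, FPR,
FNR (percent scale) and both likelihood ratios. Confidence intervals are
95% Wald normal-approximation intervals p ± z·√(p(1−p)/n) on the relevant
denominator, clipped to [0, 100]; Wald was chosen because it is the
simplest interval consistent with the published tables, and exact agreement
with those intervals is not asserted (their per-item denominators under
missing data are unpublished). FPR/FNR intervals are mirrored Se/Sp
intervals, so the complement identities Se+FNR = Sp+FPR = 100 hold exactly
for points and bounds alike. Counts may be fractional: a published
within-group percentage p with group size n converts to expected counts
p·n, which lets the accuracy table be reconstructed from published
frequency tables without inventing an integer rounding. Zero denominators
(PPV/NPV) are reported as undefined with an explicit flag; tables render
"undefined", never 0.

## ROC analysis

Positivity is strict (score > threshold), so a cut-off of 25 reads "above
25 screens positive". Thresholds are the distinct observed scores; virtual
endpoints (+∞ → (0,0), −∞ → (1,1)) close the curve. AUC is the trapezoid
area, identical to the tie-corrected rank statistic P(CH score > migraine
score) + ½P(equal); its SE uses the Hanley–McNeil formula and the p-value a
two-sided normal z-test against 0.5 (degenerate SE at perfect separation
yields the smallest representable positive p rather than 0). No smoothing
or binormal fit is applied. The operating cut-off minimises the Euclidean
distance to the top-left corner (FPR 0, TPR 1); ties break toward the lower
threshold, i.e. higher sensitivity, which is the right bias for a screening
instrument. Because half-integer cut-offs in the literature arise from
midpoints between adjacent observed scores, both the observed-score cut-off
and that midpoint are reported.

## Class balancing

The cohort is imbalanced (81 CH vs 215 migraine; within the female stratum
30 vs 180). `balanced_roc` draws, per replicate, a without-replacement
subset of the majority class equal to the minority size, keeps all minority
records, computes the replicate ROC, and vertically averages: TPR is
linearly interpolated at a fixed 101-point uniform FPR grid and the band is
mean ± 1.96·SD across replicates, clipped to [0,1] (the grid endpoints are
pinned to (0,0) and (1,1)). Ten replicates is the default; a normal band
rather than percentiles is used because percentile bands are meaningless at
10 replicates, and the residual sampling variability is reported by the
band, not suppressed. In the sex-stratified analysis the data are split by
sex first and balancing is applied within the female stratum only (the male
stratum is nearly balanced already).

## Synthetic cohorts

No patient-level data are distributable, so the generator turns the
published per-diagnosis categorical frequency table and cohort composition
into a generative model: exactly 81 CH (45 chronic / 36 episodic, 51 male /
30 female) and 215 migraine (123 chronic / 92 episodic, 35 male / 180
female); ages uniform on 18–79 (the published mean-age CIs are internally
inconsistent and are not targeted); each patient's 12 answers drawn
independently from their group's marginals. Published percentage rows that
sum to 99.9 or 100.1 are renormalised proportionally; the raw printed
values are retained in the shipped YAML spec for provenance. The pain scale
admits 0 (the instrument defines 0–10) with probability 0, since the
published frequencies tabulate 1–10 only.

**What the generator does and does not emulate.** Marginal quantities are
faithful: per-item frequencies, per-item accuracy statistics, and the
expected total score (by linearity of expectation ≈ 28.6 for CH and ≈ 19.2
for migraine, inside the published CIs around 28.4 and 19.5). Joint-score
quantities are not: real answers are positively correlated within patient,
which widens the overlap of the two total-score distributions, so under
independence the simulated total-score AUC (≈ 0.997) exceeds the published
0.955 and the published cut-off operating points (e.g. >25: 86.4% / 92.0%)
are not reproduced. Tests that pass on synthetic cohorts therefore validate
the machinery and the marginal structure, not joint-distribution claims
about real patients. A `joint_sampler` hook accepts a user-supplied
dependent sampler for sensitivity analyses.

Determinism: a fixed seed fixes the cohort bit-for-bit (CSV bytes
included); demographic labels are exact-count permutations, not draws.

## Problem sizes and numerical choices

The simulation-based checks use 200 cohorts at the study size (296
patients) for mean-score recovery, 100× scale for law-of-large-numbers
marginal checks, and 10 under-sampling replicates (200 in the Monte-Carlo
stability check); these sizes give sampling noise well inside the asserted
tolerances while keeping runs fast. Probability vectors are validated to
1e−9 after renormalisation. Report tables round to integer percent only at
render time; all stored values are full precision, and every reported
percentage is recomputable from counts stored in the report.

## Known limitations

- Item independence is the central simplification (above); no dependence
  structure is invented beyond the published marginals.
- The published frequency row for "excruciating agony" duplicates the
  restlessness row while the published accuracy row for that item differs;
  the package reconstructs what the frequency table implies and attempts no
  reconciliation.
- Wald intervals can differ by ±1 integer point from the published CIs,
  whose method and denominators are unstated.
- The no-images total is reported on its true 2–26 range.
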