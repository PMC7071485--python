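# chscreen

Diagnostic-accuracy analysis of a 12-item cluster-headache (CH) screening
questionnaire, for headache researchers and biostatisticians evaluating
screening instruments against a migraine control group.

Cluster headache is a severe primary headache whose most common
misdiagnosis is migraine. The questionnaire codes each of 12 items (pain
images, a 0–10 pain scale, verbal descriptors, key yes/no questions, attack
durations) as an integer score, higher for CH-typical answers, and sums
them to a total score ∈ [3, 32] (a "no-images" variant ∈ [2, 26]). The
package provides:

- **instrument** — strict raw-answer coding, totals, cohort CSV I/O;
- **diagnostics** — Se/Sp/PPV/NPV/FPR/FNR and likelihood ratios with 95%
  Wald CIs for dichotomous items (CH positive), fractional counts admitted
  so published frequency tables can be re-analysed directly;
- **roc** — empirical ROC curves (positive when score > threshold),
  trapezoid AUC ≡ tie-corrected rank statistic, Hanley–McNeil SE, z-test
  vs 0.5, and the cut-off closest to the top-left corner (ties favour
  sensitivity);
- **balancing** — repeated majority-class under-sampling with vertical
  curve averaging and a 95% band;
- **synth** — synthetic cohorts drawn from the published per-diagnosis
  categorical marginals and cohort composition (81 CH / 215 migraine),
  items independent within patient, bit-reproducible per seed;
- **pipeline / CLI** — simulate → score → evaluate → report, including
  sex-stratified and class-balanced analyses.

## Worked example

```sh
chscreen simulate --seed 0 --out cohort.csv
chscreen roc cohort.csv --item total_score --out roc.csv
```

prints

```
wrote 296 patients to cohort.csv
total_score: AUC=0.997 (SE 0.004, p=4.9e-324); cut-off >23 (midpoint 23.5): sensitivity 96.3%, specificity 98.1%
```

meaning: on this synthetic cohort the total score separates CH from
migraine almost perfectly (AUC near 1, significantly above the chance value
0.5), and screening positive above a total of 23 catches 96.3% of CH
patients while clearing 98.1% of migraine patients. The AUC exceeds the
value observed on real patients (0.955) because the generator draws items
independently within patient — see `docs/methods.md` for what the synthetic
cohorts do and do not emulate. `chscreen evaluate cohort.csv --seed 0 --out
report/` writes the full table bundle (frequency distributions, per-item
accuracy with CIs, ROC cut-off tables overall and by sex, balanced-ROC
curves, group mean scores); the same run on seed 0 reports mean total
scores of 28.65 (CH) and 18.56 (migraine).

The same analyses are available as a library:

```python
import chscreen as ch

cohort = ch.generate_frame(ch.default_spec(), seed=0)
report = ch.run_study(cohort, ch.StudyConfig(seed=0))
print(report.mean_scores)
print(report.roc_table[["test_item", "cutoff", "auc"]])
```

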