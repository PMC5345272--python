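# airwayprot

Label-free biopsy proteomics quantitation, airway morphometry, and
responder phenotyping for anti-IgE-treated severe asthma.

Severe allergic asthma patients treated with the anti-IgE antibody
omalizumab split into two phenotypes: **responders (OR)**, whose reticular
basement membrane (RBM) thins under treatment, and **non-responders
(NOR)**, whose RBM does not.  Responders are galectin-3 (Gal-3)-positive
in bronchial tissue at baseline, and their remodeling-related protein
classes — smooth-muscle proteins, ECM proteins including periostin,
keratins, Gal-3 itself — collapse after long-term treatment while the same
classes rise in non-responders.  `airwayprot` implements the quantitative
machinery needed to run and stress-test that analysis:

* **Differential spectral-count quantitation** — DAVE = 2(B−A)/(A+B) on
  condition-average consensus scores (bounded in [−2, 2], |DAVE| > 0.4
  significant), the magnitude-weighted DCI = (A+B)(B−A)/2, and per-patient
  ln(T36/T0) fold changes with a zero→1 absence convention, plus
  Shapiro–Wilk-gated t / exact-Wilcoxon group tests.
* **Post-search PSM filtering** — charge-dependent Xcorr cutoffs
  (>1.5 / >2.0 / >2.5 for 1+/2+/3+), peptide probability ≤ 0.001,
  consensus score ≥ 10, reverse-database FDR with a 3% flag, and a
  theoretical MW/pI 2D map (average masses; bisection pI on a Lehninger
  pKa set).
* **Morphometry** — orthogonal-intercept RBM thickness
  τ = (π/4) × mean intercept, grid-based intercept measurement on
  digitized boundaries, biopsy suitability gating (≥ 1.0 mm RBM,
  ≥ 0.1 mm²), and two-operator cell densitometry (cells/mm²).
* **Phenotyping** — OR/NOR from RBM reduction, Gal-3 positivity from
  baseline presence, Euclidean agglomerative clustering with the
  agglomerative coefficient AC = mean(1 − h_first/h_final) and 2-cut
  segregation reports.
* **Synthetic data** — seeded generators for cohorts (5–50-fold responder
  decreases, 2–10-fold non-responder increases, 546-protein profiles,
  optional crossover non-responder), PSM tables with controlled pass
  rates, membrane sections of known true thickness, and Poisson cell
  fields.

An eight-patient reference panel (per-patient scores for eosinophils,
smooth-muscle proteins, periostin, keratins and Gal-3 at baseline T0 and
36 months T36) ships as a typed fixture, so the whole pipeline runs
without external data.

## Worked example

```python
from airwayprot import load_study_panel
from airwayprot.quantitation import (class_mean_score, dave,
                                     group_mean_fold_change, round_half_up)

panel = load_study_panel().to_score_panel()
a = class_mean_score(panel, None, "OR", "T0", "smooth_muscle")   # 265.0
b = class_mean_score(panel, None, "OR", "T36", "smooth_muscle")  # 7.5
print(round_half_up(dave(a, b), 2))                              # -1.89
print(round_half_up(group_mean_fold_change(panel, None,
                                           "smooth_muscle", "NOR"), 1))  # 2.5
```

The responder smooth-muscle class falls from a group-mean score of 265 to
7.5, a DAVE of −1.89 — close to the −2.0 absence bound, i.e. near-complete
loss of smooth-muscle signal after treatment — while the non-responder
group's per-patient fold changes average +2.5 on the natural-log scale
(a ~12-fold rise).

Running the full pipeline end to end:

```bash
airwayprot report --outdir out/
```

writes the differential table, phenotype labels, Newick dendrograms and a
summary JSON.  On the bundled panel the summary shows Gal-3 positivity at
baseline for exactly the four responders, and the T36 dendrogram places
non-responder NOR2 — whose protein dynamics mirror the responders — inside
the responder cluster.  Narrative scripts under `examples/` demonstrate
each capability (differential quantitation, cohort simulation +
clustering, PSM filtering, morphometry) and print what the numbers mean.

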