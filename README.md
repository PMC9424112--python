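# oedprog

Prognostic modelling toolkit for **oral epithelial dysplasia (OED)** cohorts
reviewed by multiple pathologists.

OED is a premalignant disorder of the oral mucosa; histological grading
(WHO three-tier or binary low/high) is the standard prognostic tool but is
subjective and a weak predictor of which lesions will transform to oral
squamous cell carcinoma or recur after treatment. An alternative is to score
the *individual* histological features each pathologist marks as present,
call a consensus per feature, and count features in a simple point model.
`oedprog` implements that analysis end-to-end:

* **consensus calling** — a feature is present when a majority of raters
  (2 of 3) marked it prominent;
* **inter-rater agreement** — per-feature prevalence π, observed pairwise
  agreement Pa, and two chance-corrected coefficients:
  Fleiss-type kappa, κ = (Pa − Pe)/(1 − Pe) with Pe = π² + (1−π)², and
  Gwet's AC1 with Pe = 2π(1−π), which is robust at prevalence extremes;
* **prognostic scores** — the *six-point model* (one point each for bulbous
  /drop-shaped rete pegs, hyperchromatism, loss of epithelial cohesion,
  loss of stratification, suprabasal mitoses, nuclear pleomorphism; risk
  strata 0–1 / 2–3 / 4–6) and the *two-point model* (loss of epithelial
  cohesion and bulbous rete pegs, the two features with the best
  inter-rater agreement);
* **survival analysis** — Kaplan–Meier curves per score stratum with
  Greenwood variance and log(−log) confidence intervals, and univariate Cox
  proportional-hazards regression with Efron's correction for tied event
  times (one fit per feature per outcome);
* **discrimination** — AUROC of scores, grades and covariate-augmented
  logistic models, DeLong tests for correlated AUCs, and per-rater
  evaluation of both score models;
* **synthetic cohorts** — a calibrated generator (latent feature profiles,
  noisy raters, feature-dependent exponential hazards) that emulates a
  109-case, three-rater study, used for every parameter-recovery test.

## Worked example

```python
from oedprog import (default_config, generate, agreement_table,
                     consensus_profiles, score_cohort, auroc)
from oedprog.agreement import agreement_frame
from oedprog.cohort import cohort_to_frame
import pandas as pd

study = generate(default_config(seed=42))        # 109 cases, 3 raters
frame = cohort_to_frame(study.records)
print("events:", int(frame.transformation_event.sum()), "transformed,",
      int(frame.recurrence_event.sum()), "recurred of", len(frame))

print(agreement_frame(agreement_table(study.panel)).head(4).to_string(index=False))

profiles = consensus_profiles(study.panel)       # 2-of-3 majority rule
results, counts = score_cohort(profiles, "six_point")
print("six-point strata:", counts)

scores = pd.Series({r.case_id: r.score for r in results}).reindex(frame.index)
print(f"six-point AUROC (transformation): "
      f"{auroc(scores, frame.transformation_event.astype(int)).auc:.3f}")
```

prints

```
events: 16 transformed, 25 recurred of 109
               feature  n_positive  prevalence  complete_agreement  kappa  ac1
basal_cell_hyperplasia         242        0.74                0.62   0.35 0.59
     bulbous_rete_pegs         191        0.58                0.63   0.50 0.52
          dyskeratosis         123        0.38                0.71   0.58 0.63
       hyperchromatism         174        0.53                0.63   0.51 0.51
six-point strata: {'2-3': 76, '4-6': 23, '0-1': 10}
six-point AUROC (transformation): 0.855
```

The generator hit its calibration targets: 16/109 ≈ 15% of lesions
transformed and 25/109 ≈ 23% recurred (targets 18% and 25%), pooled feature
prevalences land near their configured values (e.g. bulbous rete pegs
191/327 ≈ 0.58), and rater noise of sensitivity 0.85 / specificity 0.90
produces kappa ≈ 0.35–0.58 — the modest-agreement regime typical of OED
feature scoring. The six-point consensus score discriminates transforming
lesions well (AUROC 0.855 on this draw) because the generating hazards are
feature-driven.

## Command line

```sh
oedprog simulate --seed 42 --out-dir data/        # ratings.csv cohort.csv truth.csv
oedprog consensus --ratings data/ratings.csv --min-agree 2 --out consensus.csv
oedprog agreement --ratings data/ratings.csv --out agreement.csv
oedprog score --consensus consensus.csv --model six_point --out scores.csv
oedprog survival --cohort data/cohort.csv --consensus consensus.csv \
    --event transformation --out cox.csv --km-json km.json
oedprog evaluate --cohort data/cohort.csv --ratings data/ratings.csv --out eval.json
oedprog run --config study.yaml --out-dir report/  # full pipeline + bundle.json
```

Exit codes: 0 ok, 2 validation error, 3 numerical failure.

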