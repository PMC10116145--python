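# c3b

Scoring, regression-based demographic norms, MCI screening diagnostics and
test-retest reliability for the **Cleveland Clinic Cognitive Battery
(C3B)** — a brief self-administered cognitive screen made of two modules:

- **VMT** (Visual Memory Test): 7 symbols on a 4×6 board, 5 learning
  trials, 2 points per correct symbol+location, 1 point for any symbol on a
  target cell; two consecutive perfect trials discontinue the test.
  Maximum 70.
- **PST** (Processing Speed Test): symbol→digit substitution against a
  9-pair key for 120 s; total correct and incorrect presses are recorded.

The package is aimed at researchers and implementers who need the battery's
computational pipeline — raw scores → demographically adjusted z-scores →
impairment calls and signal-detection diagnostics — reproducible from code,
plus the simulation machinery to validate every stage without patient data.

## The model at the core

Raw scores are adjusted with regression-based norms fitted on a stratified
healthy sample (n = 428, ages 18–89):

```
z = (raw − predicted) / RMSE

PST: predicted = 65.2217 − 0.4591·age − 0.0053·(age − 50.26714)²
                 + 0.7999·educ − 2.2132·male − 4.0893·AA        (RMSE 8.958)
VMT: predicted = 58.8785 − 0.3118·age − 0.0329·max(0, age − 71)²
                 + 0.7152·educ − 5.6555·AA                      (RMSE 12.879)
```

A subject screens positive for cognitive impairment when the lower of the
two z-scores falls below the cutoff, `min(z_PST, z_VMT) < −0.4`.
Discrimination between MCI patients and healthy controls is summarized by
the confusion matrix, sensitivity/specificity, Youden's J, the ROC/AUC and
the Youden-optimal cutoff; retest stability by the paired t, paired Cohen's
d (= t/√n) and ICC(2,1).

## Worked example

```python
from c3b import norms

models = norms.builtin_models()
demo = norms.Demographics(age=30, education=16, sex=0, race=0)

pred = norms.predicted_score(models["VMT"], demo)   # 60.97
z = norms.adjusted_z(33, models["VMT"], demo)       # -2.17
```

A 30-year-old with 16 years of education is *predicted* to score 61.0 on
the VMT; a raw score of 33 is 2.17 residual SDs below that expectation —
impaired for this demographic stratum, even though the same raw score can
be within normal limits for an older, less-educated patient. Running
`python examples/02_adjusted_zscores.py` prints both contrasting patients:

```
patient 1 (age 30, educ 16, F, non-AA)
  PST: raw 36, predicted  62.1, z -2.91 -> impaired
  VMT: raw 33, predicted  61.0, z -2.17 -> impaired
patient 2 (age 60, educ 10, M, AA)
  PST: raw 36, predicted  38.9, z -0.32 -> WNL
  VMT: raw 33, predicted  41.7, z -0.67 -> impaired
```

The `examples/` directory has one short script per capability: session
scoring, z-scores, norm refitting, MCI screening and retest reliability.
A thin CLI mirrors the same stages:

```bash
c3b zscore --test pst --age 30 --education 16 --sex F --race nonAA --raw 36
c3b simulate cohort --seed 1 --out cohort.csv
c3b fit-norms --cohort cohort.csv --test pst
c3b screen --cohort cases.csv --cutoff -0.4
```

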