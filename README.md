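# hmiol — machine-learning IOL power calculation for highly myopic eyes

Cataract surgeons replace the crystalline lens with an intraocular lens
(IOL) whose power must be chosen so the eye ends up at the intended
refraction. In highly myopic eyes (axial length AL ≥ 26 mm) the classical
vergence formulas and the newer AI calculators both lose accuracy, and
several popular calculators refuse input beyond AL = 35 mm. `hmiol`
implements a stacked machine-learning calculator designed specifically
for this population, together with everything needed to train, apply and
benchmark it:

* **Vergence engines.** SRK/T and Haigis thin-lens formulas, forward
  (spectacle refraction *R* from power *P*) and inverse (closed-form *P*
  for a target *R*), with the standard conventions pinned: keratometer
  index 1.3375 (r = 337.5/K), 12 mm vertex, SRK/T indices 1.336/1.333,
  Haigis corneal index 1.3315 and ELP = a0 + a1·ACD + a2·AL.
* **Feature transforms.** Each eye is described by its six biometrics
  (AL, flat/steep K, ACD, LT, CD), the implanted power and A constant,
  plus the Haigis-predicted refraction (feature set 2) and additionally
  the SRK/T-predicted refraction (feature set 1).
* **The ensemble.** Four sub-models — {gradient-boosted trees (XGBoost),
  RBF-kernel SVR} × {feature set 1, feature set 2} — each regress the
  observed postoperative spherical equivalent; the assembled prediction
  is the weighted average Σ w·ŷ with weights ∝ 1/MAE from an internal
  5-fold out-of-fold evaluation (equal weights selectable).
* **Planner.** Exhaustive search of the manufacturable 0.5 D power grid
  for the power whose predicted refraction is closest to the target,
  ties breaking toward the more myopic outcome. No AL or target limits.
* **Evaluation battery.** Prediction error PE = actual − predicted;
  mean/SD, MAE, MedAE, % of eyes within ±0.25/0.50/0.75/1.00 D,
  cumulative |PE| curves, PE-vs-AL trend, a composite formula
  performance index, AL subgroup reports (26–28, 28–30, ≥ 30 mm), and
  the comparison suite: Friedman with Bonferroni post-hocs, Cochran's Q
  with McNemar post-hocs, pairwise log-rank on cumulative curves.
* **Synthetic cohorts.** A seeded generator reproducing the reference
  high-myopia cohort moments (AL 29.18 ± 2.19 mm on 26–37.5 mm, etc.)
  with a known ground-truth refraction model, so every pipeline stage is
  testable without patient data.

## Worked example

```python
from hmiol import (PredictionErrorSeries, noise_floor_mae, split_cohort,
                   summarize, train_ensemble)
from hmiol.synthetic import CohortSpec, generate_cohort
import numpy as np

cohort = generate_cohort(CohortSpec(n=900, seed=21, noise_sd=0.3))
train, test = split_cohort(cohort, 0.8, seed=3)
ensemble = train_ensemble(train, seed=1)

actual = np.array([c.postop_se for c in test])
pe = actual - ensemble.predict_cases(test)
al = np.array([c.biometry.axial_length for c in test])
report = summarize(PredictionErrorSeries("ensemble", pe,
                                         tuple(c.case_id for c in test)), al)
print(report.mae, report.pct_within[0.50])
```

Running `python examples/02_simulate_train_evaluate.py` (this code)
prints:

```
cohort: 900 eyes -> 720 train / 180 test
sub-model weights (inverse out-of-fold MAE):
  xgb_set1: 0.272
  xgb_set2: 0.270
  svr_set1: 0.229
  svr_set2: 0.229
held-out MAE:   0.247 D (irreducible floor 0.239 D)
held-out MedAE: 0.213 D; SD of PE 0.314 D
within +/-0.50 D: 90.0% of eyes
```

The outcomes of this cohort are a Haigis ground truth plus N(0, 0.3 D)
noise, so a perfect predictor would score MAE 0.3·√(2/π) ≈ 0.239 D; the
ensemble's 0.247 D means it has recovered essentially all of the signal.
The other scripts in `examples/` show the vergence engines on a single
eye, inverse power planning for a −3 D target, and the full formula
comparison battery.

A command-line interface mirrors the library:

```bash
hmiol simulate --n 1462 --seed 7 --out cohort.csv
hmiol train --cohort cohort.csv --out model.joblib --seed 1
hmiol plan --model model.joblib --al 29.0 --kflat 43.2 --ksteep 44.1 \
           --acd 3.4 --lt 4.4 --cd 11.8 --aconst 118.0 --target -3.0
hmiol evaluate --predictions preds.csv --out report
```

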