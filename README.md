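# coxladder

Prognostic factors in breast cancer — age at diagnosis, tumor size,
number of positive lymph nodes — are continuous (or integer-valued)
quantities that clinical practice habitually chops into categories.
`coxladder` implements, as a tested and reusable pipeline, the classic
methodological comparison of Cox proportional-hazards models of
successively increasing covariate complexity:

1. **dichotomized** predictors (one clinical cut-point each:
   age < 35 vs ≥ 35 years, tumor size > 20 vs ≤ 20 mm, any positive
   nodes vs none);
2. **categorized** predictors (age < 35 / 35–50 / > 50; size T1 ≤ 20 mm
   / T2 21–50 mm / T3 > 50 mm; nodes N0 / N1–3 / N4–9 / N ≥ 10);
3. **fractional polynomials (FP)** — transformations x^p with powers
   from {−2, −1, −0.5, 0, 0.5, 1, 2, 3} (x⁰ ≡ ln x), degree chosen per
   covariate by a closed likelihood-ratio test procedure, extended to
   several covariates by the multivariable backfitting procedure (MFP);
4. **restricted cubic splines (RCS)** — piecewise cubics with five
   knots, linear beyond the boundary knots, spanned by four basis
   columns per covariate.

Discrimination is measured by **Harrell's concordance index** C: the
fraction of evaluable patient pairs in which the patient surviving
longer has the lower predicted hazard (0.5 = useless, 1.0 = perfect).
Each fitted model yields a **prognostic index** PI — the Cox linear
predictor, centered so a reference patient (35 years, 20 mm, 0 nodes)
has relative hazard exp(PI) = 1.00 — which is cut at the 16th/50th/84th
percentiles into risk groups G1–G4 and **transported unchanged**
(transforms and weights frozen) to an external validation cohort.

Because patient-level registry data of this kind is not
redistributable, the package ships a synthetic-cohort generator with
known ground-truth effects (linear in age, √size, log(nodes+1) on the
log-hazard scale) whose marginals emulate a large six-material
derivation series (median age 60, median tumor size 22 mm, 40 %
node-negative, 29 % distant recurrences within 10 years) and a
lower-risk external validation series (58 % node-negative, 26 %
events).  Every downstream stage is therefore testable against truth.

The survival machinery (stratified Cox partial likelihood with Breslow
or Efron ties, Newton–Raphson with step-halving, Kaplan–Meier with
Greenwood/log-log intervals, the Grambsch–Therneau proportional-hazards
test) is implemented from first principles because the FP closed test
needs the stratified log partial likelihood at arbitrary designs; the
test suite cross-checks it against independent implementations
(lifelines, R `survival`, scikit-survival).

## Worked example

```python
from coxladder import (StudyConfig, run_study)

report = run_study(StudyConfig(seed=1))
for mc, entry in report["models"].items():
    print(f"{mc:13s} C(derivation) = {entry['derivation']['c_index']['c']:.3f}"
          f"   C(validation) = {entry['validation']['c_index']['c']:.3f}")
```

prints

```
dichotomized  C(derivation) = 0.641   C(validation) = 0.659
categorized   C(derivation) = 0.674   C(validation) = 0.675
fp            C(derivation) = 0.685   C(validation) = 0.687
rcs           C(derivation) = 0.686   C(validation) = 0.688
```

The pattern is the point: discrimination improves markedly when one
cut-point per factor becomes two or three (0.641 → 0.674), and only
modestly more when the predictors stay continuous via FP or RCS
transformations (→ 0.685/0.686), with FP and RCS nearly
indistinguishable.  The report also contains, per model class, the
selected transformations, coefficients with 95 % confidence intervals,
risk-group sizes with requested *and achieved* percentiles (a
categorized model's heavily tied PI cannot be cut exactly at
16/50/84), per-group 10-year survival, and the validation-set group
shift: on the lower-risk validation cohort the lowest-risk group G1
inflates well past 16 % and the highest-risk G4 shrinks below 16 %.

The same workflow is scriptable from a shell:

```sh
coxladder simulate --kind derivation --n 4477 --seed 1 --out deriv.csv
coxladder fit --cohort deriv.csv --models fp rcs --out fits/
coxladder simulate --kind validation --n 1132 --seed 2 --out valid.csv
coxladder validate --model fits/fp_model.json \
    --grouping fits/fp_grouping.json --cohort valid.csv \
    --seed 0 --out transport.json
coxladder run --seed 1 --out report.json   # everything in one go
```

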