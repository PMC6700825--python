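# pescreen

First-trimester combined screening for preeclampsia (PE) and
small-for-gestational-age (SGA) neonates, as a tested, reusable Python
pipeline. It is aimed at screening laboratories and perinatal-epidemiology
researchers who want an open, refittable implementation of the
likelihood-ratio risk calculation used by commercial first-trimester PE
screening software, together with the statistics needed to evaluate it.

## What it computes

For each pregnancy screened at 11⁺⁰–13⁺⁶ weeks:

1. **Prior risk** per horizon (early PE: delivery < 34 weeks; late PE:
   delivery ≥ 34 weeks) from five maternal factors — BMI band, ethnicity,
   parity, history of PE, chronic hypertension:

   `odds_prior = odds_baseline × ∏ᵢ LRᵢ`

2. **MoM normalization** of the three markers — mean arterial pressure
   (MAP = ⅓ systolic + ⅔ diastolic, highest arm, mean of the last two stable
   readings), serum PLGF (pg/mL) and PAPP-A (mU/L):

   `MoM = level / median(GA)`, with `log₁₀ median(GA) = a + b·GA_days`,
   and PLGF/PAPP-A MoM additionally adjusted for weight, ethnicity and
   smoking. Adjusted log₁₀ MoM is truncated to [−1, 1].

3. **Posterior risk** by Bayes' rule with a trivariate Gaussian marker
   likelihood ratio:

   `odds_post = odds_prior × N(x; μ_affected, Σ_affected) / N(x; μ_unaffected, Σ_unaffected)`

   where `x = (log₁₀ MoM_MAP, log₁₀ MoM_PLGF, log₁₀ MoM_PAPP-A)`. Risks are
   reported clinically as "1 in N", screen-positive at cutoff 1:N when
   p ≥ 1/N.

4. **Screening performance**: ROC curves with rank-statistic AUC and DeLong
   confidence intervals, paired DeLong comparison of prior vs posterior
   AUCs, optimal cutoffs (highest mean of sensitivity and specificity),
   detection rates / PPVs at fixed false-positive rates (5/10/15%), and
   exact Clopper–Pearson binomial CIs throughout.

Because the commercial software's parameters are proprietary, every model
component here is explicit configuration: shipped defaults are calibrated to
the published summary tables of a 3,270-pregnancy Chinese screening cohort
(8 early PE, 35 late PE, 99 SGA), and a synthetic-cohort generator
reproduces that cohort's statistical structure so the entire pipeline is
testable end to end without any data download.

## Worked example

```python
import numpy as np
from pescreen import default_config, generate
from pescreen.cohort import pe_status_frame
from pescreen.mom import MoMTransformer
from pescreen.pipeline import mom_input_frame
from pescreen.risk import GaussianRiskModel, posterior_risk
from pescreen.evaluate import dr_at_fpr, roc_auc

cfg = default_config(seed=1)                       # the study conditions
frame = generate(cfg)                              # 3,270 pregnancies
status = pe_status_frame(frame)                    # none / early / late

moms = MoMTransformer(median_model=cfg.median_model).fit(None) \
        .transform(mom_input_frame(frame))
X = moms[["log10_mom_map", "log10_mom_plgf", "log10_mom_pappa"]]
print(float(moms.loc[(status=="none").to_numpy(), "mom_plgf"].median()))
# 1.1049... (unaffected PLGF MoM median; published value 1.11)

est = GaussianRiskModel().fit(X, status)
post = posterior_risk(0.0024, est.likelihood_ratio(X.to_numpy(), "early"))
print(round(roc_auc(post, (status=="early").to_numpy()).auc, 3))
# 0.97  (apparent AUC for early PE on this synthetic cohort)
res = dr_at_fpr(post, (status=="early").to_numpy(), 10.0)
print(res.dr_pct)
# 87.5  (7/8 early-PE cases detected at 10% FPR)
```

The numbers printed above are from an actual run at seed 1; the AUC is
*apparent* performance (fit and evaluated on the same cohort) and is
optimistic relative to a train/test split.

There is also a CLI covering each stage:

```bash
pescreen simulate --seed 1 --out cohort.csv
pescreen fit-model cohort.csv --out model.yaml
pescreen score cohort.csv --model model.yaml --out risks.csv
pescreen run config.yaml --out run_dir/      # full pipeline + reports
pescreen import-supplementary results.xlsx --mapping map.yaml --out scored.csv
```

## Layout

- `src/pescreen/bp.py` — blood-pressure protocol (MAP, stability, two arms)
- `src/pescreen/cohort.py` — domain types, cohort CSV I/O, PE/SGA rules
- `src/pescreen/mom.py` — median models, MoM computation and adjustment
- `src/pescreen/risk.py` — prior model, Gaussian LR model, posterior risks
- `src/pescreen/evaluate.py` — ROC/AUC, DeLong, cutoffs, exact CIs
- `src/pescreen/simulate.py` — synthetic-cohort generator
- `src/pescreen/params.py` — shipped default parameters
- `src/pescreen/pipeline.py`, `cli.py`, `modelio.py` — orchestration, CLI,
  model serialization

See `docs/methods.md` for the model assumptions, parameter provenance, and
known limitations.
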