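# fbgrisk

Visit-to-visit fasting blood glucose (FBG) indices and retinopathy
risk-model comparison for longitudinal screening cohorts.

## The problem

Diabetic retinopathy (DR) risk depends not on a single glucose snapshot
but on the level, variability and duration of glycemic exposure across
years. Epidemiologists working with multi-wave screening cohorts
summarise a participant's repeated FBG measurements into per-participant
indices and ask which of them best predicts DR beyond the classical risk
factors (age, sex, BMI, education, income, smoking, drinking,
hypertension, dyslipidemia). `fbgrisk` implements that whole workflow:
the indices, the cohort plumbing (eligibility filters, single-value
imputation), adjusted logistic association models, and the
discrimination machinery used to compare risk models — plus a calibrated
synthetic cohort generator so the pipeline is fully testable without any
restricted data.

## The indices

For a participant with FBG values $x_1,\dots,x_n$ (mmol/L) at times
$t_1<\dots<t_n$ (days):

- **SD** — sample standard deviation of the $x_i$;
- **CV** $= 100\,\mathrm{SD}/\bar x$ (%);
- **VIM** $= 100\,\mathrm{SD}/\bar x^{\beta}$, with $\beta$ the cohort-wide
  OLS slope of $\ln\mathrm{SD}$ on $\ln\bar x$, so VIM is uncorrelated with
  the mean by construction;
- **ARV** $= \frac{1}{n-1}\sum_i |x_{i+1}-x_i|$ (mean absolute successive
  change; a percent-of-mean variant is the pipeline default);
- **M-FBG** $= \bar x$;
- **cumulative FBG load** $= 100\int \max(f(t)-5.6,\,0)\,dt \,/\int
  f(t)\,dt$, where $f$ is the piecewise-linear interpolant over the
  participant's own visit window and 5.6 mmol/L is the prediabetes
  threshold — the share of the glucose curve in excess of threshold,
  weighting how high *and* how long glucose stays elevated.

Model comparison uses the Mann–Whitney AUC with DeLong variance and the
paired DeLong test for correlated ROC curves, the integrated
discrimination improvement (IDI), the categorical net reclassification
index (NRI, default categories at 5% and 15% predicted risk), and
AIC/BIC.

## Worked example

```python
import numpy as np
from fbgrisk import FBGSeries, compute_cumulative_load, compute_mfbg, compute_sd

s = FBGSeries("demo", times=np.array([0., 550., 1280., 2750.]),
              values=np.array([5.2, 6.4, 5.9, 7.1]))
print(compute_mfbg(s), compute_sd(s), compute_cumulative_load(s))
```

prints `M-FBG = 6.150` mmol/L, `SD = 0.802` mmol/L and a cumulative load
of `10.86` % — this participant spends part of the follow-up above
5.6 mmol/L, and the load quantifies that excess relative to the whole
curve. At cohort scale (`examples/04_model_comparison.py`, 5,054
simulated participants, seed 11):

```
reference model AUC (classical + baseline FBG): 0.8295

model                        AUC     dAUC       p      IDI      NRI     dAIC
classical                 0.6726  -0.1569   0.000  -0.0927  -0.3985    161.4
classical+m_fbg           0.8445   0.0150   0.041   0.0219   0.0848    -30.2
classical+cum_load        0.8462   0.0167   0.049   0.0202   0.1361    -34.5
```

Adding the cumulative load to the classical risk factors beats both the
classical model and the snapshot-FBG reference on every criterion
(higher AUC, positive IDI/NRI, lower AIC) — the qualitative ordering the
index comparison is designed to detect, here on data whose outcome is
generated from the true load.

Each script in `examples/` demonstrates one capability: cohort
simulation, single-series indices, adjusted odds ratios, model
comparison, and the full pipeline (`fbgrisk analyze` on the command line
does the same from a YAML config).

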