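# hdmice

Multiple imputation by chained equations (MICE) for data tables where the
number of candidate predictors is comparable to — or much larger than —
the number of observed rows, as in registry and omics studies. Standard
MICE cannot fit its per-variable conditional regressions when p ≳ r_j;
`hdmice` provides two *proper* regularized strategies:

* **DURR** (direct use of regularized regression): for each incomplete
  variable z_j, bootstrap the current completed data, fit a
  cross-validation-tuned lasso / elastic-net / adaptive-lasso regression of
  z_j on all other variables, and draw imputations from the Gaussian
  predictive distribution N(x'β̂*, σ̂²). The bootstrap makes β̂* a draw
  from its sampling distribution, so the imputations propagate estimation
  uncertainty.
* **IURR** (indirect use): the penalized fit is used only to *select* the
  active set Ŝ_j; the imputation model is refit by OLS on Ŝ_j and
  parameters are drawn from the flat-prior posterior
  σ²\* = RSS/χ²_ν, β\* ~ N(β̂, σ²\*(X'X)⁻¹) before each predictive draw.

M completed datasets are analysed (OLS or logistic regression) and pooled
by Rubin's rules: q̄ = mean estimate, T = W + (1 + 1/M)B,
ν = (M−1)(1 + W/((1+1/M)B))². A Monte-Carlo harness generates synthetic
high-dimensional data (AR(1) Gaussian predictors, a shared true active
set, MAR missingness calibrated to ~40% incomplete rows) and tabulates
bias, mean SE, Monte-Carlo SD, MSE and 95%-CI coverage against
gold-standard, complete-case and known-active-set reference analyses.

## Worked example

Generate a synthetic incomplete dataset (the same generator the test
suite uses), impute with IURR-lasso, and pool a regression across the
completed datasets. The same entry points accept any numeric CSV via
`read_table("input.csv")` (missing cells blank, `NA` or `NaN`):

```python
import numpy as np
from hdmice import (SimConfig, calibrate_missingness, generate_complete_data,
                    impose_mar_missingness, make_imputer, multiple_impute,
                    fit_analysis_model, pool_coefficient)

cfg = calibrate_missingness(SimConfig(n=200, p=30, q=4, seed=7))
rng = np.random.default_rng(7)
complete = generate_complete_data(cfg, rng)
data = impose_mar_missingness(complete, cfg, rng)   # MAR mask on z1..z3
print("rows with missing cells:", int((~data.mask.all(axis=1)).sum()))

ens = multiple_impute(data, make_imputer("iurr-lasso"), M=10, T=20, rng=rng)
fits = [fit_analysis_model(d, outcome=cfg.outcome_col, covariates=[0, 1, 2])
        for d in ens.datasets]
pooled = pool_coefficient(fits, index=1)            # beta1, true value 1
print(f"estimate {pooled.estimate:.3f}  "
      f"95% CI ({pooled.ci_low:.3f}, {pooled.ci_high:.3f})  df {pooled.df:.1f}")
```

which prints

```
rows with missing cells: 75
estimate 1.243  95% CI (0.344, 2.143)  df 42.8
```

— the pooled slope of z1 with a t-based interval whose width carries the
between-imputation variance (37.5% of rows had at least one missing
covariate). The same pipeline is available from the shell:

```sh
hdmice impute input.csv --method iurr-lasso -M 10 -T 20 --seed 7 --out-dir out/
hdmice simulate --methods GS,CC,mi-true,iurr-lasso --n-mc 50 --out metrics.csv
hdmice pool per_dataset_estimates.csv --out pooled.csv
```

`hdmice simulate` prints the metrics table; e.g. the gold-standard row at
the default scenario (n=100, p=200, q=4, ρ=0.1) reproduces near-zero bias
and ~95% coverage, while complete-case analysis is substantially biased
because missingness is outcome-driven.

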