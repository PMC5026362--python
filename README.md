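# audmix

Latent-cluster modelling of longitudinal audiogram data: compares three
regression predictors — pooled OLS, a linear mixed-effects model, and a
grouped mixture of linear regressions fitted by EM — on three prediction
tasks: missing-data imputation, future forecasting, and generalization to
new patients.

## The problem

Pediatric hearing thresholds (dB, one value per audiogram test) evolve with
age, and the *unit of analysis* is the PEF — one **p**atient-**e**ar-
**f**requency combination, treated as an independent longitudinal series of
4–21 tests. Threshold trajectories differ systematically between patients:
a single pooled regression underfits, while a per-PEF mixed-effects model
cannot transfer anything it learned about an individual to a patient it has
never seen.

The mixture of regressions takes a middle path. It assumes K latent
clusters, each with its own coefficient vector over the design
`[1, ln(age), gender, ln(diagnoses + 1)]`:

    threshold | cluster = k  ~  N(β_k · x, σ²_k),

with the constraint that **all rows of one PEF share a single cluster**.
Fitting is EM: the E-step computes each PEF's posterior membership from the
joint likelihood of all its rows, the M-step solves responsibility-weighted
least squares per cluster. Prediction is the posterior-weighted average of
the per-cluster regression lines, and for a *new* PEF the posterior comes
from Bayes' rule on whatever observations are supplied — no retraining:

    p(cluster = k | rows)  ∝  π_k · Π_j N(y_j ; β_k · x_j, σ²_k).

Because cluster membership is inferable from a handful of observations, the
mixture keeps its individual-level accuracy on unseen patients, where the
mixed-effects model collapses to its population-level fixed effects.

## Worked example

```python
from audmix import GeneratorConfig, generate_cohort, prepare, run_task

records, truth = generate_cohort(GeneratorConfig(n_pefs=300, seed=0))
ds, report = prepare(records)          # filters + PEF grouping + design
out = run_task("new_patient", ds, k_max=4, seed=0)
print(out["comparison"])
```

On a synthetic three-cluster cohort (300 PEFs, residual SD 5 dB) this prints
the characteristic reversal — the mixed model is no better than OLS on
patients it has never seen, while the mixture recovers the latent clusters
and stays accurate:

```
       model        mse      rmse
         ols 461.805621 21.489663
       mixed 472.190596 21.729947
mixture(k=3)  22.900561  4.785453
```

On the imputation and forecasting tasks (where the mixed model *has* seen
every PEF) the same cohort gives `ols ≈ 447 / mixed ≈ 33 / mixture(k) ≈ 25`
and `ols ≈ 556 / mixed ≈ 40 / mixture(k=3) ≈ 26` — the mixture approaches
the mixed-effects model from above as k grows, and both beat OLS by an
order of magnitude.

## Package layout

| module | contents |
| --- | --- |
| `audmix.synthetic_data` | cohort generator with known ground truth (clusters, random effects, drift, contamination) |
| `audmix.cohort_prep` | six inclusion/exclusion criteria, PEF coding, design matrix |
| `audmix.mixture_model` | EM fitting, K selection, small-cluster pruning |
| `audmix.baseline_models` | pooled OLS and the PEF-grouped mixed-effects model |
| `audmix.prediction` | posterior-weighted prediction, Bayes-rule membership inference |
| `audmix.evaluation` | the three task splits, MSE scoring, error-gap regression |

`docs/methods.md` documents the model, all tunable parameters with their
defaults and rationale, and known limitations (including one documented
statistically-unattainable recovery tolerance).
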