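# aeroee

Energy-expenditure (EE) modelling for aerobic training with wearable
sensors. `aeroee` simulates two-group athlete cohorts (elite badminton
players vs. enthusiasts) with multi-site accelerometer, heart-rate and
criterion-EE data, runs exhaustive feature-subset regression searches under
pooled five-fold cross-validation, and scores (sample size, sensor count,
model) deployment configurations with the Triple-E framework. It is aimed
at sport scientists and method developers who want a tested, seeded
pipeline for sensor-placement and sample-size questions — and a synthetic
cohort generator to benchmark such pipelines when human data are
unavailable.

## The method

For each activity a ∈ {running, cycling, rope skipping, stair walking} and
skill group, a feature table is built from the steady-state (penultimate)
minute of each participant's trace: heart rate HR, ΔHR = HR − HR_rest,
per-site vector-magnitude counts VM = √(x²+y²+z²) for the waist, wrists
and ankles, plus demographics and body composition. Every non-empty
feature subset S (optionally size-capped) is fed to seven regression
families f (linear regression, Bayesian ridge, random forest, gradient
boosting, SVR, XGBoost-style boosting, decision tree); out-of-fold
predictions from a seeded 5-fold split are pooled and scored by

    R²   = 1 − Σ(y − ŷ)² / Σ(y − ȳ)²
    MAPE = mean(|y − ŷ| / y)
    RMSE = √(mean((y − ŷ)²))

The winning (f, S) maximises R², then minimises MAPE and RMSE. A
deployment configuration with X of Y = 6 sensors and sample size N is then
scored on three axes,

    Effectiveness = R² · (1 − MAPE)
    Efficiency    = 1 − X/Y − α          (α = 0 / 0.1 / 0.2 by family)
    Extension     = (k·R²) / (1 + (k−1)·R²),   k = N/N_ref,  N_ref = 40

and the composite is the area of the triangle the three scores span on
radar axes 120° apart. See `docs/methods.md` for the full generative model
of the synthetic cohorts and all numerical conventions.

## Worked example

```bash
python examples/model_search_demo.py
```

```
elite: linear_regression on body_mass, skeletal_muscle, delta_hr
  pooled-CV R2=0.976  MAPE=1.17%  RMSE=0.198 kcal/min  sensors=1
enthusiast: linear_regression on age, fat_pct, delta_hr
  pooled-CV R2=0.954  MAPE=2.00%  RMSE=0.293 kcal/min  sensors=1
```

Both winners here get by with the heart-rate strap plus free demographic
covariates, but the elite model is visibly tighter; over replicate cohorts
enthusiast winners recruit accelerometers markedly more often than elite
winners (the planted skill-level contrast, asserted statistically in the
test suite). `examples/` contains one script per capability: cohort
simulation (`simulate_cohort.py`), the search above, sensor-count and
sample-size ablations (`ablation_curves.py`), and Triple-E configuration
ranking (`triple_e_report.py`). The ablation example prints a sensor-count
curve peaking at three sensors (R² 0.971) and degrading at six (0.922),
and a heart-rate-only sample-size sweep improving from mean R² 0.963 at
n = 20 to 0.974 at n = 40.

Typical library use:

```python
from aeroee import (GeneratorConfig, generate_cohort, apply_missingness,
                    run_group_search)

cfg = GeneratorConfig(seed=1)
cohort = apply_missingness(generate_cohort(cfg), cfg)   # 50 -> 40 complete
result = run_group_search(cohort, "running", "elite", seed=1)
print(result.model, result.feature_set, result.metrics)
```

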