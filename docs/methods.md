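# Methods

This note documents the models, defaults and numerical choices behind
`aeroee`: what the synthetic cohorts emulate, how the model search and the
Triple-E scores are defined, and what passing the test suite does and does
not establish about real training data.

## The modelling problem

During aerobic training (treadmill running, cycling, rope skipping, stair
walking), per-minute energy expenditure (EE, kcal/min) is the criterion
quantity, measured in the lab by indirect calorimetry. Wearable signals —
triaxial accelerometer counts at the waist, both wrists and both ankles,
and heart rate from a chest strap — plus demographics and body composition
are the candidate predictors. The package asks three questions: which
(model family, feature subset) predicts EE best for a given activity and
skill group; how accuracy depends on the number of wearables; and how
accuracy, sensor parsimony and sample size trade off when choosing a
deployment configuration.

## Synthetic cohort generator

No public dataset exists for this design, so cohorts are simulated. The
generator is first-class, seeded code, and its defaults define the study
conditions used by every test and script.

**Demographics.** Two groups of 25 (elite, enthusiast). Age, fat
percentage and skeletal muscle are sampled independently per group from
normal distributions with the published group means/SDs; height and body
mass are bivariate normal (e.g. elite 174.1 ± 6.3 cm, 70.8 ± 9.6 kg;
enthusiast 172.8 ± 6.6 cm, 65.3 ± 6.8 kg) with correlation 0.55. BMI is
derived from height and mass, never sampled. The correlation matters:
under independence E[mass/height²] = E[mass]·E[1/height²] exceeds
mass/height² of the means (Jensen), biasing the enthusiast BMI mean to
≈22.0 instead of the published 21.9; a height–mass correlation in the
usual adult anthropometric range recentres the derived group BMI on the
published values (≈21.9 and ≈23.3 kg/m²) while leaving both marginals
untouched, and 0.55 is the value calibrated against the published BMI
row.
Resting heart rate is not reported in the source demographics; defaults of
58 ± 6 (elite) and 68 ± 6 (enthusiast) beats/min are physiologically
plausible non-calibrated choices. Sex is Bernoulli(0.5). Mild physiological
clipping (height ≥ 120 cm, fat 1–60 %, resting HR 35–100) guards the tails
without visibly biasing the means.

**Signals.** Per participant i, a latent fitness factor u_i ~ N(0, 0.10)
perturbs the activity's base intensity in METs (running 9.8, cycling 8.0,
rope skipping 11.0, stair walking 7.5 — compendium-style values for the
prescribed intensities). True EE is MET × 3.5 × mass / 200 kcal/min (a
generator convention), scaled by a two-minute warm-up ramp (0.85, 0.95,
then 1.0); the protocol lasts 5 minutes except rope skipping (3). Heart
rate is resting HR + slope_i × EE + N(0, 0.5 bpm), with the individual
response slope centred at 5 bpm/(kcal/min). Observed criterion EE carries a
1.5 % multiplicative measurement error. Site signals are
λ(group, activity, site) × intensity × (1 + e), converted to counts/min
(scale 800 per MET-unit of loading) and allocated to x/y/z along a fixed
per-site orientation with small jitter, so the vector magnitude — not any
single axis — is the informative quantity.

**Planted group structure.** The two groups differ in how cleanly the
wearables see the latent intensity, which is what the downstream
experiments are designed to detect:

* *Elite* — technically stable, dominant-side-loaded movement: independent
  per-site noise SDs of 0.04 (right wrist), 0.08 (right ankle), 0.12
  (waist) and 0.20 (left wrist/ankle); loadings amplified on the right
  side. Heart-rate response slope CV 0.010. Consequence: the heart-rate
  channel and the right-wrist accelerometer are the only strongly
  informative wearables.
* *Enthusiast* — variable execution: each trace draws a mean-centred
  allocation disturbance (SD 0.075) shared across the five sites (effort
  shifting unpredictably between limbs) plus independent noise 0.05, and a
  weaker heart-rate coupling (slope CV 0.024). Consequence: single sites
  are poor EE proxies, but multi-site combinations cancel the allocation
  component and genuinely add information beyond heart rate.

A desk calculation fixes the expected behaviour before any simulation. For
running, relative residuals of a heart-rate-only predictor are
√(slope_cv² + ee_obs² + (0.5/ΔHR)²) ≈ 1.9 % (elite) and 3.0 %
(enthusiast); with between-subject EE spread ≈ 12.7 %, the mixed-cohort
heart-rate-only model sits near R² ≈ 0.96 and MAPE ≈ 2.0 %, inside the
reference envelope (R² ≥ 0.95, MAPE ≤ 2.33 % at n = 40). For enthusiasts a
two-site combination (allocation component ≈ 0.55 × 0.075 ≈ 4 %) appreciably
improves their 3.0 % heart-rate channel, while for elites the wrist adds
little to an already-clean 1.9 % channel — which is exactly the
sensor-count contrast the group searches should and do recover. The
calibration was frozen from this calculation plus exploratory cohort
inspection and is not tuned per test.

**Missingness.** Bluetooth dropout is modelled as whole-stream loss: per
group, a seeded draw without replacement strikes 5 participants; each loses
one stream (HR, EE or one site) in one activity, and the completeness
filter then deterministically retains 40 of 50.

**What the generator does not emulate.** Raw 60 Hz waveforms,
device-specific count algorithms, breath-by-breath gas exchange, within-
activity pacing drift, and any correlation structure between demographics
beyond the derived BMI. Passing tests therefore demonstrates that the
pipeline recovers planted structure of this kind — not that the specific
published coefficients generalise to real athletes.

## Feature extraction

Steady state is operationalised as the penultimate minute (1-based index
duration − 1; the only reading consistent with both 3- and 5-minute
tasks), requiring ≥ 2 minutes. Features are the fixed ordered 15-column
set: age, sex (male = 1, female = 0), height, body mass, BMI, fat %,
skeletal muscle, resting HR, HR, ΔHR, and the five per-site vector
magnitudes √(x²+y²+z²). The target is the same minute's criterion EE in
kcal/min.

## Model search

Families: linear regression, Bayesian ridge, random forest, gradient
boosting, SVR, XGBoost-style boosting, decision tree. Hyperparameters are
pinned (version 1.0): 50 trees for the ensembles, depth-3 boosters,
RBF-SVR with C = 10 and ε = 0.01, unconstrained single tree. SVR and
Bayesian ridge are z-scored inside each training fold; tree and plain
linear families see raw features.

Cross-validation is a seeded shuffled 5-fold split shared by every
(family, subset) pair of a search; out-of-fold predictions are pooled and
the metrics computed once on the pooled vector (more stable than per-fold
averaging at n = 20–40, and the convention recorded in all outputs). MAPE
is stored as a fraction and rendered as percent. The winner maximises R²,
then minimises MAPE, then RMSE; remaining ties prefer smaller subsets,
canonical subset order, then family order. Metric keys are rounded to 10
decimals so informationally identical subsets tie deterministically rather
than splitting on float dust.

Exhaustive enumeration over all 2¹⁵ − 1 subsets × 7 families is available
but rarely sensible; default searches cap subset size at 3 (group
searches) or 2 (heart-rate-only studies), and the replicated experiment
suites use the two fast families (linear regression, decision tree) where
the claim under test is qualitative. These problem sizes are the package's
own defaults and are reported alongside every result.

## Experiments

* **Group search** — best (model, subset) per activity × group on the
  completeness-filtered cohort (≥ 10 members required).
* **Sensor-count ablation** — N fixed (default 20, elite scope); for each
  exact budget X = 1..6 the search is restricted to subsets whose wearable
  requirement equals X (strap = 1, each site = 1, demographics = 0),
  enumerated from configurable pools (strap features {ΔHR, HR}, demo pool
  {height, body mass, sex} capped at 2) to keep budget sweeps tractable.
* **Sample-size ablation** — wearables restricted to the strap
  (demographics allowed); the winning combination is selected once at the
  full n = 40, then re-cross-validated on group-stratified seeded
  subsamples at each n, averaged over replicate draws (default 20).
* **Configuration comparison** — the three canonical configurations
  (N=20 X=3 elite; N=20 X=2 strap+right wrist; N=40 X=1 heart-rate-only)
  scored with Triple-E and ranked by composite area.

## Triple-E scoring

Effectiveness = R² (1 − MAPE) with MAPE a fraction (a percent-scale value
would drive 1 − MAPE negative for ordinary errors; a unit warning fires
above 1.5). Efficiency = 1 − X/Y − α with Y = 6 and the fixed family
penalties α (0 linear/Bayesian ridge, 0.1 decision tree/SVR, 0.2
forest/boosters); it may be negative and is stored unclamped.
Extension = (kR²)/(1 + (k−1)R²), k = N/N_ref, N_ref = 40.

The composite places the three scores as radial coordinates on radar axes
120° apart, clamps radii below at 0 (a polygon radius cannot be negative),
and takes the triangle area (√3/4)(ab + bc + ca); sorting the clamped
scores first makes the value exactly permutation-symmetric. No published
closed form exists for the composite, and the reference report's printed
areas are not reconcilable with this (or any simple) geometry from the
printed inputs; the geometry used is therefore recorded in every score and
pluggable in principle. Areas computed here are comparable to each other,
not to externally printed areas.

## Determinism and numerics

All randomness derives from one master seed via keyed BLAKE2b hashing into
the 31-bit range (`derive_seed(master, stage, replicate)`); no global RNG
state is touched, so every experiment is a pure function of (cohort,
settings, seed) and re-runs are byte-identical. Cohort CSVs round-trip
exactly (`float_precision="round_trip"` on read). Degenerate inputs are
rejected loudly: MAPE with zero targets, CV with fewer rows than folds,
budgets above six sensors, extension at its pole, traces shorter than two
minutes.

## Known limitations

Synthetic cohorts cannot validate per-activity physiology beyond the
demographic calibration (the source reports no per-activity EE/HR by
group). The enthusiast allocation-noise architecture is one plausible
mechanism for "dispersed, variable loading"; others (e.g. time-varying
technique drift) would change how much multi-site sensing helps. Winner
identity at n = 20 is noisy — selection over hundreds of subsets rides on
CV noise — which is why the qualitative claims are asserted about
replicate means, not single cohorts.
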