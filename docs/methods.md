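# Methods

This note documents the models and procedures implemented in `icudca`, the
assumptions behind them, the parameters that matter, and what the synthetic
cohorts do and do not establish about behavior on real data.

## Problem framing

The unit of observation is the **patient-day**: one calendar day D of one
ICU admission, with features built from data available through 23:59 of
day D and a binary outcome indicating ICU exit at any time during day D+1.
This alignment guarantees that predictors precede the outcome. A positive
prediction triggers *proactive chart review and recruitment outreach*, not
an automated discharge decision; the downstream consumer is a research
coordinator screening for trial eligibility among patients about to leave
the ICU.

## Synthetic cohort generator

Real patient-day extracts come from credentialed EHR databases and cannot be
redistributed, so the generator produces cohorts with the statistical
structure the downstream analysis depends on.

**Generative model.** Each admission draws a nominal maximum stay length
from a shifted geometric law (`los_geometric_p = 0.3`, median 2 nominal
days, support ≥ 1). Daily feature vectors are drawn per a manifest of
(name, domain, marginal, missingness fraction) entries across five domains:
vital-sign summaries (min/mean/SD of HR, RR, systolic BP, temperature),
laboratory summaries (mean/last/variability of creatinine, BUN, lactate,
bicarbonate, pH, WBC, hemoglobin), an early-warning score (MEWS, computed
from the daily vital means with the standard 0–3 banding per component;
missing components score 0), interventions (ventilation flag, FiO₂, PEEP,
vasopressor flag, norepinephrine-equivalent dose, RRT flag), and trajectory
(current ICU day, short-horizon trend scores). Next-day exit is a per-day
Bernoulli event with probability `sigmoid(α + Σ_j β_j z_j)` where `z_j` are
the z-scored true (pre-missingness) feature values; the first exit day
terminates the stay (no ICU re-entry), and stays with no exit by the nominal
length are censored with all labels 0.

**Prevalence calibration.** The intercept α is set by Brent root-finding so
the *expected* realized patient-day prevalence — computed exactly from the
per-day survival products given the drawn features — equals the target
(default 0.76). At ≥ 10⁴ patient-days the realization concentrates well
within ±2 percentage points. A target that cannot be bracketed raises an
infeasible-spec error. This hazard formulation is a deliberate design
choice: a fixed-length-of-stay formulation cannot simultaneously deliver a
median stay near 2 days and a ~0.76 per-day exit prevalence (prevalence is
bounded by the reciprocal of the mean stay when exits end stays), so the
nominal stay law acts as a censoring cap and prevalence — the quantity every
downstream stage depends on — takes priority. Realized stays are
correspondingly short (median 1 labeled day at default settings).

**Destinations.** Exit days are labeled `floor` with probability
`floor_fraction` (default 0.77) else `death_or_home`, independent of
features given exit; no destination model is claimed.

**Missingness.** Injected per feature after outcome generation, MCAR by
default at the manifest fractions (systolic-BP SD 45.8%, systolic-BP
min/mean 40%, PEEP 17.9%, FiO₂ 14.1%, core vitals < 1%, labs 6–27%). An
optional `mnar_logit_shift` adds outcome-dependent missingness for
robustness experiments. Absent values are NaN; the observed mask is exactly
the non-NaN pattern.

**Default risk coefficients** encode clinical direction (instability —
MEWS, lactate, vasopressors, ventilation — lowers exit probability;
stability and accumulating ICU days raise it) at a scale giving latent-risk
ROC AUC ≈ 0.85, i.e. moderate discrimination for downstream classifiers.
The true per-day linear predictor is kept in the table under an `oracle_`
prefix (excluded from modeling) so tests can compare fitted models to the
generative optimum.

**What the generator does not emulate:** within-day physiologic time series
(only daily summaries exist), cross-feature correlation beyond the shared
MEWS dependence on vitals, day-to-day autocorrelation of features within an
admission, informative missingness (unless switched on), re-admissions, and
admission-level case-mix heterogeneity. Passing tests therefore establish
that the *pipeline machinery* is correct under the stated statistical
structure, not that any particular model family will achieve a particular
AUC on real ICU data.

## Day building

Forward filling carries the most recent prior observation forward strictly
within an admission (leading absences remain absent). Features never
observed during an admission are median-imputed with medians computed from
the training partition only; features whose training missingness exceeds
60% (measured on the post-fill training table the imputer actually faces)
are dropped from every partition. Splits are performed at the admission
level — 81/9/10 train/test/holdout by admission count with largest-remainder
rounding — and 10 stratified CV folds are built within train, stratified on
the admission-level indicator "ever exits to the floor" (the stratum choice
is ours; any admission-level outcome summary would serve). Rows with an
undefined next-day outcome (possible on user data) are dropped and counted;
admissions longer than a configurable 60 labeled days are excluded as
implausible durations. Leakage is checked by a mutation oracle: perturbing
raw data of day D+k must leave every built feature on days ≤ D unchanged.

## Models

Three families behind one interface: L2-regularized logistic regression
(with standardization), random forest, and gradient-boosted trees. Grids
are deliberately small — C ∈ {0.1, 1, 10}; tree depth {8, ∞} at 200 trees;
boosting depth {2, 4} at 200 rounds, learning rate 0.1 — because at
patient-day scale these are the axes that move validation AUC. Selection is
by mean CV ROC AUC over the admission-grouped folds, ties to the earlier
grid entry, refit on the full training partition. No class reweighting or
resampling anywhere: the decision-curve stage consumes absolute risks, and
reweighting would distort calibration. Importance is family-appropriate:
|coefficient| on standardized inputs, impurity reduction, split gain.

## Evaluation

ROC AUC and PR AUC (step-wise average precision, not trapezoidal
interpolation), Brier score, F1 at a fixed 0.5 threshold, and logistic
recalibration: a GLM of the outcome on logit(p) with probabilities clipped
to [10⁻⁶, 1−10⁻⁶]. Intercept 0 / slope 1 indicates perfect calibration;
slope < 1 means overconfident (too-extreme) predictions. Degenerate inputs
(constant predictions, single-class outcomes, non-convergence) raise rather
than defaulting. Reliability tables use 20 equal-width bins whose
count-weighted observed rates reproduce the overall prevalence exactly.

## Decision curve analysis

Net benefit `NB(t) = TP/N − (FP/N)·w(t)` with `w(t) = t/(1−t)` is computed
over a default grid t = 0.01…0.99 (step 0.01) for four strategies: the
model (binarized at `p ≥ t`, ties flagged), review-all, review-none (≡ 0),
and a physiologic-stability heuristic (daily HR summary < 100 bpm, RR
summary < 28/min, no vasopressor that day). The daily *mean* is the default
vital summary because the feature set carries min/mean/SD; the columns are
configurable, and the heuristic is evaluated on raw (pre-fill) daily values
with any missing component leaving the day unflagged, so imputation cannot
inflate the baseline's sensitivity. The curve also reports flagged
fraction and TP/FP per 1,000 patient-days. The positive class for DCA is
any next-day exit by default, with an ICU-to-floor-only option
(`dca_outcome: floor_only`), since either reading is defensible for a
recruitment use case.

## Operations model

Deterministic expected-value accounting (fractional daily counts, no
queueing). Confusion counts at each threshold become rates per 100
patient-days, scaled by the census (default 30 patient-days/day):

- flagged/day = (TP₁₀₀ + FP₁₀₀)·census/100; review minutes = flagged/day × 7
- eligible/day = TP/day × eligibility (0.10); consent minutes = eligible/day × 60
- enrollments/day = eligible/day × consent rate (0.60)
- missed-eligible/day = FN/day × eligibility — the only definition
  consistent with "missed eligible transfers" given day-level accounting
- feasible ⇔ total minutes ≤ 480 and flagged/day ≤ review capacity (= census)
- net value/day = enrollments × V_enroll − missed × C_miss; **V_enroll and
  C_miss have no defaults** — no defensible generic values exist, so net
  value is only computed when a user supplies both
- days-to-target = 300 / enrollments per day (∞ at zero yield)

The 7-minute review time is the default because it is the value consistent
with the workflow's own arithmetic (a fully-flagged 30-bed census costing
~210 minutes); 15 minutes is accepted via configuration for more
conservative screening assumptions. The optimizer maximizes net value when
the value parameters are set, otherwise enrollments/day (in an
eligibility-limited setting, missed eligible patients dominate the
trade-off), with ties broken toward lower review minutes then lower
threshold, so results are deterministic. A sensitivity sweep evaluates the
optimum over a Cartesian grid of workflow parameters.

## Orchestration and determinism

All randomness fans out from one top-level seed via fixed affine offsets
(cohort, split, fit), each kept below 2³¹. Rerunning an identical
configuration reproduces every deterministic artifact byte for byte; this is
asserted end to end in the test suite. Stages serialize to plain CSV/JSON/
YAML so each CLI subcommand can re-run in isolation from the previous
stage's output and reproduce the in-pipeline result exactly.

## Numerical choices and problem sizes

- Hazards clipped to [10⁻¹², 1−10⁻¹²] inside the prevalence calibration;
  Brent tolerance 10⁻¹⁰ on the intercept.
- Logit clipping ε = 10⁻⁶ in recalibration.
- Binarization `p ≥ t`; split rounding by largest remainder; CV-score ties
  to the earlier grid entry.
- Test-suite problem sizes: structural checks run on 400–10,000-admission
  cohorts; signal-recovery checks fit on 5,000-admission cohorts
  (~6,500 patient-days) and, for the null case, score an independent cohort
  large enough that the null-AUC standard error (~0.006–0.009) sits well
  inside the ±0.02 acceptance band; calibration self-consistency uses
  n = 50,000 simulated prediction pairs.

## Known limitations

Feature independence across days means trajectory features carry less
information than in real data; the heuristic baseline's operating point is
sensitive to which daily summary it screens; calibration of tree ensembles
on small test partitions is noisy (visible as recalibration slopes far from
1 in small demonstration runs); and all operational conclusions are
expected-value statements — day-to-day variance in workload is out of scope
by design.
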