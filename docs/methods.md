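# Methods

## The excretion model and what it estimates

Scaled total (fecal + urinary) mineral excretion of a balance-trial
treatment mean is modelled as

    Y_ij = β₁ · exp(β₂ · x_ij) + u_j + e_ij,

with x the scaled intake (g/kg BW^0.75/d), u_j ~ N(0, σ²_study) a random
balance-trial intercept and e_ij ~ N(0, σ²_e / w_ij). β₁ (g/kg BW^0.75/d)
is the curve's value at zero intake and estimates endogenous fecal +
urinary loss, i.e. the net maintenance requirement per unit metabolic body
weight; β₂ (per g/kg BW^0.75/d) is a curvature statistic without direct
nutritional meaning — the exponential shape lets excretion accelerate at
high intakes, where homeostatic down-regulation of absorption dumps the
surplus.

Because the random effect enters additively, each study's marginal
distribution is multivariate Gaussian with covariance
σ²_study·11′ + diag(σ²_e/w); the marginal likelihood is evaluated exactly
through rank-one Woodbury identities rather than by numerical integration.
An adaptive Gauss–Hermite evaluation (recentred at each study's posterior
mode, rescaled by its posterior SD) is retained as an independent oracle;
the two agree to quadrature accuracy (≤ 1e-6 relative, tested at 40 nodes).

### Weights

Each observation is weighted by the normalized inverse SEM of fecal
excretion: w₁ = 1/SEM, weight = w₁ / mean(w₁), computed separately for
studies analysed with fixed- and mixed-effects models (records with an
unknown model type are pooled with "mixed", the conservative group since
mixed-model SEMs run higher). SEMs below 0.35 × group-mean SEM are raised
to that floor so extremely small SEMs cannot dominate; missing SEMs are
imputed with the group mean of reported SEMs; a reported SED is first
converted with SEM = SED/2 (a `sqrt2` divisor is selectable for the
conventional equal-replication identity). The normalizer is applied after
trimming and imputation, which makes the group mean weight exactly 1 — a
tested invariant. Weights act as residual-precision scalers
(Var(e) = σ²_e/w), the standard meta-regression convention; rescaling all
weights by a constant leaves the fit unchanged.

### Fitting, outliers, heterogeneity

Starting values: β₁ from the 10th percentile of the response, β₂ from a
log-linear regression, expanded into a 5-point multi-start grid on β₂
(×0.25…×4). Optimization is L-BFGS-B over (β₁, β₂, log σ²_study, log σ²_e)
with a Nelder–Mead polish when the line search terminates abnormally; a
residual variance driven to its floor is treated as a valid degenerate
(perfect-fit) solution. σ²_study at its boundary is reported as 0 with a
flag, not an error. Standard errors come from the numeric Hessian at the
optimum (dropping the boundary coordinate when flagged); Wald p-values use
a t reference with n_studies − 1 df.

Outlier screening removes observations with conditional studentized
residuals outside ±2 — the residual minus the empirical BLUP of its study
intercept, divided by its exact conditional SD (Var = d_i − σ²_study/(1 +
σ²_study·Σ1/d)) — then refits, iterating to convergence (max 10 passes; a
single-pass mode is available for sensitivity). The loop aborts if it would
discard more than half the records. Marginal (population-level) residuals
are not used for screening because between-study spread would then mask
within-study outliers.

Between-study heterogeneity is reported as √σ²_study as a percentage of the
mean response: < 25% low, 25–50% moderate, > 50% high.

### Interaction tests

Stability of the curve across production levels is probed by comparing the
common-curve model against group-specific intercepts (β₁_g, shared β₂) and
group-specific curvatures (shared β₁, β₂_g) over milk-yield strata
[0,20], (20,30], (30,40], (40,∞) kg/d (half-open intervals resolve the
overlapping conventional labels; strata with fewer than two studies merge
downward). The likelihood-ratio statistic is referred to an F(q,
n_studies − G) distribution (LR/q against F) rather than χ²_q: the group
contrasts are effectively between-study contrasts, and with realistic study
counts the χ² reference is visibly anticonservative (≈8% size at a nominal
5% with 40 studies in our null simulations, against ≈5.5% for the F form).

The random-study and study × intake variance components are tested on the
linear mixed model of excretion on intake via boundary likelihood-ratio
tests (0.5·χ²₁ mixture), comparing no-random → random intercept → random
intercept + slope; the rank-two marginal covariance is evaluated with
vectorized 2×2 Woodbury algebra and is itself oracle-tested against dense
multivariate-normal densities.

## Metabolizable coefficient

MC = (intake − fecal − urinary + endogenous)/intake per treatment mean.
The endogenous term defaults to β₁ × BW^0.75 — the intercept definition of
maintenance, consistent with the factorial stack; a `curve` mode using the
full exponential prediction at the record's intake is exposed because the
choice is a genuine modelling fork (the intercept mode is the default since
maintenance is defined as the intercept). With zero urinary excretion the
formula reduces exactly to the classical true absorption coefficient.

Values outside [0, 1] are flagged but retained: truncation would bias the
mean, and the studentized-residual screen removes genuinely discordant
records. The overall MC is the intercept of a weighted random-study-
intercept model (not a raw mean), so studies contributing many treatment
means do not dominate; its SE comes from the same fit. Diet covariates
(forage, CP, EE, NDF, starch) are screened one at a time with a weighted
linear mixed model MC ~ covariate + random study; the slope's Wald t uses
n_studies − 2 df.

## Cross-validated evaluation

Studies are shuffled (seeded) and dealt round-robin into 5 folds, so no
study is split across folds and fold sizes differ by at most one study.
Each training split reruns the full outlier-screened fit; held-out records
are predicted at the population level (random effect zero — forced by
independence) and are never themselves screened. Metrics use population
moments: r, v = sd_p/sd_o, u = (mean_p − mean_o)/√(sd_o·sd_p),
C_b = 2/(v + 1/v + u²), CCC = r·C_b, RMSPE% = 100·RMSE/mean(obs), plus the
MSEP decomposition (mean bias² + slope bias + random) and t-tests of
intercept = 0 / slope = 1 in the observed-on-predicted regression. Breed
milk concentrations are compared by non-overlap of t-based 95% CIs.

## The synthetic-data generator

The generator draws datasets from exactly the statistical structure the
fitter assumes, so downstream stages can be tested against known truth:

* curve coefficients default to β₁ = 0.1352, β₂ = 1.4010 (P) and
  β₁ = 0.3604, β₂ = 0.5925 (Ca);
* scaled intake is uniform over the observed ranges (0.18–1.48 P,
  0.38–3.68 Ca g/kg BW^0.75/d) — uniform maximizes design spread for
  identifiability; real compilations are right-skewed toward lower intakes,
  so simulated mean responses sit somewhat above the published means;
* σ_study = 0.09 (P) / 0.30 (Ca) and σ_resid = 0.07 (P) / 0.18 (Ca),
  chosen so the implied heterogeneity index and prediction scatter are of
  the magnitude reported for the published compilations;
* default sizes 39 studies (P) / 23 (Ca) with 3–4 treatments each;
* simulated excretion below 0.01 g/kg BW^0.75/d is floored there (mass
  flows must stay positive) and the truncation count is reported;
* total excretion splits into fecal/urinary at ≈0.98 (P) / 0.97 (Ca) fecal
  share, clipped to the observed ranges;
* fecal SEMs are lognormal matched to the published moments (mean 2.78,
  SD 1.57 g/d for P; 8.28, 6.60 for Ca), ~5% missing, ~5% of fixed-model
  studies reporting SED only; fixed/mixed labels are assigned 50/50 at the
  study level (the published split is not reported);
* body weight, milk yield, DMI and diet covariates are truncated-normal
  draws at the published descriptive statistics; diet covariates are
  null-effect by construction; breed-specific milk concentrations default
  to 0.90/1.00 g P/kg and 1.18/1.38 g Ca/kg (Holstein/Jersey) with SDs
  back-calculated from the published CIs;
* a single integer seed expands into independent substreams per study;
  identical seeds give byte-identical datasets.

What the generator does **not** emulate: digesta kinetics, saliva
recycling, bone mobilization, correlated diet covariates, non-Gaussian
study effects, or the real compilations' uneven study sizes and intake
clustering. Passing tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
every feature of real balance-trial data.

## Requirement calculators

Proposed system: NR_M = 0.1352 (P) / 0.3604 (Ca) × BW^0.75 g/d; NR_L =
milk concentration × milk yield with breed defaults 0.90/1.00 (P) and
1.18/1.38 (Ca) g/kg, overridable by measured values; DIR = (NR_M + NR_L)/MC
with MC 0.69 (P) / 0.65 (Ca); dietary concentration = DIR/DMI. Comparators
follow the published NASEM-2021 and NRC-2001 equations; where those systems
give separate forage and concentrate absorption coefficients, the diet AC
is the linear mass-fraction blend over the forage fraction — the one
interpretive step in the comparators, adopted as standard factorial
practice. DMI is always user input. The preset comparison grid uses milk
yields 10–50 kg/d with forage fractions 0.80/0.60/0.50/0.45/0.40, BW
interpolated linearly 500→700 kg and DMI 20.7→27.0 kg/d between the
anchor scenarios; reported precision is g/d to integers and g/kg DM to one
decimal.

## Test problem sizes and numerical choices

The statistical acceptance checks run at the default study conditions:
parameter recovery over 200 replicate datasets per mineral (median relative
bias of β̂₁ below 10%, Wald-CI coverage within [90%, 98%]); null
calibration of the milk-yield interaction test (40 studies × 4 treatments)
and of the covariate screen (39 studies, weight-consistent residuals) over
500 replicates each, with the rejection rate required inside 0.05 ± 3
binomial SEs; and a 20-replicate full-pipeline run per mineral whose
replicate-mean intercept, overall MC and CV RMSPE must sit within ±0.02,
±0.02 and ±3 percentage points of the generating truth — the same
tolerances a replication on the real compilation would be held to.

Convergence uses L-BFGS-B defaults tightened to ftol 1e-12 / gtol 1e-8;
log-variances are bounded in [−25, 6]; exponents are clipped at ±50 to
avoid overflow during multi-start exploration. Ties and degenerate inputs:
single-study inputs and constant covariates are rejected or reported NA
rather than silently fitted; empty milk-yield strata merge downward with a
log line.

## Known limitations

* The maintenance estimate is an extrapolation of the fitted curve to zero
  intake; its SE is design-sensitive (leverage of the low-intake range).
* Fixed overall MC values ignore source- and physiology-specific
  absorption differences; measured diet MCs should replace them when known.
* The iterative ±2 studentized-residual rule truncates the residual
  distribution and can bias variance components slightly downward; the
  single-pass mode bounds that effect.
* Requirement coverage is maintenance + lactation only — no gestation,
  growth, or body-reserve terms.
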