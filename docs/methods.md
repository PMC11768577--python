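# Methods

This note documents the models, parameter conventions, numerical
choices, and limitations of `salbupop`. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## 1. Virtual population

Each cohort group is a (race, health-status) cell with its own size,
male fraction and BMI-class mix. The packaged default reproduces the
40-subject study composition: three healthy ethnic groups (American,
Asian, Chinese; 10 each) plus an American Child–Pugh A cirrhosis group
(10), male fraction 0.6 in every group (24 M / 16 F overall), and
BMI-class mixes placing 4 subjects in the obese class (BMI ≥ 30).
`health_status = obese` is derived from BMI in non-cirrhosis groups.

* **Age** — truncated normal N(40, 18²) on [5, 65] years. A uniform
  draw over the range would center at 35 y with SD 17.3; the reported
  cohort moments (mean ≈ 39.5, SD ≈ 18.4) are matched better by the
  truncated normal, so it is the default.
* **Height** — piecewise-linear reference curves (110 cm at age 5 to the
  adult value at age 20, flat afterwards; male 176 cm / female 163 cm)
  with additive race offsets (Asian −4 cm, Chinese −3 cm) and an
  individual N(0, 5²) cm deviation.
* **Weight** — BMI × (height/100)², BMI drawn uniformly within the
  group-assigned class (normal 18.5–24.9, overweight 25–29.9, obese
  30–40). BSA uses Du Bois–Du Bois:
  `BSA = 0.007184 · W^0.425 · H^0.725`.
* **CYP2D6 / CYP2C19 expression** — lognormal covariates matched to the
  reported mean ± SD (1.90 ± 1.60 and 1.30 ± 1.50 "%"). The reported
  denominator is undefined, so they are carried as opaque covariates and
  do not modify clearance by default.
* **Reproducibility** — each subject draws from an independent RNG
  substream keyed by `(seed, subject_index)`, so cohorts are bitwise
  reproducible and extensible without reshuffling earlier subjects.

### Physiology scaling

Reference-adult organ-volume fractions (of body weight, density
1 kg/L) and regional blood-flow fractions (of cardiac output) are
packaged for the 13 tissues plus venous/arterial blood; they are rounded
composites of standard reference-man compilations (ICRP 89 and common
PBPK physiology tables). Per subject: volumes ∝ body weight, cardiac
output = 336 L/h × BSA / 1.89 m², flows ∝ cardiac output. Obesity
multiplies the adipose fraction by 1.5 (compensated from muscle and
rest-of-body); Child–Pugh A cirrhosis multiplies hepatic arterial flow
by 0.85 and hepatic intrinsic clearance by 0.8 (both configurable).
The gut wall is not an explicit compartment; its arterial share is
carried by the liver-arterial fraction so total hepatic inflow is
≈ 25.5% of cardiac output.

## 2. PBPK model

Perfusion-limited whole-body model: venous and arterial blood pools,
lung in series carrying the full cardiac output, 12 tissues in parallel.
Tissue venous-outflow blood concentration is `C_t · R_bp / Kp_t`. Mass
balance is exact by construction; the integrator is LSODA at
rtol 1e-8 / atol 1e-10 with doses applied as state jumps between
integration segments.

* **Absorption (CAT)** — stomach, seven small-intestine segments, colon;
  first-order transit (gastric emptying 4 h⁻¹ fasted, total SI transit
  3.32 h over 7 segments, colon residence 13.5 h); segmental absorption
  `k_a,i = 2 P_eff / R_i` (R = 1.5 cm SI, 2.5 cm colon). Absorbed drug
  enters the liver inlet (portal routing). Salbutamol's solubility
  (14.47 mg/mL) is four orders of magnitude above the 4 mg dose scale,
  so dissolution is treated as instantaneous.
* **Hepatic elimination** — well-stirred: the intrinsic blood clearance
  is calibrated once on the reference adult so that the linear-regime
  systemic plasma clearance equals the compound's hepatic plasma
  clearance (38.06 L/h), then scaled to each subject by liver volume and
  the cirrhosis multiplier. Blood/plasma conversion uses R_bp = 1.108.
* **Renal elimination** — first-order on arterial plasma at the kidney,
  16.32 L/h (plasma).
* **Kp set** — the packaged 12 published tissue values; the single bone
  value (2.27) is applied to both red and yellow marrow.
* **Units** — internal: µg, L, h, µg/L plasma; event-record I/O uses
  µg/mL (DV) and mg (AMT).

The simulated reference adult reproduces the published single-dose
validation within the < 2-fold acceptance rule; the acceptance suite
recomputes this (AUC∞ fold-error, Cmax, t½) at run time.

## 3. Population model

Two-compartment disposition with linear elimination, first-order
absorption (`ka`) preceded by a transit chain implemented in closed
gamma form (Savić-type):

    rate(t) = F · D · Ktr (Ktr t)^n e^(−Ktr t) / Γ(n+1),  n = Ktr·Mtt − 1,

valid for non-integer transit numbers and integrating to the
bioavailable dose. Apparent parameterization throughout (bioavailability
absorbed into Cl/F, V/F; `bio_f` fixed at 1), since oral data alone
cannot separate F.

* **Interindividual variability** — additive normal,
  `p_i = θ_p + Σ β·(cov − ref) + Σ β·1{category} + η_p`,
  η ~ N(0, diag ω²). Continuous covariates are centered at the dataset
  median; reference categories male / american / healthy. Parameters
  that fall non-positive are rejection-resampled in simulation and
  clipped at 1e-6 (flagged) during estimation.
* **Residual error** — combined-2, `sd = √(a² + b² f²)` on the µg/mL DV
  scale (a combined-1 form `a + b·f` is available via config).
* **Prediction paths** — the reference path integrates the three-state
  ODE with LSODA (rtol 1e-8, max step bounded by the transit timescale);
  the fast path used inside estimation/simulation/diagnostics convolves
  exact per-interval transit masses (regularized incomplete-gamma
  differences, robust for −1 < n < 0) with the analytic three-exponential
  disposition impulse response on a uniform grid (default dt = 0.0625 h;
  second-order accurate, ~1e-3 worst-case relative error at the earliest
  low-concentration samples, cross-checked against the ODE path in the
  test suite). Dataset simulation and estimation share the same grid so
  that discretization cannot masquerade as residual error at the very
  small residual scales of this compound (b ≈ 0.15%).

## 4. Estimation (SAEM)

Two phases: exploration (`k1`, step size 1, simulated annealing — ω² and
the error constants may shrink at most 10% per iteration) and smoothing
(`k2`, step size `(k − k1)^−0.7`). E-step kernels per iteration:

1. independence proposal from the prior N(0, ω²);
2. random-walk proposals shaped by a per-subject Laplace conditional
   covariance (Gauss–Newton curvature of the weighted residuals plus the
   prior precision, refreshed every 25 iterations) with per-subject
   scale adapted toward 0.3–0.4 acceptance;
3. an adaptive Gaussian independence kernel centered on slow-moving
   conditional moments;
4. a component-wise random walk.

The chain state is the individual parameter vector φ_i = μ_i + η_i and
is held invariant across M-step updates of μ (η is re-based), so
subjects whose proposals are rejected do not drift with the population
mean. M-step: per-parameter least squares of the stochastic-approximation
averages on the covariate design (θ and β jointly); ω² from the SA
second moments; the error constants (a, b) are re-optimized on the
current complete-data residuals (Nelder–Mead on log(a), log(b)) and
stochastically smoothed — the combined error model has no closed-form
sufficient statistics. Subjects are processed in sorted-ID order and all
draws are arrays over that order, so estimates are invariant to dataset
row permutations and bitwise reproducible under a fixed seed.

**Initialization.** `initial_estimates` provides NCA heuristics
(Cl/F = dose/AUC, V from Cl·t½/ln 2, Mtt from median tmax, ka = 1,
Q = Cl/3, V2 = V1) refined by a naive-pooled weighted least-squares fit
of the mean profile. For information-rich datasets,
`individual_fit_init` fits every subject's curve by bounded weighted
least squares (alternating with error-model updates) and assembles
θ = median, ω = SD, (a, b) from pooled residuals, and the starting η per
subject. The initialization fits are constrained to a physiological box
(notably Q ≤ 3·Cl): without it, the weakly identified distribution
parameters collapse into a degenerate one-compartment limit
(Q → ∞). The box constrains only initialization, never SAEM.

**Marginal likelihood** — per-subject importance sampling with a
location-scale t(4) proposal centered at the conditional mean with the
conditional SD (from the chain tail); exact when no random effects are
present. Nested-model −2LL differences in the covariate search share one
IS seed so Monte-Carlo noise largely cancels.

**BICc** — `−2LL + P_subj·log N + P_obs·log n_obs`, with θ, β, ω counted
as subject-level and the residual-error constants as observation-level.

**Standard errors** — numeric Hessian of the smoothed IS −2LL (fixed IS
seed; central differences on the diagonal), RSE = 100·SE/|estimate|;
negative-curvature directions are reported as missing. An `include`
argument computes a parameter-block Hessian, which is also how Wald
tests for covariate coefficients are obtained (β block at fixed
remaining parameters).

## 5. Covariate search

EBE-based screening (Pearson and Spearman for continuous, one-way ANOVA
for categorical; a pair is flagged when the smallest p-value is below
0.05 — the forward likelihood-ratio test is the real gate), VIF > 15
collinearity filtering (the offender with the least significant
screening p is dropped), then forward selection (accept if −2LL drops by
more than χ²₀.₀₅,₁ = 3.84) and backward elimination (remove unless −2LL
rises by at least χ²₀.₀₀₁,₁ = 10.83), candidates ordered by a
configurable clinical-priority list then screening p-value. The
COSSAC-like variant ranks relationships by correlation tests on
conditional-distribution samples (chain-tail means, not EBEs) and
additionally requires a BICc improvement; it omits the proprietary
scheduling heuristics of the original implementation.

## 6. Diagnostics

* **IWRES** = (y − f_i)/sd(f_i) with f_i from MAP empirical Bayes
  estimates (prior-scaled L-BFGS-B, multi-start).
* **NPDE** — n_sim simulated replicates at the observed design;
  per-subject decorrelation by the empirical simulated mean and Cholesky
  factor; rank-based discrepancies (seeded uniform jitter on ties)
  mapped through Φ⁻¹. Singular covariances fall back to the marginal
  discrepancy and are flagged. Requires n_sim ≥ 50.
* **VPC** — observed 10/50/90th percentiles per time-quantile bin
  (default 8 bins, bins under 3 observations merged) against the 5th–95th
  percentile band of the same statistic across replicates; an outlier is
  an observed percentile outside its band.
* **Outlier proportion** — fraction of observations outside the 90%
  individual prediction interval, |y − f_i| > z₀.₉₅·sd(f_i).

## 7. Study-condition choices and problem sizes

* Regimen: 4 mg oral q6h, 4 doses over 24 h (a q4h variant is one
  config switch away). Dataset: 40 subjects × 21 samples = 840
  observation rows.
* Sampling schedule: a standard rich design — dense absorption-phase
  samples after the first dose (0.25–6 h), mid-interval coverage, and
  troughs around later doses. A uniform 21-point grid was examined and
  rejected: under it the marginal likelihood is nearly flat between the
  two-compartment generating model and a one-compartment surrogate with
  degenerate ka, which defeats absorption-parameter estimation; the
  dense-early design is also what a pharmacometric study of an oral
  immediate-release drug would use.
* Default SAEM budgets in the pipeline and acceptance script:
  k1 = 200, k2 = 100, 500–1000 IS draws; property tests use reduced
  replicate counts and iteration budgets sized to their statistical
  claims.

## 8. What the synthetic data do and do not show

The generator emulates the study conditions (cohort composition, dosing,
sampling, the published final-model parameter set) but not features of
real data: no dropout or missingness, no BLQ censoring at analysis time
(values below LLOQ are flagged, not dropped), noiseless extraction of
PBPK profiles (the popPK residual error then absorbs model discrepancy
rather than assay noise), and normal (not truncated) IIV is assumed at
estimation time while simulation rejection-resamples non-positive
parameters — for parameters whose ω is a large fraction of θ (Ktr), the
realized population mean therefore exceeds the nominal θ.

Passing tests demonstrate internal consistency of the workflow on data
generated by its own model family, not predictive validity for real
patients.

## 9. Known limitations

* **Identifiability of disposition under the study design.** With 24 h
  of q6h dosing and no washout, a single subject's curve cannot separate
  clearance from deep peripheral distribution (fits with Cl ≈ 43 L/h and
  V2 ≈ 5·10⁴ L reproduce the same curve as Cl ≈ 140, V2 ≈ 130 to within
  the residual error), and the population likelihood is correspondingly
  flat in (V1, Q, V2) and most ω directions. The absorption-side
  parameters (Mtt, Ktr, ka) and total Cl/F are identified; RSEs for the
  flat directions are reported as missing or very large, which mirrors
  the very large published uncertainties for Cl and V1.
* The PBPK gut model is an open CAT substitute for a proprietary
  absorption engine; only approximate (< 2-fold) agreement with the
  published validation values is claimed, per the 2-fold acceptance rule.
* No enzyme-level metabolism, transporters, food effects, dissolution
  dynamics, correlated random effects, inter-occasion variability, or
  BLQ likelihood (see module non-goals).
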