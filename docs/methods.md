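# Methods

## Scope and intent

`physiopop` simulates the physiology of healthy adult (16–65 yr) UK and
US populations — by gender and ethnicity — as a hierarchical probability
model: first the anthropometric "shell" (age, height, body mass, BMI,
cardiac output), then the organs within it (15 organ/tissue masses and
blood flows), with exact mass and flow balance.  The model doubles as an
explicit prior distribution for Bayesian inverse problems built around
PBPK models, which is why every distribution is a standard truncated
normal or log-normal with closed-form parameters rather than an
algorithm buried in code.  Kinetics, metabolism, and inference itself
are out of scope: the package produces physiologies, not dose estimates.

## Phase 1: the anthropometric shell

* **Age** is continuous uniform on [16, 65] by default.  A census-grade
  piecewise age distribution would add precision the downstream use
  cannot exploit; the uniform is an adequate approximation for a
  working-age population.  Exact ages and age intervals replace the
  default.
* **Height and ln body mass** are bivariate normal.  Means are quadratic
  in age, with coefficients specific to each of the 12 sub-populations;
  the residual correlation ρ (0.28–0.46) is essential — without it the
  joint distribution of stature and mass is far too diffuse.  Sampling
  uses the marginal/conditional factorisation of the bivariate normal.
  Each draw is truncated: default bounds are location ± 3σ, overridden
  by any user-supplied interval (body-mass intervals mapped to the log
  scale).  The variable with the smaller standardised width
  σ⁻¹(upper − lower) is drawn first (height on ties), so the tighter
  constraint anchors the conditional; with no constraints the joint law
  is order-invariant (property-tested by a two-sample KS check).
  Exact values bypass sampling entirely and pass through on their
  natural scale.
* **BMI filter.**  The population is restricted to BMI ∈ [17.5, 32.5]
  kg·m⁻² by rejection of (height, mass) pairs, keeping the age; this
  reproduces post-hoc truncation of the population without distorting
  the conditional structure.  The cap is 10,000 rejection rounds, after
  which a `ConstraintError` is raised rather than silently relaxing the
  window; exact height+mass pairs violating the window fail immediately.
* **Cardiac output** (L·min⁻¹) regresses on height and age: males with
  a logistic maturation term α + h₁H + a₁A + a₂/(1 + e^(−a₃(A−18))),
  females with a cubic polynomial in age (females reach physical
  maturity earlier, so one functional form cannot serve both).  The
  normal residual (σ ≈ 0.09–0.11) is truncated below at zero — never
  binding in practice since locations are 5–7 L·min⁻¹.

## Phase 2: organs and tissues

Mass models per organ (locations in kg, or ln kg for the log-normal
organs lung, spleen, adipose, muscle):

| organ(s) | location form |
|---|---|
| lung, heart, kidneys, liver, pancreas, spleen, stomach, intestines | α + h₁H |
| brain | α + a₁A |
| sexual organs | α |
| skin | α + m₁BM + m₂BM² |
| bone (male) | α + h₁H + h₂H·(1 + e^(−a₁(A−18)))⁻¹ |
| bone (female) | α + a₁A + a₂A² + h₁H |
| adipose, muscle | α + a₁A + a₂A² + h₁H + b₁BMI (+ b₂BMI²) |

"Bone" denotes the total skeleton.  The male bone a₁ is the logistic
rate (yr⁻¹) of skeletal maturation, not an additive age slope.  The
muscle form admits a quadratic BMI term; no shipped population uses one
(b₂ = 0), and absent coefficients evaluate to zero.

* **Truncation.**  Every organ mass is truncated to its central 90%
  (location ± 1.6449σ, the 5th–95th percentile band) so single organs
  are never absurdly small or large.  Should a normal organ's 5th
  percentile be non-positive (it is not, for any shipped population, at
  in-range covariates) the lower bound is clamped at 10⁻⁴ kg with a
  warning.
* **Adipose–muscle coupling.**  ln(adipose) and ln(muscle) are drawn
  jointly with correlation ρ ∈ [−0.9, −0.86]: surplus body mass is
  predominantly fat *or* predominantly muscle.  The joint draw uses the
  same sequential scheme as phase 1 — adipose from its truncated
  marginal, muscle from the conditional given adipose, truncated to
  muscle's own marginal band.  Whether that 90% truncation should be
  marginal or joint is genuinely open; we chose the sequential-marginal
  reading for consistency with the phase-1 machinery, and the test suite
  pins the resulting post-truncation correlation against an
  independently coded rejection-sampling oracle of the same scheme.
* **Flows** are fractions of cardiac output, N(c₁, σ²) truncated at
  ±2σ (intra-individual flow variability is poorly characterised and
  the nominal SDs are generous, hence the tight truncation).  Fractions
  are gender-specific and shared across ethnicities and countries.  The
  fractions sum to ≈ 1.03 (male) / 1.02 (female) before balancing.
* **Balance.**  Flows are rescaled by the common factor
  CO / Σ flows, so they sum to cardiac output exactly.  Masses are
  balanced by rescaling *only* adipose and muscle by
  λ = (BM − Σ other masses)/(adipose + muscle): these two tissues carry
  almost all the variance, and rescaling every organ could push small
  organs below realistic sizes.  A single common λ is the
  minimal-intervention choice — it preserves the sampled adipose:muscle
  ratio and hence their correlation structure.  Rescaling may move
  adipose/muscle outside their 90% bands; that is accepted, since
  balancing happens after sampling by design.  Individuals with
  λ ∉ [0.2, 5] (including λ ≤ 0, i.e. the other organs already exceed
  body mass) are rejected and wholly resampled, with the count reported;
  after 1,000 fruitless rounds the simulation errors rather than emit a
  distorted population.  Under default settings rejections are
  essentially zero.
* After balancing, adipose+muscle account for roughly 50–80% of body
  mass across the default populations.

Organ masses and flows are conditionally independent given the phase-1
covariates (no direct mass–flow coupling); the only extra-covariate
dependence modelled is the adipose–muscle correlation.

## Aggregation, blood, and the sink update

Compartment lumping sums member organs' masses and flows; the default
scheme is rapidly perfused = {heart, lung, spleen, pancreas, sexual
organs} and slowly perfused = {skin, muscle}, fully configurable.  The
simulated organ masses include resident blood; `subtract_blood` removes
a whole-body blood mass (e.g. 4.1 kg) according to user-supplied
per-organ blood weight fractions, reporting the removed total as a
`blood` entry so mass is conserved.  There is deliberately no default
fraction table — reference blood-content values must be provided
explicitly.  `sink_rebalance` supports single-component MCMC updates:
after setting one organ's mass and flow, skeletal muscle (or a chosen
sink) absorbs the difference so totals stay exact; proposals the sink
cannot absorb raise an error for the caller to reject.  No closed-form
distribution is offered for aggregated compartments (a sum of normals
and log-normals has none); that approximation is application-specific
and out of scope.

## Literature priors and the plausibility screen

Two published prior styles are reproduced for comparison.  The
four-compartment specification (fat, slowly perfused, rapidly perfused,
liver) uses independent log-normals for every mass and flow, read as
LN(geometric mean, geometric SD) — the dispersion values near 2 are only
sensible as geometric SDs; cardiac output is the sum of the four flows.
The childbearing-age specification uses a bounded log-normal body
weight, bounded normal cardiac output (L/hr, converted to L/min), and
truncated-normal tissue fractions multiplied onto body weight / cardiac
output; its known gut/intestine double-counting is reproduced as
published, not corrected.  The screen builds absolute min/max bounds per
quantity from a 10,000-member population simulated by this package
(standing in for the original generator's output) and classifies a
sampled physiology as plausible iff every quantity is inside its bounds.
For the four-compartment prior, liver flow is compared against our liver
arterial flow as-is (no portal-vein summation); the screen's <1% result
is driven by several quantities at once and is insensitive to this
choice.

## Numerical choices

* Truncated-normal draws use inverse-CDF sampling (`scipy.stats.
  truncnorm.ppf`), one uniform per draw, in a fixed documented order
  (age, first anthropometry variable, second, cardiac output, then
  organ masses and flow fractions in the canonical organ order), so a
  seed fully determines the output.
* σ = 0 is honoured as the degenerate limit (draws equal locations),
  which enables closed-form oracle tests of the whole pipeline.
* A constraint interval lying beyond ±8σ of its marginal raises an
  error (no usable probability mass).
* Quantiles use linear interpolation between order statistics; at
  n = 10⁴ the quantile method is immaterial at reporting precision.
* The truncation constant is `norm.ppf(0.95)` ≈ 1.6449 exactly, not a
  rounded literal.
* Coefficients are stored as plain JSON, one file per sub-population,
  loaded with full validation; a checksum test freezes the transcription.
  The per-gender flow parameters are asserted equal across data files to
  within 10⁻⁴ (two source tables report the female skin flow SD at
  different precision, 0.0139 vs 0.014; both are kept as given).

## What the simulator does and does not establish

The generator's defaults (n = 10,000 per population in the reference
computations, BMI window [17.5, 32.5], the shipped coefficient tables)
are the reference study conditions, and the acceptance checks run at
that scale.  The model inherits the limitations of its sources: it
describes *healthy* adults 16–65 with BMI ≤ 32.5 — no children, elderly,
or obese physiologies (severe obesity would need a different muscle/skin
model and raised cardiac output); height is an imperfect proxy for
organ-bearing "size"; flow variability is nominal and tightly truncated
rather than measured; biochemical/metabolic variability is not modelled.
Passing tests demonstrate internal consistency (balance, truncation,
coefficient recovery, reproduction of the reference summary statistics),
not fidelity to any individual's physiology.
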