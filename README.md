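# physiopop

Virtual human physiology populations for PBPK modelling and reverse
dosimetry.

Physiologically based pharmacokinetic (PBPK) models need, for every
simulated person, a mutually consistent set of organ masses and regional
blood flows.  Describing each organ with an independent probability
distribution produces mostly impossible bodies — organs that outweigh
the person, flows that exceed cardiac output.  `physiopop` instead
simulates people hierarchically, the way population-generator software
does, but with a concise, fully explicit probability model that can also
serve as a prior distribution in Bayesian inverse problems
(dose reconstruction, QIVIVE).

## The model

For an adult (16–65 yr) of known country (UK/US), gender and ethnicity:

**Phase 1 — the "shell".**  Age A ~ U(16, 65) (or a known value or
interval).  Height and ln body mass are bivariate normal with
quadratic-in-age means,

    H       ~ N(α_H + a₁A + a₂A²,  σ_H²)
    ln BM   ~ N(α_B + b₁A + b₂A²,  σ_B²),   corr(H, ln BM) = ρ

sampled via the marginal/conditional factorisation
Y | X ~ N(μ_Y + (σ_Y/σ_X)ρ(X − μ_X), (1 − ρ²)σ_Y²), each draw truncated
to its constraint interval (default ±3σ).  Interval knowledge such as
"body mass between 75 and 80 kg" simply replaces the truncation bounds;
the variable with the smaller standardised interval width
σ⁻¹(upper − lower) is drawn first.  The population is restricted to
BMI ∈ [17.5, 32.5] by rejection.  Cardiac output follows a
gender-specific regression on age and height (logistic age term for
males, cubic for females) with normal residual.

**Phase 2 — the organs.**  Each of 15 organs/tissues (lung, brain,
heart, kidneys, liver, pancreas, spleen, stomach, small and large
intestine, sexual organs, skin, bone, adipose, skeletal muscle) gets a
mass from a normal — or, for lung, spleen, adipose and muscle, a
log-normal — distribution whose location is a tabulated function of age,
height, body mass and BMI, truncated to its central 90%.  The ln-masses
of adipose and muscle are drawn jointly with a strong negative
correlation (ρ ≈ −0.9): excess mass is fat *or* muscle, rarely both.
Flows are normal fractions of cardiac output truncated at ±2σ.  Balance
is then enforced exactly: flows are rescaled to sum to cardiac output,
and adipose+muscle are rescaled by a common factor so masses sum to body
mass.

All coefficients, for the 12 sub-populations, ship as auditable JSON
under `src/physiopop/data/`.

## Worked example

```python
from physiopop import (ContextualConstraints, DEFAULT_SCHEME,
                       simulate_population, summarize)

pop = simulate_population(
    ("US", "female", "Non-Black Hispanic"), 10_000,
    constraints=ContextualConstraints(age=16), seed=1)
table = summarize(pop, DEFAULT_SCHEME)
print(table.loc[["body_mass_kg", "cardiac_output_l_min", "mass_liver_kg",
                 "flow_liver_l_min", "flow_kidneys_l_min",
                 "flow_adipose_l_min", "flow_rapidly_perfused_l_min",
                 "flow_slowly_perfused_l_min"]].round(2))
```

prints

```
                             median   p2.5  p97.5
quantity
body_mass_kg                  58.14  43.07  81.02
cardiac_output_l_min           5.90   5.56   6.25
mass_liver_kg                  1.89   1.20   2.59
flow_liver_l_min               0.41   0.23   0.60
flow_kidneys_l_min             1.17   0.77   1.56
flow_adipose_l_min             0.53   0.31   0.76
flow_rapidly_perfused_l_min    0.68   0.49   0.88
flow_slowly_perfused_l_min     1.00   0.69   1.32
```

— 10,000 sixteen-year-old Hispanic women: median 58 kg, cardiac output
5.9 L/min, and every individual's 15 organ masses summing exactly to her
body mass (flows likewise to cardiac output).  The `rapidly_perfused`
compartment lumps heart, lung, spleen, pancreas and sexual organs;
`slowly_perfused` lumps skin and skeletal muscle.  Note the simulated
organ masses include their resident blood; `subtract_blood` removes a
whole-body blood mass given per-organ fractions.

The same is available from a shell:

```sh
physiopop simulate --country US --gender female --ethnicity Hispanic \
    --age 16 --n 10000 --seed 1 --out pop.csv
physiopop summarize --input pop.csv
physiopop compare --prior sohn --n 10000 --seed 1
physiopop validate-params
```

`compare` screens a broad literature prior (independent log-normals for
four lumped compartments) against the min/max envelope of a simulated
reference population: fewer than 1% of its draws are physiologically
plausible, which is the case for the hierarchical prior this package
implements.

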