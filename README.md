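# myoflux

Constraint-based modelling of skeletal-muscle energy metabolism under graded
exercise demand, for researchers studying how a muscle cell partitions ATP
production between carbohydrate oxidation and β-oxidation — and how that
balance breaks in diseases with secondary metabolic alterations such as
calpainopathy (limb-girdle muscular dystrophy R1).

## What it computes

The core is flux balance analysis (FBA): given a stoichiometric network with
matrix *S* and flux bounds, solve

```
max  c·v    subject to   S·v = 0,   lb ≤ v ≤ ub
```

with *c* selecting the ATP demand reaction, plus flux variability analysis
(FVA), the per-reaction min/max flux compatible with a near-optimal
objective. Fluxes are in μmol·gDW⁻¹·min⁻¹ and uptake is a negative exchange
flux. Degenerate optima are resolved parsimoniously (secondary minimisation
of Σ|v|), so reported distributions are solver-independent; FVA remains the
authoritative statement of variability.

On top of that LP core the package implements a four-stage pipeline:

1. **Uptake fitting** — at each exercise intensity (% of VO₂max) the O₂
   uptake and ATP output are fixed from experimental values; the glucose and
   fatty-acid uptakes that realise them are inferred by sweeping the glucose
   bound down from its FVA-maximal value until the carbohydrate share of ATP
   production, `Y_glc·|v_glc| / (Y_glc·|v_glc| + Y_fa·|v_fa|)`, matches the
   literature target for that intensity.
2. **Pathway accounting** — per-pathway fluxes and shares, either through
   representative enzymes (phosphoglycerate mutase for glycolysis,
   acetyl-CoA acyltransferase for β-oxidation, ...) or ATP-yield-weighted
   uptakes.
3. **Disease model** — published enzyme regulations (expression
   fold-changes, activity changes, qualitative warnings) become
   multiplicative correction factors; each regulated reaction is capped at
   `factor × (maximal control flux across intensities)`. An activity change
   of +133 % maps to factor 2.33; a fold-change maps to itself; a warning
   caps at the control maximum.
4. **Compensation** — intensity sweeps of the disease network under the
   control nutrient caps, then lifting uptake bounds nutrient-set by
   nutrient-set, scoring recovery by the RMSE between disease and control
   ATP curves.

Everything runs against either a genome-scale SBML model (e.g. the MitoCore
mitochondrial network, imported through COBRApy) or the bundled **mini-muscle**
network: a lumped muscle-cell energy system whose yields have closed forms
(glucose 32 ATP / 6 O₂ per unit, palmitate-like fatty acid 106 ATP / 23 O₂,
anaerobic glucose 2 ATP + 2 lactate), making every pipeline stage testable
against exact oracles.

## Worked example

```python
from myoflux import MuscleEnergyModel, RegulationRecord
from myoflux.synth import MiniMuscleConfig, build_mini_muscle, default_scenarios

cfg = MiniMuscleConfig()
net = build_mini_muscle(cfg)
scenarios = [s for s, _ in default_scenarios(cfg)]
model = MuscleEnergyModel(net, scenarios, "EX_glc", "EX_fa", "EX_o2")
results = model.fit()
print(results.summary())
```

prints

```
Muscle energy metabolism — uptake fit
======================================================
network: mini-muscle (20 reactions)
fuel yields (ATP per unit uptake): EX_glc=32, EX_fa=106
sweep step: 0.01 μmol·gDW⁻¹·min⁻¹; share tolerance: 0.02

 percent_vo2max  o2_flux  atp_flux  glucose_uptake  fa_uptake  achieved_cho_share
             25   -2.996      14.6         -0.1825   -0.08264                 0.4
             65   -7.386     36.52         -0.5706    -0.1723                 0.5
             85    -10.6      54.8           -1.37    -0.1034                 0.8
            100   -14.06        75          -2.344         -0                   1
```

— at rest (25 % VO₂max) the cell covers 40 % of its 14.6 μmol·gDW⁻¹·min⁻¹
ATP demand from glucose and 60 % from fat; at maximal intensity it burns
glucose only. Building a disease variant and scanning compensations:

```python
records = [
    RegulationRecord("BETA_OX",    "rnaseq",  0.5),    # β-oxidation halved
    RegulationRecord("ETC_NADH",   "rnaseq",  0.6),    # respiratory NADH oxidation down
    RegulationRecord("TCA",        "qualitative_warning", float("nan")),
    RegulationRecord("GLYCOLYSIS", "activity", 133.0), # aldolase-like up-regulation
]
disease_net, bounds, _ = results.build_disease_model(records)
report = results.compensation_scan(
    disease_net,
    [{"EX_fa"}, {"EX_glc"}, {"EX_glc", "EX_glyc"}],
)
```

yields disease ATP `{25: 14.6, 65: 27.39, 85: 44.83, 100: 46.88}` — no
deficit at rest, a 1.6-fold shortfall at maximal intensity — and

```
lifted {nothing}: RMSE 15.60
lifted {EX_fa}: RMSE 15.60          # β-oxidation already saturated: no help
lifted {EX_glc}: RMSE 10.98         # fully corrects the 65 % intensity
lifted {EX_glc, EX_glyc}: RMSE 10.98
```

The same workflow is available from the shell: `myoflux make-synthetic`,
`curate`, `fit-uptakes`, `build-disease`, `sweep`, `compensate` (see
`myoflux --help`); all outputs are TSV with a provenance header.

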