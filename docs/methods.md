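# Methods

## Model and assumptions

The package treats a muscle cell's energy metabolism as a stoichiometric
network at steady state. A flux vector *v* (μmol·gDW⁻¹·min⁻¹) is feasible
when `S·v = 0` for all internal metabolites and every flux respects its
bounds; flux balance analysis (FBA) maximises the flux through the ATP
demand reaction over that polytope, and flux variability analysis (FVA)
reports each reaction's attainable min/max at a fraction of that optimum
(default 1.0, i.e. without degrading the optimum). The framework assumes
optimal operation and ignores metabolite concentrations, enzyme kinetics
and regulation dynamics: a solution is a snapshot of one demand condition,
not a trajectory.

Uptake is a negative exchange flux; "uptake magnitude" always means the
absolute value. "Unbounded" caps are represented by a finite sentinel
(default 1000 μmol·gDW⁻¹·min⁻¹, configurable) so every LP stays bounded.

### Degeneracy

FBA optima are frequently degenerate. After optimising the objective, the
solver secondarily minimises total absolute flux (Σ|v|) at the pinned
optimum, implemented as a second LP over (v, t) with t ≥ |v|. This makes
every reported flux distribution a deterministic, solver-independent
representative of the optimal face; FVA ranges — not single fluxes — remain
the authoritative statement of what is variable. Both LPs run on HiGHS
(scipy.optimize.linprog) with feasibility/optimality tolerances of 1e−9;
optimal solutions are asserted to satisfy ‖S·v‖∞ ≤ 1e−8.

## The mini-muscle network

`myoflux.synth` builds a lumped network — one reaction per pathway — so that
maximal yields have closed forms and every downstream stage can be tested
against exact oracles. Lumps and their stoichiometry:

| reaction | lump |
|---|---|
| GLYCOLYSIS | glucose → 2 pyruvate + 2 ATP + 2 NADH(cytosol) |
| LDH | pyruvate + NADH(cytosol) ⇌ lactate (reversible) |
| PDH | pyruvate → acetyl-CoA + NADH(mito) + CO₂ |
| BETA_OX | fatty acid + 2 ATP → 8 acetyl-CoA + 7 NADH + 7 FADH₂ (palmitate-like C16) |
| TCA | acetyl-CoA → 3 NADH + 1 FADH₂ + 1 ATP + 2 CO₂ |
| ETC_NADH / ETC_FADH2 | NADH (or FADH₂) + ½O₂ → P/O × ATP |
| SHUTTLE_NADH | cytosolic NADH + ½O₂ → ATP (lossless shuttle by default) |
| KETOLYSIS | 3-hydroxybutyrate + 1 ATP → 2 acetyl-CoA + NADH |
| AA_DEG | amino-acid lump → acetyl-CoA + NADH + CO₂ (nitrogen ignored) |
| GLYCEROL_ENTRY | glycerol → pyruvate + FADH₂ + 1 ATP net (mitochondrial G3P shuttle route) |

Default P/O ratios are the textbook 2.5 (NADH) and 1.5 (FADH₂), giving
glucose 32 ATP / 6 O₂ per unit, fatty acid 106 ATP / 23 O₂, ketone body
21.5 / 4.5, amino-acid lump 12.5 / 2.5, glycerol 15 / 3.5, and anaerobic
glucose 2 ATP with 2 lactate exported. Default uptake caps are 5 (glucose)
and 1 (fatty acid); the minor fuels (ketone bodies, amino acids, glycerol)
default to 0 so that experiments enable them explicitly — their baseline
magnitudes in a working muscle are not well quantified, and a zero default
keeps ground-truth recovery exact.

What the generator deliberately does **not** emulate: genome-scale
redundancy (isoenzymes, alternative routes, transporters), nitrogen and
proton bookkeeping, amino-acid-specific stoichiometry, kinetics. A test
passing on the mini-muscle therefore demonstrates correctness of the
*procedure*, not of genome-scale predictions; the pipeline accepts an SBML
model for the latter.

### Study conditions

The default graded-exercise conditions are four intensities — 25, 65, 85 and
100 % of VO₂max — with ATP demands 14.6, 36.52, 54.8 and 75
μmol·gDW⁻¹·min⁻¹ and carbohydrate-oxidation share targets 0.40, 0.50, 0.80
and 1.00, the values reported for exercising muscle in the exercise-physiology
literature. For the mini-muscle the generator derives the unique aerobic
(glucose, fatty-acid) pair realising each demand from the analytic yields
and emits the implied O₂ flux as the scenario constraint, so every scenario
carries a known ground truth. The packaged `scenarios_literature.tsv`
carries the corresponding literature O₂ values (−3.7, −7.9, −11.1, −14) for
use with genome-scale models.

## Uptake fitting

O₂ and ATP are *equality* constraints during fitting (an option relaxes ATP
to a lower bound for sensitivity checks). The sweep starts at the
FVA-maximal glucose uptake and decreases its magnitude in steps of 0.01
μmol·gDW⁻¹·min⁻¹ — the resolution at which fitted uptakes are typically
reported — accepting the first bound whose achieved carbohydrate share is
within 0.02 of the target. The fatty-acid uptake is read from the same
parsimonious solution rather than from a second FVA, which makes the
returned pair unique; this is a package choice where the procedure would
otherwise be underdetermined. The carbohydrate share used as the fitting
criterion is yield-weighted: `Y_glc·|v_glc| / (Y_glc·|v_glc| + Y_fa·|v_fa|)`,
with yields taken from the closed forms (mini-muscle) or measured once per
model by single-fuel FBA probes. A second, representative-flux share mode is
exposed for descriptive pathway reports, because published pathway
percentages do not always state which normalisation they use.

## Disease model

Regulation records carry one of three evidence types, each mapped to a
multiplicative correction factor: measured activity change of *p* % →
`1 + p/100` (in-vitro activities are taken as maxima); expression
fold-change *F* → *F* (maximal enzymatic activity assumed proportional to
total expression); qualitative warning → a configurable factor, default 1.0
(capped at the healthy maximum). Each regulated reaction's upper bound
becomes `factor × max |flux| across the control intensity solutions`
(global scope; a per-intensity profile is available). Reversible reactions
are capped symmetrically in both directions, since activity data do not
distinguish direction; when several records target one reaction the most
restrictive cap wins. Bounds are caps, not fixed values: disease enzymes may
run below them.

A consequence worth noting: a reaction the parsimonious control solutions
never use (e.g. LDH in the fully aerobic mini-muscle optima) has a control
maximum of 0, so any up-regulation record on it caps it at 0. The bundled
demo regulation set therefore targets reactions with non-zero control flux;
genome-scale models, whose control solutions carry small LDH fluxes, do not
hit this edge.

## Intensity sweeps and compensation

In disease/control comparison sweeps, O₂ becomes an uptake *cap* (a
constrained network may consume less than the healthy one) and the ATP
demand is maximised **up to the scenario's demanded flux** — a cell meets
demand rather than overproducing. Under its own fitted caps the control
network therefore reproduces the demand exactly, and a constrained variant
falls short; recovery after lifting a nutrient set's caps to the large-bound
sentinel is scored by the RMSE between the disease and control ATP curves
over the four intensities (units μmol·gDW⁻¹·min⁻¹). Capping production at
demand guarantees disease ≤ control pointwise, hence the asserted
monotonicity: lifting a superset of nutrients never increases RMSE.

FVA variability reports use the same per-intensity constraint setup at
fraction-of-optimum 1. A zero-width range means the optimum admits exactly
one flux through that enzyme — the collapse of metabolic flexibility that
characterises the constrained disease model from 65 % VO₂max upward.

## Curation

Species curation consumes a static EC-presence table (offline, reproducible)
instead of live database queries, and removes a reaction only when its EC is
recorded absent *and* the reaction id appears on an explicit removal
whitelist — encoding the manual literature check as data rather than code.
Unknown or entry-less ECs are reported, never removed. The packaged presence
table is a synthetic stand-in covering the mini-muscle EC numbers.

## Numerical choices and degenerate inputs

- LP tolerances 1e−9 (HiGHS primal/dual), mass-balance assertion 1e−8,
  parsimonious objective pin slackened by 1e−9·max(1, |z|).
- FVA clamps inverted (round-off) ranges to their midpoint; at a negative
  optimum the near-optimality threshold scales as z/fraction so the
  constraint keeps its meaning.
- All-zero pathway fluxes yield all-zero shares with an explicit flag rather
  than NaN.
- Empty scenario lists, unmatched regulation records and per-intensity
  infeasibilities are collected and reported, never silently dropped, and do
  not abort batch runs.
- Every random generation step takes an explicit seed (module default
  20241209).

## Problem sizes

The bundled analyses run on the 20-reaction mini-muscle network with four
intensity scenarios; uptake-recovery checks use 20 randomly drawn
ground-truth scenarios per seed, and oracle comparisons enumerate flux
polytopes of at most 6 reactions. These sizes make the full test suite and
the acceptance script complete in seconds while exercising every code path;
genome-scale runs (≈500 reactions) use the same code unchanged.

## Known limitations

- Single objective (ATP demand); no biomass, no multi-objective trade-offs.
- No thermodynamic (loopless) constraints: parsimony suppresses, but does
  not forbid, futile cycles.
- The lumped glycerol route enters via the mitochondrial G3P shuttle
  (FADH₂); muscles with a dominant cytosolic route would yield differently.
- Fitting adjusts exactly two uptakes (glucose, fatty acid); other fuels
  keep their configured caps.
- SBML support covers Level 3 + FBC bounds/annotations; kinetic laws and
  events are rejected explicitly rather than parsed.
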