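# dietfba

Compile chemically complex growth-medium descriptions into quantitative
nutritional constraints for genome-scale metabolic models, predict biomass
yield by flux balance analysis, diagnose missing nutrients through LP
reduced costs, and scan nutrient supplementations for growth effects.

## The problem

Constraint-based models predict growth by maximising flux through a biomass
reaction subject to steady state and exchange bounds:

```
max  c·v    s.t.   S·v = 0,   lb ≤ v ≤ ub
```

where `S` is the stoichiometric matrix and exchange pseudo-reactions connect
the network to its environment (negative flux = uptake). The quality of any
prediction hinges on those uptake bounds — yet most real media are defined
at the level of complex components (tryptone, yeast extract, serum), not
molecules, and modellers routinely fall back on arbitrary uptake values.

`dietfba` closes that gap with a reproducible pipeline:

1. **describe** the medium as components + amounts + environment (pH,
   oxygen regime) in plain tabular files;
2. **decompose** complex components into molecular constituents via
   mass-fraction composition tables (manufacturer sheets, literature);
3. **convert** masses to concentrations (mmol/L) and inject the
   environmental compounds — water (~5.55·10⁴ mmol/L for aqueous media),
   oxygen, and protons (10^(−pH)·1000 mmol/L);
4. **speciate**: salts dissociate to ions, polymers are substituted by a
   model-supported unit, redox-ambiguous metals split across oxidation
   states (default 50/50 Fe²⁺/Fe³⁺), conjugate acid/base pairs collapse to
   the model's form;
5. **map** compounds to exchange reactions across nomenclature dialects
   (`EX_x(e)` vs `EX_x_e`) with explicit policies for unmatched compounds;
6. **simulate**: set each matched exchange lower bound to −concentration
   and solve the LP. With bounds in mmol per litre of medium and a
   BiGG-normalised biomass reaction (unit flux = 1 gDW), the objective is a
   biomass **yield in gDW/L**; with bounds in mmol/gDW/h it is a growth
   rate (rate mode);
7. **troubleshoot**: at zero growth, the reduced cost
   `∂(objective)/∂(lower bound)` of each closed or binding uptake ranks the
   nutrients whose absence limits growth; the repair loop adds them at
   user-supplied (or trace) concentrations until the model grows;
8. **scan**: re-solve once per compound with +Δ mmol/L or +x% to find which
   nutrients the predicted yield actually responds to.

Every compiled concentration carries a provenance trail (component, rule,
intermediate values), so a diet file is an auditable artifact rather than a
bag of numbers.

## Worked example

`examples/02_map_and_simulate.py` builds a miniature LB-like medium (a
10 g/L protein hydrolysate, 5.844 g/L NaCl, 0.1 mmol/L iron) and a toy
model that consumes its three amino acids:

```
FBA status: optimal
predicted biomass yield: 1.122460 gDW/L
closed-form check (limiting amino acid ala__L): 1.122460 gDW/L
```

The hydrolysate yields 3.37 mmol/L alanine (10 g/L × 0.03 g/g ÷ 89.09 g/mol),
and the toy biomass needs 3 mmol alanine per gDW, so the yield is
3.37/3 = 1.12 gDW/L — alanine is the limiting nutrient. The supplementation
scan (`examples/04_supplement_scan.py`) confirms it: +30% alanine raises
the yield by 18.7% while every other compound's effect is below the 10⁻⁶
cutoff. The troubleshooting example (`examples/03_troubleshoot_missing_nutrient.py`)
shows the reduced-cost diagnosis restoring growth of a medium missing a
trace ion:

```
initial FBA: status=optimal, objective=0 gDW/L
  candidate: EX_trace_ion(e)  |reduced cost| = 1e+03
iteration 1: added trace_ion at 0.000307 mmol/L; objective 0 -> 0.307
```

`examples/lb_case_study.py` runs the full published E. coli/LB
reproduction (yield 1.54 gDW/L after molybdate repair, core-model yield
0.59 gDW/L, acetate secretion ranges, oxygen and glucose supplementation)
once the BiGG model files and the published LB diet table are placed under
`data/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's verifiable quantities from scratch: it runs the
full roadmap (compile → map → simulate → troubleshoot → scan) on the
deterministic toy bundle, checks the FBA objective against the closed-form
min-ratio optimum there and on seed-randomised toy models, and writes the
results JSON to `--out`. It exits non-zero on any inconsistency.

## Layout

```
src/dietfba/
  medium.py        medium/composition/diet types and tabular I/O
  compile.py       decomposition, unit conversion, speciation, environment
  mapping.py       compound -> exchange-reaction resolution
  fba.py           model container, SBML/JSON reading, diet bounds, FBA, FVA
  troubleshoot.py  reduced-cost diagnosis and diet repair
  scan.py          supplementation scans
  fixtures.py      toy models/recipes with closed-form optima
  workflow.py      file-level pipeline (RunConfig + stage runners)
examples/          one narrative script per capability
docs/methods.md    modelling assumptions, defaults, numerical choices
```
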