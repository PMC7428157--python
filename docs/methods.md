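# Methods

## Scope and model

`dietfba` turns a component-level medium description into exchange-reaction
bounds for flux balance analysis (FBA) and interrogates the resulting linear
program. FBA here is the standard LP

```
max c·v   subject to   S·v = 0,  lb ≤ v ≤ ub
```

over a stoichiometric matrix `S` (metabolites × reactions). Exchange
pseudo-reactions — reactions touching exactly one (external) metabolite —
carry the environment: negative flux is uptake, positive is secretion.

Two constraint interpretations are supported and never mixed:

* **yield mode** — exchange lower bounds are set to −concentration in mmol
  per litre of medium. BiGG-style biomass reactions are normalised so unit
  flux produces 1 g dry weight, so the optimal objective is a biomass yield
  in gDW per litre of medium.
* **rate mode** — bounds are maximum uptake fluxes in mmol/gDW/h and the
  objective is a growth rate (1/h). Converting concentrations into uptake
  fluxes requires compound- and organism-specific kinetics (Monod-type),
  which is deliberately out of scope: the package accepts user-supplied
  flux values in rate mode but never estimates them.

## Diet compilation

Pipeline order is fixed and auditable: decompose → mass→molar → merge →
speciate → inject environment.

**Decomposition.** A complex component at `a` g/L with composition entries
`(compound, w g/g)` contributes `a·w` g/L of each compound. Composition
fraction sums are validated to ≤ 1 + 10⁻⁶ (a component cannot yield more
mass than itself), so total decomposed mass never exceeds the input.

**Mass → molar.** `mmol/L = (g/L) / (g/mol) × 1000`. Protein-hydrolysate
amino-acid fractions are treated as free amino-acid mass equivalents
(manufacturer convention); `residue_mass=True` instead divides by
`MW − 18.015` for residue-based composition data. Hydrated salts should be
registered with the hydrate's molar mass; the water of hydration is
discarded as negligible against the ~55.5 M solvent background.

**Merging.** The same compound arriving from several components is summed;
compilation is therefore order-independent (a tested invariant).

**Speciation rules** (`source → products`, four kinds):

* `dissociation` — stoichiometric, e.g. NaCl → Na⁺ + Cl⁻ (1:1 conserves
  molar amount per product);
* `oxidation_split` — molar fractions summing to 1; the default iron split
  is 0.5/0.5 Fe²⁺/Fe³⁺, reflecting measured intracellular ratios, and is
  overridable per rule. For well-defined media the split should instead be
  derived from the source salts (FeSO₄ → Fe²⁺, FeCl₃ → Fe³⁺);
* `polymer_substitution` — replace a polymer by the smallest
  model-supported unit (e.g. cellulose as cellobiose); mass conservation is
  checked when molar masses are known. Substituting monomers instead is
  possible but lets the model skip the hydrolysis step;
* `surrogate` — 1:1 replacement of a form the model lacks by one it has
  (butyric acid → butyrate; conjugate pairs collapse to the model's form).

Rule chains are topologically ordered; cycles are an error.

**Environment.** Aqueous media get water at `1000 / 18.015 × 1000 =
5.5509·10⁴ mmol/L` (density 1 g/cm³). Oxygen defaults to 18.2 mmol/L for
aerobic aqueous recipes — an uptake-equivalent value derived from aerobic
E. coli batch cultures, not an air-saturation solubility (true dissolved O₂
is ~0.25 mmol/L; the larger value reflects continuous resupply by
diffusion and sparging over the culture, and is the single most sensitive
number in the whole pipeline). `oxygen_mmol_per_L = 0` encodes anaerobic
conditions. Protons are `10^(−pH) × 1000` mmol/L exactly (pH 7 → 10⁻⁴
mmol/L). Injection fails loudly if the diet already contains h2o/o2/h, to
prevent double counting.

Zero-concentration entries are pruned everywhere: absence from a compiled
diet *means* closed uptake.

## Identifier mapping

Exchange reactions are indexed by their single external metabolite with the
compartment suffix stripped; the suffix dialect (`(e)`/`[e]` vs `_e`) is
inferred by majority vote or forced. Matching is exact-id after alias
expansion — no fuzzy matching, because a silently wrong assignment corrupts
every downstream number. Unmatched compounds follow one of three policies:
`drop` (warn, aliases ignored), `surrogate-then-drop` (alias table first,
e.g. nicotinamide → nicotinate, then drop), `fail` (raise listing all
unmatched). Model curation — adding missing exchanges/transporters — is out
of scope; the mapping report names what curation would need.

## Solving and sensitivities

The LP runs through a minimal pluggable backend (`dietfba._lp`); the
default is scipy's HiGHS interface. Reported conventions:

* reduced costs are `∂(optimal objective)/∂(bound)` of the *maximisation*
  problem: a growth-limiting uptake bound has a negative lower reduced
  cost whose magnitude is the yield gained per extra mmol/L;
* metabolite duals are `∂(objective)/∂(accumulation)`;
* strong duality (objective = bound-weighted multipliers) and steady-state
  residuals are asserted in tests at 10⁻⁶–10⁻⁹.

Tolerances: feasibility 10⁻⁹, reduced costs below 10⁻⁸ treated as zero,
growth threshold 10⁻⁶ (shared with the supplementation cutoff).

**Degenerate optima.** FBA flux vectors are generally non-unique. Any
secretion claim should therefore be made on the flux range at the fixed
optimum (two extra LPs with `c·v ≥ opt·(1−10⁻⁶)`), which
`fixed_optimum_flux_range` provides; the pipeline's cheap `non_unique`
flag probes only the biomass flux range against 5× the fixing slack and
does not certify uniqueness of the whole vector.

## Troubleshooting

At a zero-growth optimum, exchange reactions whose lower bound is zero or
binding are ranked by |reduced cost| (ties broken lexicographically). If
maintenance-style positive lower bounds (e.g. fixed ATP hydrolysis) make
the LP infeasible outright, they are relaxed to zero *for diagnosis only*
and the relaxation is reported — growth is always judged on the true
model. The repair loop adds the top suggestion at the user's candidate
concentration (default 10⁻³ mmol/L, an explicit trace-level placeholder
that should be replaced by a literature value) and re-solves; each
iteration is weakly objective-improving because it only relaxes bounds.
Exhausting the iteration budget points at model defects, for which the
package deliberately offers no gap-filling.

A caveat inherited from LP theory: reduced costs are local derivatives. A
diet missing *two* jointly essential nutrients has zero gain from any
single addition and dual-degenerate reduced costs; the ranking is then
solver-dependent, which is why the oracle tests only assert agreement when
the top magnitude is decisively separated from the runner-up.

## Supplementation scan

One re-solve per compound, everything else untouched. Absolute mode adds
Δ mmol/L (opening the exchange for compounds absent from the diet — how
non-native carbohydrates are tested); relative mode scales by 1+x (absent
compounds stay absent). Relative differences are `(perturbed − base)/base`;
since supplementation only relaxes bounds of a maximisation LP, no
difference can be negative beyond solver noise (a tested invariant).
Effects below the 10⁻⁶ cutoff are retained in raw output but excluded from
the effect set.

## Synthetic fixtures and what green tests establish

The toy model family (per substrate: exchange → transport → internal pool;
one biomass reaction with fixed stoichiometries; optional maintenance
drain and redundant transporter) has the closed-form optimum
`min_i (conc_i − maint·[i=1]) / stoich_i`, so solver output is checked
against arithmetic, and against brute-force vertex enumeration on ≤8
reactions. The toy recipe bundle (hydrolysate → 3 amino acids; NaCl
dissociation; Fe oxidation split; aqueous aerobic pH 7) compiles to exactly
10 entries and exercises every compiler branch.

These fixtures emulate the *structure* of the real problem — complex
components, speciation, environment injection, nomenclature mapping,
limiting-nutrient LPs — but not its scale or biology: no genome-scale
network, no realistic biomass composition, no cofactor/energy coupling, no
secretion chemistry. A green toy suite establishes that the pipeline's
arithmetic, bookkeeping and LP sensitivities are correct, not that any
particular organism's yield prediction is accurate. The published E. coli
LB reproduction (yield 1.54 gDW/L on the genome-scale model after
molybdate repair at 3.07·10⁻⁴ mmol/L; 0.59 gDW/L on the core model;
acetate ranges containing 46.72 / 4.5 mmol/L; oxygen +30% → >17% yield;
glucose +20 mM → +54%) requires the BiGG model files and the published
per-compound LB table, which are measured/curated inputs this package
treats as data and does not re-derive; `examples/lb_case_study.py` runs
the whole narrative once they are fetched.

## Known limitations

* No kinetics: concentrations-to-uptake-rate conversion (rate mode inputs)
  is the user's responsibility.
* No bioavailability or host-side transformation of nutrients.
* No model curation or gap-filling; the troubleshooter stops at the diet.
* No combinatorial (multi-compound) supplementation search.
* ODS spreadsheets are not read directly (no ODS reader in the supported
  dependency set); export composition/diet tables to CSV/TSV first.
* Exact flux vectors at degenerate optima are solver-dependent; only
  objectives and flux ranges are comparable across solvers.
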