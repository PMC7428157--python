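"""Reproduce the E. coli LB-medium case study end to end.

Requires three externally fetched inputs in a data directory (default:
``data/`` at the repository root):

* ``iJO1366.json``     — genome-scale E. coli K-12 model, from BiGG:
                         http://bigg.ucsd.edu/static/models/iJO1366.json
* ``e_coli_core.json`` — core E. coli model, from BiGG:
                         http://bigg.ucsd.edu/static/models/e_coli_core.json
* ``lb_diet.tsv``      — the per-compound LB diet (columns ``compound``,
                         ``concentration_mmol_per_L``), exported to TSV from
                         the published stepwise LB diet table (distributed
                         as an ODS spreadsheet alongside the roadmap
                         article). These concentrations are measured/curated
                         data and are deliberately not re-derived here.

What it shows, and the published values it should land on:

1. mapping the LB diet onto iJO1366 (53 compounds matched, the rest
   dropped with warnings — metals, folate and other compounds without
   exchange reactions);
2. FBA predicting zero growth, diagnosed via reduced costs: the top-ranked
   missing nutrient is molybdate (EX_mobd), repaired at 3.07e-4 mmol/L,
   after which the yield is 1.54 gDW per litre of LB;
3. the same diet on the core model: 0.59 gDW/L (~38% of genome-scale);
4. acetate secretion at the fixed growth optimum: the flux-variability
   range should contain 46.72 mmol/L (genome-scale) and 4.5 mmol/L (core);
5. supplementation: oxygen +30% -> more than +17% yield; glucose +20 mmol/L
   -> about +54% yield.

Run:  python examples/lb_case_study.py [data_dir]
"""

import sys
import warnings
from pathlib import Path

from dietfba import (
    apply_diet_bounds,
    build_exchange_index,
    fixed_optimum_flux_range,
    map_diet,
    rank_missing_nutrients,
    read_model,
    repair_diet,
    scan,
    solve_fba,
)
from dietfba.medium import read_compiled_diet

# surrogate choices for LB compounds without their own exchange reaction
LB_ALIASES = {"ncam": "nac"}  # nicotinamide -> nicotinate

MOLYBDATE_MMOL_PER_L = 3.07e-4  # trace molybdenum content of the medium


def run(data_dir: Path, quiet: bool = False) -> dict:
    def say(*args):
        if not quiet:
            print(*args)

    data_dir = Path(data_dir)
    diet = read_compiled_diet(data_dir / "lb_diet.tsv")
    say(f"LB diet: {len(diet)} compounds, e.g. {diet.items()[:3]}")

    model = read_model(data_dir / "iJO1366.json")
    index = build_exchange_index(model)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mappings = map_diet(diet, index, LB_ALIASES, policy="surrogate-then-drop")
    n_matched = sum(m.status in ("matched", "surrogate") for m in mappings)
    n_dropped = sum(m.status == "dropped" for m in mappings)
    say(f"mapping: {n_matched} matched, {n_dropped} without exchange reactions")

    bounded = apply_diet_bounds(model, mappings, diet, mode="yield")
    first = solve_fba(bounded)
    say(f"initial FBA: status={first.status}, objective={first.objective_value}")

    suggestions = rank_missing_nutrients(bounded)
    top = suggestions[0] if suggestions else None
    say(f"top missing nutrient by |reduced cost|: {top.exchange_reaction_id if top else None}")

    repaired_diet, repaired, trail = repair_diet(
        bounded,
        diet,
        candidate_bounds={"mobd": MOLYBDATE_MMOL_PER_L},
        max_iterations=5,
    )
    final = solve_fba(repaired)
    say(f"repaired in {len(trail)} iteration(s): yield {final.objective_value:.4g} gDW/L")

    ac_rxn = index.get("ac")
    ac_range = fixed_optimum_flux_range(repaired, ac_rxn, final.objective_value)
    say(f"acetate secretion range at fixed optimum: {ac_range} mmol/L")

    core = read_model(data_dir / "e_coli_core.json")
    core_index = build_exchange_index(core)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        core_maps = map_diet(repaired_diet, core_index, LB_ALIASES)
    core_bounded = apply_diet_bounds(core, core_maps, repaired_diet, mode="yield")
    core_res = solve_fba(core_bounded)
    say(f"core-model yield: {core_res.objective_value:.4g} gDW/L "
        f"({core_res.objective_value / final.objective_value:.0%} of genome-scale)")
    core_ac = fixed_optimum_flux_range(
        core_bounded, core_index["ac"], core_res.objective_value
    )

    oxy = scan(repaired, mappings, repaired_diet, mode="relative", delta=0.30,
               extra_compounds=(), exchange_index=index)
    oxy_diff = {r.compound_id: r.relative_difference for r in oxy.rows}.get("o2", 0.0)
    say(f"oxygen +30%: relative yield difference {oxy_diff:+.1%}")

    glc = scan(repaired, mappings, repaired_diet, mode="absolute", delta=20.0,
               extra_compounds=("glc__D",), exchange_index=index)
    glc_diff = {r.compound_id: r.relative_difference for r in glc.rows}.get("glc__D", 0.0)
    say(f"glucose +20 mmol/L: relative yield difference {glc_diff:+.1%}")

    return {
        "n_matched": n_matched,
        "n_dropped": n_dropped,
        "initial_objective": first.objective_value,
        "top_missing": top.exchange_reaction_id if top else None,
        "yield_gdw_per_L": final.objective_value,
        "acetate_range_mmol_per_L": ac_range,
        "core_yield_gdw_per_L": core_res.objective_value,
        "core_acetate_range_mmol_per_L": core_ac,
        "oxygen_plus30_rel_diff": oxy_diff,
        "glucose_plus20mM_rel_diff": glc_diff,
    }


if __name__ == "__main__":
    data = Path(sys.argv[1]) if len(sys.argv) > 1 else Path(__file__).resolve().parent.parent / "data"
    missing = [n for n in ("iJO1366.json", "e_coli_core.json", "lb_diet.tsv") if not (data / n).exists()]
    if missing:
        sys.exit(
            f"missing inputs under {data}: {', '.join(missing)}\n"
            "fetch the models from http://bigg.ucsd.edu/static/models/ and "
            "export the published LB diet table to lb_diet.tsv (see module docstring)"
        )
    run(data)
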