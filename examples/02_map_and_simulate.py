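"""Map a compiled diet to a model and predict biomass yield (steps 4-5).

Writes the toy bundle to disk in its public formats (CSV tables + BiGG-style
JSON model), then runs the file-level pipeline: compile -> map -> bound
exchanges -> FBA. The toy model consumes the three amino acids at fixed
stoichiometry, so the predicted yield equals the min-ratio closed form and
can be checked by hand.
"""

import tempfile
import warnings
from pathlib import Path

from dietfba import RunConfig, run_simulate
from dietfba.fixtures import write_toy_bundle

tmp = Path(tempfile.mkdtemp())
paths = write_toy_bundle(tmp / "bundle")
config = RunConfig(
    recipe=paths["recipe"],
    compositions=paths["compositions"],
    rules=paths["rules"],
    registry=paths["registry"],
    model=paths["model"],
    output_dir=tmp / "out",
)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    diet, bounded, mappings, result = run_simulate(config)

print("mapping:")
for m in mappings:
    print(f"  {m.compound_id:8s} {m.status:9s} {m.exchange_reaction_id or '-'}")

print(f"\nFBA status: {result.status}")
print(f"predicted biomass yield: {result.objective_value:.6f} {result.objective_units}")
print(f"flux solution unique at the optimum: {not result.non_unique}")

expected = (10 * 0.03 / 89.09 * 1000) / 3.0  # ala__L limits: conc / stoichiometry
print(f"closed-form check (limiting amino acid ala__L): {expected:.6f} gDW/L")
print(f"\nreports written under {config.output_dir} (diet.tsv, mapping.tsv, fba_report.json)")
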