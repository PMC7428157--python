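"""File-level pipeline: configuration, stage runners, report assembly.

Mirrors the six-step roadmap as composable functions over files:

* :func:`run_compile`  — steps 1–3: recipe + compositions + rules -> diet TSV
* :func:`run_map`      — step 4: diet vs model -> mapping TSV
* :func:`run_simulate` — step 5: bounds + FBA -> JSON report
* :func:`run_troubleshoot` — step 6: reduced-cost repair -> audit JSON
* :func:`run_scan`     — supplementation scan -> report TSV
* :func:`run_roadmap`  — all of the above in order

Each runner resolves a :class:`RunConfig` once, writes machine-readable
outputs into ``config.output_dir``, serialises the config verbatim into
every JSON report for reproducibility, and returns the in-memory objects so
library users can keep going without re-reading files. Warnings emitted by
the stages are captured to ``warnings.jsonl`` (one JSON object per line).
Re-running with identical inputs produces byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

from .compile import compile_diet, read_speciation_rules
from .fba import (
    FBAResult,
    GROWTH_THRESHOLD,
    MetabolicModel,
    apply_diet_bounds,
    fixed_optimum_flux_range,
    read_model,
    solve_fba,
)
from .mapping import build_exchange_index, map_diet, read_alias_table, write_mapping_report
from .medium import (
    CompiledDiet,
    read_compound_registry,
    read_composition_table,
    read_recipe,
    write_compiled_diet,
)
from .scan import DEFAULT_CUTOFF, rank_report, scan, write_report
from .troubleshoot import repair_diet

__all__ = [
    "RunConfig",
    "run_compile",
    "run_map",
    "run_simulate",
    "run_troubleshoot",
    "run_scan",
    "run_roadmap",
]


@dataclass
class RunConfig:
    """Resolved inputs and knobs for one pipeline run."""

    recipe: Path
    compositions: Path
    rules: Path
    registry: Path
    model: Path
    output_dir: Path
    aliases: Path | None = None
    mode: str = "yield"  # yield | rate
    dialect: str = "auto"  # exchange-suffix convention
    policy: str = "surrogate-then-drop"
    scan_mode: str = "relative"
    scan_delta: float = 0.30
    cutoff: float = DEFAULT_CUTOFF
    growth_threshold: float = GROWTH_THRESHOLD
    residue_mass: bool = False

    def __post_init__(self) -> None:
        for name in ("recipe", "compositions", "rules", "registry", "model", "output_dir"):
            setattr(self, name, Path(getattr(self, name)))
        if self.aliases is not None:
            self.aliases = Path(self.aliases)

    def to_json_obj(self) -> dict:
        out = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            out[f.name] = str(v) if isinstance(v, Path) else v
        return out


class _WarningLog:
    """Capture stage warnings as JSON lines alongside the Python machinery."""

    def __init__(self, path: Path) -> None:
        self.path = path
        self.records: list[dict] = []

    def __enter__(self) -> "_WarningLog":
        self._ctx = _warnings.catch_warnings(record=True)
        self._caught = self._ctx.__enter__()
        _warnings.simplefilter("always")
        return self

    def __exit__(self, *exc) -> None:
        self._ctx.__exit__(*exc)
        for w in self._caught:
            self.records.append({"category": w.category.__name__, "message": str(w.message)})
        with open(self.path, "a") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
        for w in self._caught:  # re-emit for interactive users
            _warnings.warn_explicit(w.message, w.category, w.filename, w.lineno)


def _prepare(config: RunConfig) -> Path:
    config.output_dir.mkdir(parents=True, exist_ok=True)
    return config.output_dir


def run_compile(config: RunConfig) -> CompiledDiet:
    """Steps 1–3: compile the recipe and write ``diet.tsv``."""
    out = _prepare(config)
    recipe = read_recipe(config.recipe)
    compositions = read_composition_table(config.compositions)
    rules = read_speciation_rules(config.rules)
    registry = read_compound_registry(config.registry)
    diet = compile_diet(recipe, compositions, rules, registry, residue_mass=config.residue_mass)
    write_compiled_diet(diet, out / "diet.tsv")
    return diet


def run_map(config: RunConfig, diet: CompiledDiet | None = None, model: MetabolicModel | None = None):
    """Step 4: map the diet onto the model; writes ``mapping.tsv``."""
    out = _prepare(config)
    if diet is None:
        diet = run_compile(config)
    if model is None:
        model = read_model(config.model)
    index = build_exchange_index(model, dialect=config.dialect)
    aliases = read_alias_table(config.aliases) if config.aliases else {}
    with _WarningLog(out / "warnings.jsonl"):
        mappings = map_diet(diet, index, aliases, policy=config.policy)
    write_mapping_report(mappings, out / "mapping.tsv")
    return diet, model, index, mappings


def _fba_report_obj(config: RunConfig, result: FBAResult) -> dict:
    report: dict = {
        "config": config.to_json_obj(),
        "status": result.status,
        "mode": result.mode,
        "objective_units": result.objective_units,
        "objective_value": result.objective_value,
    }
    if result.optimal:
        nonzero = result.fluxes[result.fluxes.abs() > 1e-9].sort_index()
        rc = result.reduced_costs[result.reduced_costs.abs() > 1e-9].sort_index()
        report["nonzero_fluxes"] = {k: float(v) for k, v in nonzero.items()}
        report["reduced_costs"] = {k: float(v) for k, v in rc.items()}
        report["non_unique"] = result.non_unique
    return report


def run_simulate(config: RunConfig):
    """Step 5: apply diet bounds, solve FBA, write ``fba_report.json``.

    The biomass flux is additionally checked for alternate optima via a
    fixed-optimum flux range on the objective reaction, and the result is
    flagged ``non_unique`` when the range is wider than 1e-6.
    """
    out = _prepare(config)
    diet, model, index, mappings = run_map(config)
    with _WarningLog(out / "warnings.jsonl"):
        bounded = apply_diet_bounds(model, mappings, diet, mode=config.mode)
    result = solve_fba(bounded, mode=config.mode)
    if result.optimal and result.objective_value > 0 and bounded.biomass_reaction:
        lo, hi = fixed_optimum_flux_range(
            bounded, bounded.biomass_reaction, result.objective_value
        )
        # the optimum-fixing slack itself widens the range; only widths well
        # beyond it indicate alternate optima of the objective value
        slack = max(abs(result.objective_value) * 1e-6, 1e-6)
        result.non_unique = bool(hi - lo > 5 * slack)
    with open(out / "fba_report.json", "w") as fh:
        json.dump(_fba_report_obj(config, result), fh, indent=1, sort_keys=True)
    return diet, bounded, mappings, result


def run_troubleshoot(config: RunConfig, candidate_bounds=None, max_iterations: int = 10):
    """Step 6: repair a non-growing diet; writes ``repair_audit.json``."""
    out = _prepare(config)
    diet, bounded, mappings, result = run_simulate(config)
    reverse = {
        m.exchange_reaction_id: m.compound_id
        for m in mappings
        if m.exchange_reaction_id is not None
    }
    repaired_diet, repaired_model, trail = repair_diet(
        bounded,
        diet,
        candidate_bounds=candidate_bounds,
        max_iterations=max_iterations,
        reverse_mapping=reverse,
        growth_threshold=config.growth_threshold,
    )
    final = solve_fba(repaired_model, mode=config.mode)
    audit = {
        "config": config.to_json_obj(),
        "initial_objective": result.objective_value,
        "final_objective": final.objective_value,
        "iterations": [step.to_json_obj() for step in trail],
    }
    with open(out / "repair_audit.json", "w") as fh:
        json.dump(audit, fh, indent=1, sort_keys=True)
    write_compiled_diet(repaired_diet, out / "diet_repaired.tsv")
    return repaired_diet, repaired_model, trail, final


def run_scan(config: RunConfig, extra_compounds=(), diet=None, bounded=None, mappings=None):
    """Supplementation scan; writes ``scan_report.tsv`` (ranked)."""
    out = _prepare(config)
    if diet is None or bounded is None or mappings is None:
        diet, bounded, mappings, _ = run_simulate(config)
    index = build_exchange_index(bounded, dialect=config.dialect)
    report = scan(
        bounded,
        mappings,
        diet,
        mode=config.scan_mode,
        delta=config.scan_delta,
        extra_compounds=tuple(extra_compounds),
        cutoff=config.cutoff,
        exchange_index=index,
    )
    write_report(report, out / "scan_report.tsv")
    return report


def run_roadmap(config: RunConfig, candidate_bounds=None, extra_compounds=()):
    """Run compile -> map -> simulate -> (troubleshoot if needed) -> scan.

    The troubleshooter only engages when the simulated objective does not
    clear the growth threshold. Returns a dict with every stage's product.
    """
    diet, bounded, mappings, result = run_simulate(config)
    trail = []
    if not result.optimal or (result.objective_value or 0.0) <= config.growth_threshold:
        diet, bounded, trail, result = run_troubleshoot(
            config, candidate_bounds=candidate_bounds
        )
    report = run_scan(
        config, extra_compounds=extra_compounds, diet=diet, bounded=bounded, mappings=mappings
    )
    return {
        "diet": diet,
        "model": bounded,
        "mappings": mappings,
        "fba": result,
        "repair_trail": trail,
        "scan": report,
        "ranked_scan": rank_report(report),
    }
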