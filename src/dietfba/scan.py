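"""Systematic nutrient-supplementation scan.

For each compound of a compiled diet (optionally extended by extra
compounds such as glucose), the uptake bound is perturbed — by an absolute
increment (e.g. +1 mmol/L) or a relative one (e.g. +30%) — the FBA is
re-solved, and the relative change of the optimal objective is recorded.
Compounds whose effect falls below a cutoff (default 1e-6 relative) are kept
in the raw table but excluded from the "effect" set.

Because the baseline is an LP maximum and supplementation only relaxes
bounds, no relative difference can be negative (beyond solver noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .fba import MetabolicModel, ModelError, solve_fba
from .mapping import MetaboliteMapping
from .medium import CompiledDiet

__all__ = [
    "SupplementationReport",
    "ScanRow",
    "scan",
    "rank_report",
    "write_report",
    "DEFAULT_CUTOFF",
    "GLUCOSE_BOOST_MMOL_PER_L",
]

#: Relative-difference cutoff below which a supplementation effect is noise.
DEFAULT_CUTOFF = 1e-6

#: Convenience amount for the classic +20 mM glucose boost experiment.
GLUCOSE_BOOST_MMOL_PER_L = 20.0


@dataclass(frozen=True)
class ScanRow:
    compound_id: str
    baseline_objective: float
    perturbed_objective: float
    relative_difference: float


@dataclass
class SupplementationReport:
    mode: str  # absolute | relative
    delta: float  # mmol/L for absolute, fraction for relative
    cutoff: float
    rows: list[ScanRow] = field(default_factory=list)

    @property
    def effects(self) -> list[ScanRow]:
        """Rows whose |relative difference| clears the cutoff."""
        return [r for r in self.rows if abs(r.relative_difference) >= self.cutoff]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "compound": r.compound_id,
                    "baseline": r.baseline_objective,
                    "perturbed": r.perturbed_objective,
                    "relative_difference": r.relative_difference,
                    "mode": self.mode,
                    "delta": self.delta,
                }
                for r in self.rows
            ],
            columns=["compound", "baseline", "perturbed", "relative_difference", "mode", "delta"],
        )


def scan(
    model: MetabolicModel,
    mappings: Sequence[MetaboliteMapping],
    diet: CompiledDiet,
    mode: str = "relative",
    delta: float = 0.30,
    extra_compounds: Sequence[str] = (),
    cutoff: float = DEFAULT_CUTOFF,
    exchange_index: Mapping[str, str] | None = None,
) -> SupplementationReport:
    """One FBA re-solve per supplemented compound, diet otherwise unchanged.

    ``model`` must already carry the diet bounds (the baseline). In
    ``absolute`` mode each compound's concentration is raised by ``delta``
    mmol/L — for a compound absent from the diet this means opening its
    exchange at ``delta`` (that is how carbohydrates not native to the medium
    are tested). In ``relative`` mode concentrations are scaled by
    ``1 + delta``; absent compounds stay absent (a relative increment of
    nothing is nothing).

    ``extra_compounds`` not in the diet need ``exchange_index`` (compound ->
    exchange reaction) to locate their exchanges.

    Raises :class:`ModelError` if the baseline does not grow — run the
    troubleshooter first.
    """
    if mode not in ("absolute", "relative"):
        raise ValueError(f"mode must be 'absolute' or 'relative', got {mode!r}")
    if delta < 0:
        raise ValueError(f"delta must be >= 0, got {delta}")

    baseline = solve_fba(model)
    if not baseline.optimal or baseline.objective_value <= 0:
        raise ModelError(
            "baseline FBA does not grow "
            f"(status={baseline.status}, objective="
            f"{baseline.objective_value}); diagnose with the troubleshooter "
            "before scanning supplementations"
        )
    base_obj = float(baseline.objective_value)

    rxn_for: dict[str, str] = {
        m.compound_id: m.exchange_reaction_id
        for m in mappings
        if m.status in ("matched", "surrogate")
    }
    if exchange_index:
        for cpd, rxn in exchange_index.items():
            rxn_for.setdefault(cpd, rxn)

    targets: list[str] = sorted(set(diet.compounds) | set(extra_compounds))
    rows: list[ScanRow] = []
    for cpd in targets:
        if cpd not in rxn_for:
            # unmapped compound: supplementing it cannot touch the model
            rows.append(ScanRow(cpd, base_obj, base_obj, 0.0))
            continue
        conc = diet.get(cpd, 0.0)
        if mode == "absolute":
            new_conc = conc + delta
        else:
            new_conc = conc * (1.0 + delta)
        if new_conc == conc:
            rows.append(ScanRow(cpd, base_obj, base_obj, 0.0))
            continue
        j = model.reaction_index(rxn_for[cpd])
        perturbed = model.copy()
        perturbed.lb[j] = -new_conc
        res = solve_fba(perturbed)
        if not res.optimal:
            raise ModelError(
                f"supplementing {cpd!r} made the LP {res.status}; this should "
                "not happen for a bound relaxation"
            )
        pert_obj = float(res.objective_value)
        rows.append(ScanRow(cpd, base_obj, pert_obj, (pert_obj - base_obj) / base_obj))
    return SupplementationReport(mode=mode, delta=delta, cutoff=cutoff, rows=rows)


def rank_report(report: SupplementationReport) -> list[ScanRow]:
    """Rows sorted by descending relative difference, ties lexicographic."""
    return sorted(report.rows, key=lambda r: (-r.relative_difference, r.compound_id))


def write_report(report: SupplementationReport, path: str | Path) -> None:
    """TSV: compound, baseline, perturbed, relative_difference, mode, delta."""
    df = report.to_frame()
    ranked = rank_report(report)
    order = {r.compound_id: i for i, r in enumerate(ranked)}
    df = df.iloc[df["compound"].map(order).argsort(kind="stable")]
    df.to_csv(Path(path), sep="\t", index=False)
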