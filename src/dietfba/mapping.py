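"""Map compiled-diet compounds to a model's exchange reactions.

Metabolic models expose their environment through exchange pseudo-reactions,
conventionally named ``EX_<metabolite><external suffix>`` where the suffix is
``(e)`` or ``_e`` depending on the model's nomenclature dialect. This module
builds an index from external-metabolite base id to exchange reaction, then
resolves each diet compound against it.

Matching is by exact id after alias expansion — no fuzzy matching, because a
wrong assignment silently corrupts every downstream simulation. Compounds
the model cannot represent are handled by explicit policy: dropped with a
warning, replaced by a chemically related surrogate from a user-supplied
alias table (e.g. nicotinamide -> nicotinate), or treated as a hard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Mapping, Sequence

import pandas as pd

from .medium import CompiledDiet, _read_table, _sep_for

if TYPE_CHECKING:  # avoid import cycle; fba imports this module
    from .fba import MetabolicModel

__all__ = [
    "MetaboliteMapping",
    "MappingError",
    "build_exchange_index",
    "map_diet",
    "read_alias_table",
    "write_alias_table",
    "write_mapping_report",
]

POLICIES = ("drop", "surrogate-then-drop", "fail")


class MappingError(ValueError):
    pass


@dataclass(frozen=True)
class MetaboliteMapping:
    """Resolution of one diet compound against one model."""

    compound_id: str
    exchange_reaction_id: str | None
    status: str  # matched | surrogate | dropped
    note: str = ""

    def __post_init__(self) -> None:
        if self.status not in ("matched", "surrogate", "dropped"):
            raise MappingError(f"invalid mapping status {self.status!r}")
        if self.status in ("matched", "surrogate") and not self.exchange_reaction_id:
            raise MappingError(
                f"{self.compound_id!r}: status {self.status} requires an "
                "exchange reaction id"
            )
        if self.status == "dropped" and self.exchange_reaction_id is not None:
            raise MappingError(
                f"{self.compound_id!r}: dropped mapping must not carry a reaction id"
            )


def _strip_external_suffix(metabolite_id: str, dialect: str) -> str | None:
    """Base compound id of an external metabolite, or None if not external."""
    if dialect == "(e)":
        if metabolite_id.endswith("(e)"):
            return metabolite_id[: -len("(e)")]
        if metabolite_id.endswith("[e]"):
            return metabolite_id[: -len("[e]")]
        return None
    if dialect == "_e":
        return metabolite_id[:-2] if metabolite_id.endswith("_e") else None
    raise MappingError(f"unknown dialect {dialect!r}; use '(e)', '_e' or 'auto'")


def build_exchange_index(model: "MetabolicModel", dialect: str = "auto") -> dict[str, str]:
    """Index external-metabolite base id -> exchange reaction id.

    Covers exactly the model's exchange pseudo-reactions (single
    participating metabolite). ``dialect='auto'`` infers the external-suffix
    convention by majority vote over the exchange metabolites.
    """
    if not model.exchange_reactions:
        raise MappingError(
            "model declares no exchange reactions; if its boundary reactions "
            "use an unusual convention, rebuild the model container with an "
            "explicit exchange list or override the dialect"
        )
    Scsc = model.S.tocsc()
    rxn_met: dict[str, str] = {}
    for rxn in model.exchange_reactions:
        j = model.reaction_index(rxn)
        rows = Scsc.indices[Scsc.indptr[j] : Scsc.indptr[j + 1]]
        if len(rows) != 1:  # not a pure exchange; skip defensively
            continue
        rxn_met[rxn] = model.metabolite_ids[rows[0]]

    if dialect == "auto":
        votes = {"(e)": 0, "_e": 0}
        for met in rxn_met.values():
            if met.endswith("(e)") or met.endswith("[e]"):
                votes["(e)"] += 1
            elif met.endswith("_e"):
                votes["_e"] += 1
        dialect = max(votes, key=votes.get)  # type: ignore[arg-type]
        if votes[dialect] == 0:
            raise MappingError(
                "could not infer the external-compartment dialect: no exchange "
                "metabolite ends with '(e)', '[e]' or '_e'; pass dialect "
                "explicitly"
            )

    index: dict[str, str] = {}
    for rxn, met in sorted(rxn_met.items()):
        base = _strip_external_suffix(met, dialect)
        if base is not None and base not in index:
            index[base] = rxn
    if not index:
        raise MappingError(
            f"no exchange metabolite matched the {dialect!r} dialect; try the "
            "other dialect or 'auto'"
        )
    return index


def map_diet(
    diet: CompiledDiet,
    index: Mapping[str, str],
    alias_table: Mapping[str, str] | None = None,
    policy: str = "surrogate-then-drop",
) -> list[MetaboliteMapping]:
    """Resolve every diet compound to exactly one :class:`MetaboliteMapping`.

    Policies for compounds without a direct match:

    * ``drop`` — drop immediately (aliases ignored), with a warning;
    * ``surrogate-then-drop`` — try the alias table (status ``surrogate``),
      drop if that fails too;
    * ``fail`` — try the alias table, then raise listing *all* unmatched.

    Deterministic and stable under permutation of the diet: output order is
    sorted by compound id.
    """
    if policy not in POLICIES:
        raise MappingError(f"unknown policy {policy!r}; allowed {POLICIES}")
    if not index:
        raise MappingError("empty exchange index")
    alias_table = dict(alias_table or {})

    mappings: list[MetaboliteMapping] = []
    unmatched: list[str] = []
    for cpd in diet.compounds:
        if cpd in index:
            mappings.append(MetaboliteMapping(cpd, index[cpd], "matched"))
            continue
        if policy != "drop" and cpd in alias_table and alias_table[cpd] in index:
            target = alias_table[cpd]
            mappings.append(
                MetaboliteMapping(
                    cpd,
                    index[target],
                    "surrogate",
                    note=f"used related compound {target!r} as surrogate",
                )
            )
            continue
        if policy == "fail":
            unmatched.append(cpd)
            continue
        warnings.warn(
            f"diet compound {cpd!r} has no exchange reaction in the model; dropped",
            stacklevel=2,
        )
        mappings.append(
            MetaboliteMapping(cpd, None, "dropped", note="no exchange reaction in model")
        )
    if unmatched:
        raise MappingError(
            "unmatched diet compounds (policy=fail): " + ", ".join(sorted(unmatched))
        )
    return mappings


# ---------------------------------------------------------------------------
# alias table and report I/O
# ---------------------------------------------------------------------------


def read_alias_table(path: str | Path, dialect: str | None = None) -> dict[str, str]:
    """Read ``compound,alias_of[,relationship]`` rows into a compound->surrogate map."""
    df = _read_table(Path(path), dialect, {"compound", "alias_of"})
    table: dict[str, str] = {}
    for _, row in df.iterrows():
        table[str(row["compound"]).strip()] = str(row["alias_of"]).strip()
    return table


def write_alias_table(
    table: Mapping[str, str], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    rows = [
        {"compound": c, "alias_of": a, "relationship": "surrogate"}
        for c, a in sorted(table.items())
    ]
    pd.DataFrame(rows, columns=["compound", "alias_of", "relationship"]).to_csv(
        path, sep=_sep_for(path, dialect), index=False
    )


def write_mapping_report(
    mappings: Sequence[MetaboliteMapping], path: str | Path
) -> None:
    """TSV report: compound, status, exchange id, note."""
    rows = [
        {
            "compound": m.compound_id,
            "status": m.status,
            "exchange_reaction": m.exchange_reaction_id or "",
            "note": m.note,
        }
        for m in mappings
    ]
    pd.DataFrame(rows, columns=["compound", "status", "exchange_reaction", "note"]).to_csv(
        Path(path), sep="\t", index=False
    )
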