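"""Domain types and tabular I/O for growth media.

A growth medium is described at three levels:

* a :class:`MediumRecipe` — what a protocol sheet says: components (possibly
  chemically complex, e.g. tryptone) with amounts, plus the environmental
  setting (pH, oxygen regime, aqueous or not);
* :class:`ComponentComposition` tables — mass fractions of molecular
  constituents per gram of a complex component, typically taken from
  manufacturer specifications or compositional literature;
* a :class:`CompiledDiet` — the machine-usable product: a flat map from
  molecular compound to concentration in mmol/L, with per-entry provenance
  recording how each number was obtained.

All tabular readers accept CSV and TSV (dialect sniffed from the extension or
overridden explicitly). Amounts are canonicalised at read time: mg/L -> g/L
and mol/L -> mmol/L, so downstream code only ever sees g/L for masses and
mmol/L for molar amounts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Compound",
    "CompoundRegistry",
    "CompositionEntry",
    "ComponentComposition",
    "RecipeItem",
    "MediumRecipe",
    "ProvenanceRecord",
    "CompiledDiet",
    "MediumValidationError",
    "MediumParseError",
    "read_recipe",
    "write_recipe",
    "read_composition_table",
    "write_composition_table",
    "read_compound_registry",
    "read_compiled_diet",
    "write_compiled_diet",
    "MASS_UNITS",
    "MOLAR_UNITS",
    "KNOWN_UNITS",
    "WATER_MW",
    "DEFAULT_AEROBIC_OXYGEN_MMOL_PER_L",
]

#: Molar mass of water, g/mol.
WATER_MW = 18.015

#: Default dissolved-oxygen availability for aerobic aqueous cultures,
#: mmol per litre of medium (uptake-equivalent value measured in E. coli
#: batch cultures; see docs/methods.md).
DEFAULT_AEROBIC_OXYGEN_MMOL_PER_L = 18.2

MASS_UNITS = {"g/L": 1.0, "mg/L": 1e-3}
MOLAR_UNITS = {"mmol/L": 1.0, "mol/L": 1e3}
KNOWN_UNITS = frozenset(MASS_UNITS) | frozenset(MOLAR_UNITS)

#: Sum of mass fractions of one component may exceed 1 by at most this.
MASS_FRACTION_TOL = 1e-6


class MediumValidationError(ValueError):
    """A medium object violates a domain invariant."""


class MediumParseError(ValueError):
    """A tabular medium file could not be parsed."""


# ---------------------------------------------------------------------------
# compounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Compound:
    """A unique molecule or ion with known mass.

    ``molecular_weight`` may be ``None`` for compounds that only ever enter a
    diet in molar units; any mass->molar conversion requires it.
    """

    id: str
    name: str = ""
    molecular_weight: float | None = None
    formula: str | None = None
    charge: int | None = None
    aliases: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.id:
            raise MediumValidationError("compound id must be non-empty")
        if self.molecular_weight is not None and not self.molecular_weight > 0:
            raise MediumValidationError(
                f"compound {self.id!r}: molecular_weight must be > 0, "
                f"got {self.molecular_weight!r}"
            )


class CompoundRegistry:
    """Mapping of compound id -> :class:`Compound`, ids unique."""

    def __init__(self, compounds: Iterable[Compound] = ()) -> None:
        self._by_id: dict[str, Compound] = {}
        for cpd in compounds:
            self.add(cpd)

    def add(self, compound: Compound) -> None:
        if compound.id in self._by_id:
            raise MediumValidationError(f"duplicate compound id {compound.id!r}")
        self._by_id[compound.id] = compound

    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._by_id

    def __getitem__(self, compound_id: str) -> Compound:
        try:
            return self._by_id[compound_id]
        except KeyError:
            raise KeyError(f"unknown compound {compound_id!r}") from None

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._by_id.values())

    def __len__(self) -> int:
        return len(self._by_id)

    def molar_mass(self, compound_id: str) -> float:
        mw = self[compound_id].molecular_weight
        if mw is None:
            raise MediumValidationError(
                f"compound {compound_id!r} has no molecular weight; supply one "
                "in the compound registry to convert its mass to mmol/L"
            )
        return mw


# ---------------------------------------------------------------------------
# component compositions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionEntry:
    compound_id: str
    mass_fraction: float  # g constituent per g component
    source: str = ""

    def __post_init__(self) -> None:
        if self.mass_fraction < 0:
            raise MediumValidationError(
                f"mass fraction for {self.compound_id!r} is negative "
                f"({self.mass_fraction})"
            )


@dataclass
class ComponentComposition:
    """Mass-fraction breakdown of one complex component.

    Invariant: fractions are non-negative and sum to at most 1 (a component
    cannot yield more mass than itself); re-validated after any edit via
    :meth:`validate`.
    """

    component_id: str
    entries: list[CompositionEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        total = sum(e.mass_fraction for e in self.entries)
        if total > 1.0 + MASS_FRACTION_TOL:
            raise MediumValidationError(
                f"component {self.component_id!r}: mass fractions sum to "
                f"{total:.6g} g/g > 1 — a component cannot yield more mass "
                "than itself"
            )

    @property
    def total_mass_fraction(self) -> float:
        return sum(e.mass_fraction for e in self.entries)


# ---------------------------------------------------------------------------
# recipes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecipeItem:
    """One line of a medium recipe.

    ``ingredient`` is either a complex-component id (resolved through a
    composition table) or a compound id (used directly when the ingredient is
    already molecular, e.g. NaCl). ``amount``/``unit`` are canonical: g/L for
    mass, mmol/L for molar amounts.
    """

    ingredient: str
    amount: float
    unit: str  # "g/L" or "mmol/L" after canonicalisation

    def __post_init__(self) -> None:
        if self.unit not in KNOWN_UNITS:
            raise MediumValidationError(
                f"unknown unit {self.unit!r} for {self.ingredient!r}; "
                f"allowed: {sorted(KNOWN_UNITS)}"
            )
        if self.amount < 0:
            raise MediumValidationError(
                f"negative amount {self.amount} for {self.ingredient!r}"
            )

    @staticmethod
    def canonical(ingredient: str, amount: float, unit: str) -> "RecipeItem":
        if unit in MASS_UNITS:
            return RecipeItem(ingredient, amount * MASS_UNITS[unit], "g/L")
        if unit in MOLAR_UNITS:
            return RecipeItem(ingredient, amount * MOLAR_UNITS[unit], "mmol/L")
        raise MediumValidationError(
            f"unknown unit {unit!r} for {ingredient!r}; allowed: {sorted(KNOWN_UNITS)}"
        )


@dataclass
class MediumRecipe:
    """A growth medium as a protocol sheet states it.

    ``oxygen_mmol_per_L = 0`` encodes anaerobic conditions. ``aqueous`` media
    get water injected at compile time.
    """

    items: list[RecipeItem] = field(default_factory=list)
    pH: float = 7.0
    oxygen_mmol_per_L: float = DEFAULT_AEROBIC_OXYGEN_MMOL_PER_L
    aqueous: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.pH <= 14.0:
            raise MediumValidationError(f"pH {self.pH} outside [0, 14]")
        if self.oxygen_mmol_per_L < 0:
            raise MediumValidationError(
                f"oxygen_mmol_per_L must be >= 0, got {self.oxygen_mmol_per_L}"
            )


# ---------------------------------------------------------------------------
# compiled diets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProvenanceRecord:
    """One transformation step that contributed to a diet entry."""

    source: str  # component or mechanism the value came from
    rule: str  # e.g. "decompose", "mass_to_molar", "dissociation", "environment"
    detail: Mapping[str, object] = field(default_factory=dict)

    def to_json_obj(self) -> dict:
        return {"source": self.source, "rule": self.rule, "detail": dict(self.detail)}


class CompiledDiet:
    """Map compound id -> concentration (mmol/L, strictly positive).

    Zero entries are pruned on construction: absence of a compound later
    means its uptake is closed. Every entry carries a non-empty provenance
    trail.
    """

    def __init__(
        self,
        entries: Mapping[str, float],
        provenance: Mapping[str, list[ProvenanceRecord]] | None = None,
    ) -> None:
        provenance = dict(provenance or {})
        self._entries: dict[str, float] = {}
        self._provenance: dict[str, list[ProvenanceRecord]] = {}
        for cpd, conc in entries.items():
            if conc < 0:
                raise MediumValidationError(
                    f"negative concentration {conc} for {cpd!r}"
                )
            if conc == 0:
                continue
            trail = list(provenance.get(cpd, ()))
            if not trail:
                raise MediumValidationError(
                    f"diet entry {cpd!r} has no provenance record"
                )
            self._entries[cpd] = float(conc)
            self._provenance[cpd] = trail

    # -- mapping-ish surface -------------------------------------------------
    def __contains__(self, compound_id: str) -> bool:
        return compound_id in self._entries

    def __getitem__(self, compound_id: str) -> float:
        return self._entries[compound_id]

    def get(self, compound_id: str, default: float = 0.0) -> float:
        return self._entries.get(compound_id, default)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self._entries))

    @property
    def compounds(self) -> list[str]:
        return sorted(self._entries)

    def items(self) -> list[tuple[str, float]]:
        return [(c, self._entries[c]) for c in sorted(self._entries)]

    def provenance(self, compound_id: str) -> list[ProvenanceRecord]:
        return list(self._provenance[compound_id])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompiledDiet):
            return NotImplemented
        return self._entries == other._entries

    def __repr__(self) -> str:
        return f"CompiledDiet({len(self)} compounds)"

    def with_entry(
        self, compound_id: str, concentration: float, record: ProvenanceRecord
    ) -> "CompiledDiet":
        """Return a copy with one entry added/overwritten (provenance appended)."""
        entries = dict(self._entries)
        prov = {c: list(t) for c, t in self._provenance.items()}
        entries[compound_id] = concentration
        prov.setdefault(compound_id, []).append(record)
        return CompiledDiet(entries, prov)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "compound": cpd,
                "concentration_mmol_per_L": conc,
                "provenance_json": json.dumps(
                    [r.to_json_obj() for r in self._provenance[cpd]]
                ),
            }
            for cpd, conc in self.items()
        ]
        return pd.DataFrame(rows, columns=["compound", "concentration_mmol_per_L", "provenance_json"])


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect in ("csv", "CSV"):
        return ","
    if dialect in ("tsv", "TSV"):
        return "\t"
    if dialect not in (None, "infer"):
        raise MediumParseError(f"unknown table dialect {dialect!r}")
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def _read_table(path: str | Path, dialect: str | None, required: set[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep=_sep_for(path, dialect), dtype=str, comment="#")
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=sorted(required))
    df.columns = [c.strip() for c in df.columns]
    missing = required - set(df.columns)
    if missing:
        raise MediumParseError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    return df


def _parse_float(value: object, path: Path, row: int, col: str) -> float:
    try:
        return float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise MediumParseError(
            f"{path}, row {row}: cannot parse {col}={value!r} as a number"
        ) from None


def read_recipe(
    path: str | Path,
    dialect: str | None = None,
    sidecar: str | Path | None = None,
) -> MediumRecipe:
    """Read a medium recipe table (``component,amount,unit``).

    Environmental settings come from extra columns ``pH`` /
    ``oxygen_mmol_per_L`` / ``aqueous`` (constant per file) or from a
    YAML/JSON sidecar file; the sidecar wins over extra columns. A sidecar
    named ``<recipe>.env.yaml`` next to the recipe is picked up automatically.
    """
    path = Path(path)
    df = _read_table(path, dialect, {"component", "amount", "unit"})

    env: dict[str, object] = {}
    for col in ("pH", "oxygen_mmol_per_L", "aqueous"):
        if col in df.columns and len(df) and df[col].notna().any():
            vals = df[col].dropna().unique()
            if len(vals) > 1:
                raise MediumParseError(
                    f"{path}: environment column {col!r} not constant: {list(vals)}"
                )
            env[col] = vals[0]

    auto_sidecar = path.with_suffix(path.suffix + ".env.yaml")
    if sidecar is None and auto_sidecar.exists():
        sidecar = auto_sidecar
    if sidecar is not None:
        with open(sidecar) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise MediumParseError(f"{sidecar}: environment sidecar must be a mapping")
        env.update(loaded)

    items: list[RecipeItem] = []
    for i, row in df.iterrows():
        ingredient = row["component"]
        if pd.isna(ingredient) or not str(ingredient).strip():
            raise MediumParseError(f"{path}, row {i}: empty component name")
        amount = _parse_float(row["amount"], path, int(i), "amount")
        unit = str(row["unit"]).strip()
        if unit not in KNOWN_UNITS:
            raise MediumParseError(
                f"{path}, row {i}: unknown unit {unit!r}; allowed {sorted(KNOWN_UNITS)}"
            )
        if amount < 0:
            raise MediumValidationError(
                f"{path}, row {i}: negative amount {amount} for {ingredient!r}"
            )
        items.append(RecipeItem.canonical(str(ingredient).strip(), amount, unit))

    kwargs: dict[str, object] = {}
    if "pH" in env:
        kwargs["pH"] = float(env["pH"])  # type: ignore[arg-type]
    if "oxygen_mmol_per_L" in env:
        kwargs["oxygen_mmol_per_L"] = float(env["oxygen_mmol_per_L"])  # type: ignore[arg-type]
    if "aqueous" in env:
        raw = env["aqueous"]
        kwargs["aqueous"] = (
            raw if isinstance(raw, bool) else str(raw).strip().lower() in ("true", "1", "yes")
        )
    return MediumRecipe(items=items, name=path.stem, **kwargs)  # type: ignore[arg-type]


def write_recipe(recipe: MediumRecipe, path: str | Path, dialect: str | None = None) -> None:
    """Write a recipe table plus its environment sidecar (round-trips read_recipe)."""
    path = Path(path)
    sep = _sep_for(path, dialect)
    df = pd.DataFrame(
        [{"component": it.ingredient, "amount": it.amount, "unit": it.unit} for it in recipe.items],
        columns=["component", "amount", "unit"],
    )
    df.to_csv(path, sep=sep, index=False)
    env = {
        "pH": recipe.pH,
        "oxygen_mmol_per_L": recipe.oxygen_mmol_per_L,
        "aqueous": recipe.aqueous,
    }
    with open(path.with_suffix(path.suffix + ".env.yaml"), "w") as fh:
        yaml.safe_dump(env, fh)


def read_composition_table(
    path: str | Path, dialect: str | None = None
) -> list[ComponentComposition]:
    """Read ``component,compound,mass_fraction,source`` rows into compositions.

    One :class:`ComponentComposition` per distinct component, in order of
    first appearance; fraction sums validated per component.
    """
    path = Path(path)
    df = _read_table(path, dialect, {"component", "compound", "mass_fraction"})
    if "source" not in df.columns:
        df["source"] = ""
    grouped: dict[str, list[CompositionEntry]] = {}
    for i, row in df.iterrows():
        frac = _parse_float(row["mass_fraction"], path, int(i), "mass_fraction")
        entry = CompositionEntry(
            compound_id=str(row["compound"]).strip(),
            mass_fraction=frac,
            source="" if pd.isna(row["source"]) else str(row["source"]),
        )
        grouped.setdefault(str(row["component"]).strip(), []).append(entry)
    return [ComponentComposition(comp, entries) for comp, entries in grouped.items()]


def write_composition_table(
    compositions: Iterable[ComponentComposition], path: str | Path, dialect: str | None = None
) -> None:
    path = Path(path)
    rows = [
        {
            "component": comp.component_id,
            "compound": e.compound_id,
            "mass_fraction": e.mass_fraction,
            "source": e.source,
        }
        for comp in compositions
        for e in comp.entries
    ]
    pd.DataFrame(rows, columns=["component", "compound", "mass_fraction", "source"]).to_csv(
        path, sep=_sep_for(path, dialect), index=False
    )


def read_compound_registry(path: str | Path, dialect: str | None = None) -> CompoundRegistry:
    """Read a compound registry table (``id,name,molecular_weight[,formula,charge,aliases]``).

    ``aliases`` is a ``|``-separated list.
    """
    path = Path(path)
    df = _read_table(path, dialect, {"id"})
    registry = CompoundRegistry()
    for i, row in df.iterrows():
        mw = None
        if "molecular_weight" in df.columns and not pd.isna(row.get("molecular_weight")):
            mw = _parse_float(row["molecular_weight"], path, int(i), "molecular_weight")
        charge = None
        if "charge" in df.columns and not pd.isna(row.get("charge")):
            charge = int(float(row["charge"]))
        aliases: tuple[str, ...] = ()
        if "aliases" in df.columns and not pd.isna(row.get("aliases")):
            aliases = tuple(a for a in str(row["aliases"]).split("|") if a)
        registry.add(
            Compound(
                id=str(row["id"]).strip(),
                name="" if "name" not in df.columns or pd.isna(row.get("name")) else str(row["name"]),
                molecular_weight=mw,
                formula=None
                if "formula" not in df.columns or pd.isna(row.get("formula"))
                else str(row["formula"]),
                charge=charge,
                aliases=aliases,
            )
        )
    return registry


def write_compiled_diet(diet: CompiledDiet, path: str | Path) -> None:
    """Write a compiled diet as TSV ``compound, concentration_mmol_per_L, provenance_json``."""
    diet.to_frame().to_csv(Path(path), sep="\t", index=False)


def read_compiled_diet(path: str | Path) -> CompiledDiet:
    df = _read_table(Path(path), "tsv", {"compound", "concentration_mmol_per_L"})
    entries: dict[str, float] = {}
    prov: dict[str, list[ProvenanceRecord]] = {}
    for i, row in df.iterrows():
        cpd = str(row["compound"]).strip()
        entries[cpd] = _parse_float(
            row["concentration_mmol_per_L"], Path(path), int(i), "concentration_mmol_per_L"
        )
        if "provenance_json" in df.columns and not pd.isna(row.get("provenance_json")):
            prov[cpd] = [
                ProvenanceRecord(r["source"], r["rule"], r.get("detail", {}))
                for r in json.loads(row["provenance_json"])
            ]
        else:
            prov[cpd] = [ProvenanceRecord(source="file", rule="loaded", detail={"path": str(path)})]
    return CompiledDiet(entries, prov)
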