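"""Protein-anchored standard diet and worst-case residue intake.

The exposure model: build a one-day diet of animal-origin foods whose total
protein roughly meets the EFSA Population Reference Intake (PRI, 0.83 g
protein per kg body weight per day for a 30-year-old adult), then assume
every consumed matrix carries antimicrobial residue exactly at its MRL.
The residue intake from each portion is then

    intake (µg/day) = MRL (µg/kg) x portion mass (kg),

summed per substance and divided by consumer body weight to give a
worst-case dietary dose in µg/kg bw/day.  Only matrices commonly eaten
(muscle, milk, eggs) enter the exposure; liver, fat and kidney, though they
carry MRLs, are excluded at the diet layer.

All arithmetic is exact; rounding (half-up, 2 decimals for per-kg doses,
1 decimal for µg totals) happens only when a report is rendered.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from os import PathLike
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from ._round import round_half_up
from .mrl import Matrix, MatrixNotPermittedError, MrlLookupError, MrlRegistry

__all__ = [
    "FoodItem",
    "FoodTable",
    "Portion",
    "Diet",
    "ProteinAssessment",
    "ResidueIntakeReport",
    "DietMatrixError",
    "EXPOSURE_MATRICES",
    "DEFAULT_PRI",
    "load_food_table",
    "load_diet",
    "protein_requirement",
    "diet_protein",
    "worst_case_intake",
    "bundled_food_table",
    "bundled_diet",
]

#: Matrices admitted into the dietary exposure (liver, fat, kidney excluded
#: as rarely eaten).
EXPOSURE_MATRICES = frozenset({Matrix.MUSCLE, Matrix.MILK, Matrix.EGGS})

#: EFSA PRI for protein, g per kg body weight per day (30-year-old adult).
DEFAULT_PRI = 0.83


class DietMatrixError(ValueError):
    """A diet portion maps to a matrix outside the exposure whitelist."""


@dataclass(frozen=True)
class FoodItem:
    food_id: str
    label: str
    matrix: Matrix
    protein_per_100g: float  # g protein per 100 g edible part

    def __post_init__(self) -> None:
        if not 0 <= self.protein_per_100g <= 100:
            raise ValueError(f"{self.food_id}: protein_per_100g outside [0, 100]")


class FoodTable:
    """Food-composition lookup: food_id -> :class:`FoodItem`."""

    def __init__(self, items: Iterable[FoodItem] = ()) -> None:
        self._items: dict[str, FoodItem] = {}
        for it in items:
            if it.food_id in self._items:
                raise ValueError(f"duplicate food_id {it.food_id!r}")
            self._items[it.food_id] = it

    def __getitem__(self, food_id: str) -> FoodItem:
        try:
            return self._items[food_id]
        except KeyError:
            raise KeyError(f"unknown food_id {food_id!r}") from None

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._items

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items.values())


@dataclass(frozen=True)
class Portion:
    food_id: str
    mass: float  # g edible part

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"{self.food_id}: portion mass must be > 0")


@dataclass(frozen=True)
class Diet:
    portions: tuple[Portion, ...]
    consumer_bw: float  # kg

    def __post_init__(self) -> None:
        if self.consumer_bw <= 0:
            raise ValueError("consumer body weight must be > 0")
        object.__setattr__(self, "portions", tuple(self.portions))

    def scaled(self, factor: float) -> "Diet":
        """Diet with every portion mass multiplied by ``factor``."""
        return Diet(
            tuple(Portion(p.food_id, p.mass * factor) for p in self.portions),
            self.consumer_bw,
        )


@dataclass(frozen=True)
class ProteinAssessment:
    total_protein: float  # g/day
    requirement: float    # g/day
    surplus: float        # g/day, total - requirement


@dataclass
class ResidueIntakeReport:
    """Worst-case residue intake, exact values plus display rounding.

    ``per_item`` maps (food_id, substance) to µg/day; pairs where the
    substance is not permitted in the food's matrix (e.g. sulfonamides in
    eggs) contribute nothing and are listed in ``non_applicable``.
    """

    per_item: dict[tuple[str, str], float]
    per_substance_total: dict[str, float]
    grand_total: float
    per_kg_dose: dict[str, float]       # exact, µg/kg bw/day
    consumer_bw: float
    non_applicable: set[tuple[str, str]] = field(default_factory=set)

    def per_kg_dose_rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Per-kg doses rounded half-up — the values a report prints."""
        return {s: round_half_up(v, ndigits) for s, v in self.per_kg_dose.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of per-item intakes (µg/day, 1 decimal)."""
        rows = [
            {"food_id": f, "substance": s, "intake_ug_per_day": round_half_up(v, 1)}
            for (f, s), v in self.per_item.items()
        ]
        for f, s in sorted(self.non_applicable):
            rows.append({"food_id": f, "substance": s, "intake_ug_per_day": None})
        return pd.DataFrame(rows, columns=["food_id", "substance", "intake_ug_per_day"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substance": s,
                "total_ug_per_day": round_half_up(t, 1),
                "per_kg_dose_ug": round_half_up(self.per_kg_dose[s], 2),
            }
            for s, t in self.per_substance_total.items()
        ]
        return pd.DataFrame(rows, columns=["substance", "total_ug_per_day", "per_kg_dose_ug"])


def protein_requirement(bw: float, pri: float = DEFAULT_PRI) -> float:
    """Daily protein requirement in g/day: body weight (kg) x PRI (g/kg/day)."""
    if bw <= 0:
        raise ValueError("body weight must be > 0")
    if pri < 0:
        raise ValueError("PRI must be >= 0")
    return bw * pri


def diet_protein(diet: Diet, foods: FoodTable, pri: float = DEFAULT_PRI) -> ProteinAssessment:
    """Total protein of a diet against the PRI-derived requirement."""
    total = sum(p.mass * foods[p.food_id].protein_per_100g / 100.0 for p in diet.portions)
    req = protein_requirement(diet.consumer_bw, pri)
    return ProteinAssessment(total_protein=total, requirement=req, surplus=total - req)


def worst_case_intake(
    diet: Diet,
    foods: FoodTable,
    registry: MrlRegistry,
    substances: Sequence[str],
) -> ResidueIntakeReport:
    """Residue intake assuming every matrix is contaminated at its MRL.

    Raises :class:`DietMatrixError` for portions whose matrix lies outside
    the exposure whitelist.  A (substance, matrix) pair the regulation
    forbids contributes zero and is recorded as non-applicable; an
    unregistered pair is an error.
    """
    per_item: dict[tuple[str, str], float] = {}
    non_applicable: set[tuple[str, str]] = set()
    totals: dict[str, float] = {s: 0.0 for s in substances}

    for portion in diet.portions:
        item = foods[portion.food_id]
        if item.matrix not in EXPOSURE_MATRICES:
            raise DietMatrixError(
                f"portion {portion.food_id!r}: matrix {item.matrix.value!r} is outside "
                f"the exposure whitelist {sorted(m.value for m in EXPOSURE_MATRICES)}"
            )
        mass_kg = portion.mass / 1000.0
        for substance in substances:
            try:
                limit = registry.lookup(substance, item.matrix)
            except MatrixNotPermittedError:
                non_applicable.add((portion.food_id, substance))
                continue
            intake = limit * mass_kg  # µg/kg x kg = µg/day
            per_item[(portion.food_id, substance)] = (
                per_item.get((portion.food_id, substance), 0.0) + intake
            )
            totals[substance] += intake

    grand_total = sum(totals.values())
    per_kg = {s: t / diet.consumer_bw for s, t in totals.items()}
    return ResidueIntakeReport(
        per_item=per_item,
        per_substance_total=totals,
        grand_total=grand_total,
        per_kg_dose=per_kg,
        consumer_bw=diet.consumer_bw,
        non_applicable=non_applicable,
    )


def load_food_table(path: str | PathLike) -> FoodTable:
    """Read a delimited food-composition table.

    Header: ``food_id, label, matrix, protein_per_100g`` (tab/comma
    autodetected).
    """
    df = pd.read_csv(path, sep=None, engine="python")
    items = [
        FoodItem(
            food_id=str(r["food_id"]).strip(),
            label=str(r["label"]).strip(),
            matrix=Matrix(str(r["matrix"]).strip()),
            protein_per_100g=float(r["protein_per_100g"]),
        )
        for _, r in df.iterrows()
    ]
    return FoodTable(items)


def load_diet(path: str | PathLike) -> tuple[Diet, float]:
    """Read a diet config (YAML): returns (diet, pri).

    Keys: ``consumer_bw_kg``, optional ``pri_g_per_kg`` and a ``portions``
    list of ``{food_id, mass_g}`` (or ``{food_id, mass_g, count}`` where
    count is a convenience multiplier for unit foods like eggs).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    portions = tuple(
        Portion(str(p["food_id"]), float(p["mass_g"]) * float(p.get("count", 1)))
        for p in cfg["portions"]
    )
    diet = Diet(portions=portions, consumer_bw=float(cfg["consumer_bw_kg"]))
    return diet, float(cfg.get("pri_g_per_kg", DEFAULT_PRI))


def bundled_food_table() -> FoodTable:
    """CREA-derived protein contents for the bundled foods."""
    ref = importlib.resources.files("residose.data") / "foods_crea.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_food_table(p)


def bundled_diet() -> tuple[Diet, float]:
    """The standard 453 g one-day diet for a 60 kg adult (milk, egg, meat, fish)."""
    ref = importlib.resources.files("residose.data") / "diet_standard.yaml"
    with importlib.resources.as_file(ref) as p:
        return load_diet(p)
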