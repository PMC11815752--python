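"""Maximum residue limit (MRL) registry.

Encodes an extract of Commission Regulation (EU) No 37/2010 — the MRLs for
chlortetracycline and for the sulfonamide group across edible matrices —
as a queryable registry.  Each entry carries the regulation's side
provisions as flags:

* ``fin_fish_muscle_skin`` — for fin fish the muscle MRL applies to
  "muscle and skin in natural proportions";
* ``class_combined_total`` — the limit applies to the combined total of all
  substances in the class (the sulfonamide group total of 100 µg/kg);
* ``not_for_egg_producers`` — the substance must not be used in animals
  producing eggs for human consumption, so no egg MRL exists;
* ``mrl_not_for_fin_fish`` — the tissue MRL does not apply to fin fish.

All limits are stored in µg residue per kg matrix; an input column in
mg/kg is converted at parse time.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from enum import Enum
from os import PathLike
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Matrix",
    "SubstanceClass",
    "Provision",
    "ResidueLimit",
    "MrlRegistry",
    "MrlParseError",
    "MrlLookupError",
    "MatrixNotPermittedError",
    "load_mrl_table",
    "write_mrl_table",
    "bundled_registry",
]


class Matrix(str, Enum):
    """Edible matrix to which a residue limit applies."""

    MUSCLE = "muscle"
    FAT = "fat"
    LIVER = "liver"
    KIDNEY = "kidney"
    MILK = "milk"
    EGGS = "eggs"


class SubstanceClass(str, Enum):
    TETRACYCLINE = "tetracycline"
    SULFONAMIDE = "sulfonamide"
    OTHER = "other"


class Provision(str, Enum):
    FIN_FISH_MUSCLE_SKIN = "fin_fish_muscle_skin"
    CLASS_COMBINED_TOTAL = "class_combined_total"
    NOT_FOR_EGG_PRODUCERS = "not_for_egg_producers"
    MRL_NOT_FOR_FIN_FISH = "mrl_not_for_fin_fish"


class MrlParseError(ValueError):
    """Malformed MRL table row."""


class MrlLookupError(LookupError):
    """No limit registered for the requested (substance, matrix) pair."""


class MatrixNotPermittedError(MrlLookupError):
    """The substance may not legally occur in the requested matrix."""


@dataclass(frozen=True)
class ResidueLimit:
    """One regulatory limit: substance x matrix -> µg/kg, plus provisions."""

    substance_id: str
    substance_class: SubstanceClass
    matrix: Matrix
    limit: float  # µg residue per kg matrix
    provisions: frozenset[Provision] = field(default_factory=frozenset)
    marker_residue: str = ""
    species_scope: str = "All food-producing species"

    def __post_init__(self) -> None:
        if self.limit < 0:
            raise ValueError(f"negative limit for {self.substance_id}/{self.matrix.value}")

    @property
    def class_combined(self) -> bool:
        """True when the limit applies to the class sum, not each congener."""
        return Provision.CLASS_COMBINED_TOTAL in self.provisions


class MrlRegistry:
    """Queryable collection of :class:`ResidueLimit` entries.

    ``(substance, matrix)`` pairs are unique; lookup of an unregistered pair
    raises, and lookup of a pair the regulation forbids (sulfonamides in
    eggs) raises :class:`MatrixNotPermittedError`.
    """

    def __init__(self, entries: Iterable[ResidueLimit] = ()) -> None:
        self._entries: dict[tuple[str, Matrix], ResidueLimit] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ResidueLimit) -> None:
        key = (entry.substance_id, entry.matrix)
        if key in self._entries:
            raise MrlParseError(
                f"duplicate (substance, matrix) pair: {entry.substance_id}/{entry.matrix.value}"
            )
        self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries.values())

    @property
    def entries(self) -> list[ResidueLimit]:
        return list(self._entries.values())

    def substances(self) -> list[str]:
        return sorted({s for s, _ in self._entries})

    def get(self, substance: str, matrix: Matrix | str) -> ResidueLimit:
        matrix = Matrix(matrix)
        if matrix is Matrix.EGGS:
            # a substance barred from egg-producing animals has no egg MRL
            for (sub, _), e in self._entries.items():
                if sub == substance and Provision.NOT_FOR_EGG_PRODUCERS in e.provisions:
                    raise MatrixNotPermittedError(
                        f"{substance} is not for use in animals producing eggs "
                        "for human consumption: matrix not permitted"
                    )
        try:
            return self._entries[(substance, matrix)]
        except KeyError:
            raise MrlLookupError(
                f"no MRL registered for ({substance}, {matrix.value})"
            ) from None

    def lookup(self, substance: str, matrix: Matrix | str) -> float:
        """Return the limit in µg/kg.

        For entries flagged ``class_combined_total`` the returned value
        applies to the summed residues of the whole substance class.
        """
        return self.get(substance, matrix).limit

    def is_permitted(self, substance: str, matrix: Matrix | str) -> bool:
        try:
            self.get(substance, matrix)
            return True
        except MatrixNotPermittedError:
            return False
        except MrlLookupError:
            return True  # merely unregistered, not forbidden

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "substance": e.substance_id,
                "class": e.substance_class.value,
                "matrix": e.matrix.value,
                "limit_ug_per_kg": e.limit,
                "provisions": ";".join(sorted(p.value for p in e.provisions)),
            }
            for e in self._entries.values()
        ]
        return pd.DataFrame(rows, columns=["substance", "class", "matrix", "limit_ug_per_kg", "provisions"])


def _parse_provisions(raw: object, row: int) -> frozenset[Provision]:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)) or raw == "":
        return frozenset()
    try:
        return frozenset(Provision(tok.strip()) for tok in str(raw).split(";") if tok.strip())
    except ValueError as exc:
        raise MrlParseError(f"row {row}: unknown provision flag in {raw!r}") from exc


def load_mrl_table(path: str | PathLike) -> MrlRegistry:
    """Read a delimited-text MRL table into a registry.

    Expected header: ``substance, class, matrix, limit_ug_per_kg, provisions``
    (tab or comma separated, autodetected; provisions semicolon-joined,
    may be empty).  A ``limit_mg_per_kg`` column is accepted instead of
    ``limit_ug_per_kg`` and converted (×1000) at parse time.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip() for c in df.columns]
    if "limit_ug_per_kg" in df.columns:
        limits = df["limit_ug_per_kg"].astype(float)
    elif "limit_mg_per_kg" in df.columns:
        limits = df["limit_mg_per_kg"].astype(float) * 1000.0
    else:
        raise MrlParseError("missing limit_ug_per_kg (or limit_mg_per_kg) column")
    required = {"substance", "class", "matrix"}
    if missing := required - set(df.columns):
        raise MrlParseError(f"missing columns: {sorted(missing)}")

    registry = MrlRegistry()
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        try:
            matrix = Matrix(str(row["matrix"]).strip())
        except ValueError:
            raise MrlParseError(f"row {rowno}: unknown matrix {row['matrix']!r}") from None
        limit = float(limits.loc[i])
        if limit < 0:
            raise MrlParseError(f"row {rowno}: negative limit {limit}")
        try:
            sclass = SubstanceClass(str(row["class"]).strip())
        except ValueError:
            sclass = SubstanceClass.OTHER
        entry = ResidueLimit(
            substance_id=str(row["substance"]).strip(),
            substance_class=sclass,
            matrix=matrix,
            limit=limit,
            provisions=_parse_provisions(row.get("provisions"), rowno),
        )
        try:
            registry.add(entry)
        except MrlParseError as exc:
            raise MrlParseError(f"row {rowno}: {exc}") from None
    return registry


def write_mrl_table(registry: MrlRegistry, path: str | PathLike) -> None:
    """Write a registry back to tab-separated text (round-trips with load)."""
    df = registry.to_frame()
    df["limit_ug_per_kg"] = df["limit_ug_per_kg"].map(
        lambda v: int(v) if float(v).is_integer() else v
    )
    df.to_csv(path, sep="\t", index=False)


def bundled_registry() -> MrlRegistry:
    """Registry for the Reg. 37/2010 extract bundled with the package.

    Covers chlortetracycline (muscle 100, liver 300, kidney 600, milk 100,
    eggs 200 µg/kg) and the sulfonamide class total (100 µg/kg in muscle,
    fat, liver, kidney and milk; no egg MRL — not for egg producers).
    """
    ref = importlib.resources.files("residose.data") / "mrl_reg37_2010.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_mrl_table(p)
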