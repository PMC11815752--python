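"""Interspecies dose translation by body-surface-area (Km) scaling.

The standard FDA conversion between species uses Km factors (body weight
divided by body surface area):

    HED (µg/kg/day) = animal dose (µg/kg/day) x Km_animal / Km_human

with Km = 3 for mouse and 37 for an adult human.  Inverting gives the
animal dose matching a human dietary dose:

    animal dose = HED x Km_human / Km_animal

A human worst-case dietary dose of 0.84 µg/kg/day therefore maps to a
mouse dose of 0.84 x 37/3 = 10.36 -> 10.4 µg/kg/day (half-up, 1 decimal).

Also provided: the drinking-water administration calculator that turns a
per-kg dose into a bottle concentration, given mean body weight, daily
water intake, bottle volume and refill interval.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._round import round_half_up

__all__ = [
    "KM_FACTORS",
    "KmFactor",
    "DoseSpec",
    "WaterDosing",
    "hed_from_animal",
    "animal_from_hed",
    "drinking_water_concentration",
]

#: Default Km factors (bw/BSA); only mouse and human ship, others may be
#: registered by the caller.
KM_FACTORS: dict[str, float] = {"mouse": 3.0, "human": 37.0}


@dataclass(frozen=True)
class KmFactor:
    species: str
    km: float

    def __post_init__(self) -> None:
        if self.km <= 0:
            raise ValueError("Km factor must be > 0")


@dataclass(frozen=True)
class DoseSpec:
    """A dose assigned to a species, µg per kg body weight per day."""

    substance: str
    species: str
    dose: float

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


@dataclass(frozen=True)
class WaterDosing:
    """Drinking-water administration report for one dose level."""

    daily_amount_ug: float          # per animal per day
    concentration_ug_per_ml: float
    per_bottle_amount_ug: float     # substance dissolved per bottle fill
    required_volume_ml: float       # consumption over the refill interval
    bottle_volume_ml: float
    feasible: bool                  # bottle covers the refill interval

    @property
    def warning(self) -> str | None:
        if self.feasible:
            return None
        return (
            f"required consumption {self.required_volume_ml:g} mL over the refill "
            f"interval exceeds bottle volume {self.bottle_volume_ml:g} mL"
        )


def _check_km(km_animal: float, km_human: float) -> None:
    if km_animal <= 0 or km_human <= 0:
        raise ValueError("Km factors must be > 0")


def hed_from_animal(animal_dose: float, km_animal: float = 3.0, km_human: float = 37.0) -> float:
    """Human equivalent dose from an animal dose, unrounded."""
    _check_km(km_animal, km_human)
    if animal_dose < 0:
        raise ValueError("dose must be >= 0")
    return animal_dose * km_animal / km_human


def animal_from_hed(
    hed: float,
    km_animal: float = 3.0,
    km_human: float = 37.0,
    round_to: int | None = 1,
    substance: str = "",
    species: str = "mouse",
) -> DoseSpec:
    """Animal dose matching a human equivalent dose.

    ``round_to`` decimals, half-up (default 1, matching dosing practice);
    pass ``None`` for the unrounded value.
    """
    _check_km(km_animal, km_human)
    if hed < 0:
        raise ValueError("dose must be >= 0")
    dose = hed * km_human / km_animal
    if round_to is not None:
        dose = round_half_up(dose, round_to)
    return DoseSpec(substance=substance, species=species, dose=dose)


def drinking_water_concentration(
    dose: float,
    mean_bw: float = 25.0,
    water_intake: float = 5.0,
    bottle_volume: float = 200.0,
    refill_days: float = 3.0,
    n_animals: int = 7,
) -> WaterDosing:
    """Translate a per-kg dose into a drinking-water concentration.

    Parameters
    ----------
    dose : µg per kg body weight per day.
    mean_bw : mean animal body weight, g.
    water_intake : daily water intake per animal, mL.
    bottle_volume : volume of one bottle fill, mL.
    refill_days : days between bottle changes.
    n_animals : animals drinking from the bottle.

    The report flags infeasibility when the cage's consumption over the
    refill interval exceeds the bottle volume.
    """
    if min(mean_bw, water_intake, bottle_volume, refill_days) <= 0 or n_animals <= 0:
        raise ValueError("all administration parameters must be > 0")
    if dose < 0:
        raise ValueError("dose must be >= 0")
    daily = dose * mean_bw / 1000.0           # µg/animal/day
    conc = daily / water_intake               # µg/mL
    per_bottle = conc * bottle_volume         # µg dissolved per fill
    required = water_intake * refill_days * n_animals
    return WaterDosing(
        daily_amount_ug=daily,
        concentration_ug_per_ml=conc,
        per_bottle_amount_ug=per_bottle,
        required_volume_ml=required,
        bottle_volume_ml=bottle_volume,
        feasible=required <= bottle_volume,
    )
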