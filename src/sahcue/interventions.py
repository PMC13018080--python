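"""Acquisition costing of existing and candidate drug regimens.

Reproduces per-day and per-course costs from unit prices (NADAC 2025;
AWP for 25% albumin, which NADAC does not list) and fixed dosing rules.
All arithmetic is exact ``Decimal`` cents so the published two-decimal
figures are regenerated bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal

from .errors import DomainError
from .money import cents

# IV clazosentan is quoted as a lump-sum course price in the Japanese
# market; both dollar figures are carried, linked by the implied
# 2023->2025 inflation factor (no FX modelling).
CLAZOSENTAN_JPY = 2_215_691
CLAZOSENTAN_USD_2023 = 15_332.03
CLAZOSENTAN_USD_2025 = 16_280.15


@dataclass(frozen=True)
class DosingRegimen:
    """Fixed-schedule drug: unit cost x units/day x duration."""

    name: str
    unit_cost: Decimal
    units_per_day: int
    duration_days: int
    notes: str = ""

    def __post_init__(self) -> None:
        if self.unit_cost < 0 or self.units_per_day < 0 or self.duration_days < 0:
            raise DomainError(f"regimen '{self.name}' has negative dosing fields")


@dataclass(frozen=True)
class AlbuminDosing:
    """IV 25% albumin: whole bags are dispensed per weight-based dose."""

    name: str = "albumin"
    dose_g_per_kg: float = 1.25
    weight_kg: float = 80.0
    bag_g: float = 12.5
    bag_cost: Decimal = Decimal("55.87")
    n_doses: int = 1
    notes: str = ""

    def __post_init__(self) -> None:
        if self.bag_cost < 0 or self.n_doses < 0 or self.dose_g_per_kg < 0 or self.weight_kg < 0:
            raise DomainError(f"albumin dosing '{self.name}' has negative fields")


@dataclass(frozen=True)
class PricedRegimen:
    """Regimen quoted only as a lump-sum course price (e.g. clazosentan)."""

    name: str
    total_cost: Decimal
    notes: str = ""


@dataclass(frozen=True)
class ComboRegimen:
    name: str
    components: tuple = field(default_factory=tuple)
    notes: str = ""


Regimen = DosingRegimen | AlbuminDosing | PricedRegimen | ComboRegimen


def albumin_bags(a: AlbuminDosing) -> int:
    """Whole bags dispensed per dose (dose is rounded up to full bags)."""
    if a.bag_g <= 0:
        raise DomainError("bag size must be > 0")
    grams = a.dose_g_per_kg * a.weight_kg
    if grams == 0:
        return 0
    return math.ceil(grams / a.bag_g - 1e-9)


def unit_cost_of(r: Regimen) -> Decimal:
    if isinstance(r, DosingRegimen):
        return cents(r.unit_cost)
    if isinstance(r, AlbuminDosing):
        return cents(r.bag_cost)
    if isinstance(r, PricedRegimen):
        return cents(r.total_cost)
    raise DomainError(f"'{r.name}' has no single dosing-unit cost")


def regimen_cost(r: Regimen) -> tuple[Decimal, Decimal]:
    """(cost per day, cost for the full course), exact to the cent."""
    if isinstance(r, DosingRegimen):
        per_day = cents(r.unit_cost * r.units_per_day)
        return per_day, cents(per_day * r.duration_days)
    if isinstance(r, AlbuminDosing):
        per_day = cents(r.bag_cost * albumin_bags(r))
        return per_day, cents(per_day * r.n_doses)
    if isinstance(r, PricedRegimen):
        total = cents(r.total_cost)
        return total, total
    if isinstance(r, ComboRegimen):
        _, per_day, total = combo_cost(list(r.components))
        return per_day, total
    raise DomainError(f"unknown regimen type {type(r).__name__}")


def combo_cost(regimens: list[Regimen]) -> tuple[Decimal, Decimal, Decimal]:
    """Component-wise sums: (per dosing unit, per day, per course).

    The per-unit column adds heterogeneous units (tablet + bag); it is a
    display convention carried over from the source table, not a price of
    any dispensable unit.
    """
    per_unit = per_day = total = Decimal("0.00")
    for r in regimens:
        per_unit += unit_cost_of(r)
        d, t = regimen_cost(r)
        per_day += d
        total += t
    return cents(per_unit), cents(per_day), cents(total)


_SINGLES: dict[str, Regimen] = {
    "cilostazol-200": DosingRegimen(
        "cilostazol-200", Decimal("0.13"), 2, 14, "100 mg tablet, 200 mg/day x 14 days"
    ),
    "cilostazol-300": DosingRegimen(
        "cilostazol-300", Decimal("0.13"), 3, 14, "100 mg tablet, 300 mg/day x 14 days"
    ),
    "nimodipine": DosingRegimen(
        "nimodipine", Decimal("1.09"), 12, 21, "30 mg capsule, 60 mg every 4 h x 21 days"
    ),
    "albumin-1": AlbuminDosing(name="albumin-1", n_doses=1, notes="IV 25% albumin, 1.25 g/kg x 1 dose"),
    "albumin-7": AlbuminDosing(name="albumin-7", n_doses=7, notes="IV 25% albumin, 1.25 g/kg x 7 doses"),
    "clazosentan": PricedRegimen(
        "clazosentan", Decimal("16280.15"), "IV clazosentan course, USD 2025 (JPY market price)"
    ),
}

_COMBOS = {
    "cilostazol-200+albumin-1": ("cilostazol-200", "albumin-1"),
    "cilostazol-200+albumin-1+nimodipine": ("cilostazol-200", "albumin-1", "nimodipine"),
    "cilostazol-300+albumin-7": ("cilostazol-300", "albumin-7"),
}


def default_catalog() -> dict[str, Regimen]:
    catalog: dict[str, Regimen] = dict(_SINGLES)
    for name, parts in _COMBOS.items():
        catalog[name] = ComboRegimen(name, tuple(catalog[p] for p in parts))
    return catalog


def default_catalog_config() -> dict:
    """Catalog serialized for the config file (see parameters.RegimenConfig)."""
    from .parameters import RegimenConfig  # late: parameters imports this module

    out: dict[str, RegimenConfig] = {}
    for name, r in default_catalog().items():
        if isinstance(r, DosingRegimen):
            out[name] = RegimenConfig(
                kind="fixed",
                unit_cost=float(r.unit_cost),
                units_per_day=r.units_per_day,
                duration_days=r.duration_days,
                notes=r.notes,
            )
        elif isinstance(r, AlbuminDosing):
            out[name] = RegimenConfig(
                kind="albumin",
                unit_cost=float(r.bag_cost),
                dose_g_per_kg=r.dose_g_per_kg,
                weight_kg=r.weight_kg,
                bag_g=r.bag_g,
                n_doses=r.n_doses,
                notes=r.notes,
            )
        elif isinstance(r, PricedRegimen):
            out[name] = RegimenConfig(kind="priced", total_cost=float(r.total_cost), notes=r.notes)
        else:
            out[name] = RegimenConfig(kind="combo", components=list(c.name for c in r.components), notes=r.notes)
    return out


def catalog_from_config(regimens: dict) -> dict[str, Regimen]:
    """Materialize Regimen objects from config entries (combos resolved last)."""
    catalog: dict[str, Regimen] = {}
    combos: dict[str, list[str]] = {}
    for name, rc in regimens.items():
        if rc.kind == "fixed":
            catalog[name] = DosingRegimen(
                name, cents(rc.unit_cost), int(rc.units_per_day), int(rc.duration_days), rc.notes
            )
        elif rc.kind == "albumin":
            catalog[name] = AlbuminDosing(
                name=name,
                dose_g_per_kg=rc.dose_g_per_kg,
                weight_kg=rc.weight_kg,
                bag_g=rc.bag_g,
                bag_cost=cents(rc.unit_cost),
                n_doses=int(rc.n_doses),
                notes=rc.notes,
            )
        elif rc.kind == "priced":
            catalog[name] = PricedRegimen(name, cents(rc.total_cost), rc.notes)
        elif rc.kind == "combo":
            combos[name] = list(rc.components or [])
        else:
            raise DomainError(f"unknown regimen kind '{rc.kind}' for '{name}'")
    for name, parts in combos.items():
        missing = [p for p in parts if p not in catalog]
        if missing:
            raise DomainError(f"combo '{name}' references unknown regimens {missing}")
        catalog[name] = ComboRegimen(name, tuple(catalog[p] for p in parts))
    return catalog
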