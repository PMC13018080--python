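"""Model constants, structured-config IO, and inflation adjustment.

Every constant the engine uses lives in one :class:`ModelConfig`: utility
weights by functional band, unit costs, the nursing-home retention
schedule, the cohort transition schedule (a calibration product, not a
literature reproduction), stratum calibration anchors, willingness-to-pay
tiers, the cohort definition, and the drug-regimen catalog.  Configs
round-trip through a flat, commented YAML document.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from . import _calibrate
from ._calibrate import GRID_EARLY, INTERVALS
from .errors import ConfigFormatError, ConfigValidationError, DomainError
from .state import StateDistribution

STRATA = ("ci", "no_ci")


class UtilityWeights(BaseModel):
    """Point-in-time utility per year of life, by functional band."""

    u_independent: float = 0.74  # mRS 0-2
    u_dependent: float = 0.38  # mRS 3-5
    u_dead: float = 0.0

    @model_validator(mode="after")
    def _ordered(self) -> "UtilityWeights":
        if not 0 <= self.u_dead <= self.u_dependent <= self.u_independent <= 1:
            raise ValueError(
                "utilities must satisfy 0 <= u_dead <= u_dependent <= u_independent <= 1"
            )
        return self


class CostInputs(BaseModel):
    """Unit costs (USD 2025) and the two post-hospitalization adjustment factors."""

    acute_with_ci: float = 122_200.96  # acute admission, infarction stratum (NIS 2016-2021)
    acute_without_ci: float = 89_997.00
    annual_mrs02: float = 14_293.80  # annual post-discharge care, independent band
    annual_mrs35: float = 15_633.30  # annual post-discharge care, dependent band
    nh_annual: float = 114_665.00  # Genworth 2025 annual nursing-home cost
    nh_firstyear_factor: float = 0.85  # discharges between 3 months and 1 year
    y2to5_multiplier: float = 1.33  # expands the 2/3/5-year evaluations to a 4-year block

    @model_validator(mode="after")
    def _bounds(self) -> "CostInputs":
        for name in ("acute_with_ci", "acute_without_ci", "annual_mrs02", "annual_mrs35", "nh_annual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("nh_firstyear_factor", "y2to5_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        return self


class NursingHomeSchedule(BaseModel):
    """Retention of 3-month nursing-home residents over time.

    ``post5y_mode`` resolves two conflicting readings of the post-5-year
    rule: ``retain_all`` freezes occupancy at its 5-year level (no further
    discharges; deaths still remove residents) while ``retain_13pct``
    decays occupancy by the stated 13% annual continuation factor.
    """

    retention_3mo_to_1y: float = 0.70
    retention_1y_to_2y: float = 0.61
    retention_1y_to_5y: float = 0.36
    annual_rate_post5y: float = 0.13
    post5y_mode: str = "retain_all"
    # band-level 3-month utilizations; calibrated, not literature
    utilization_3mo_by_band: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _bounds(self) -> "NursingHomeSchedule":
        for name in ("retention_3mo_to_1y", "retention_1y_to_2y", "retention_1y_to_5y", "annual_rate_post5y"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.retention_1y_to_5y > self.retention_1y_to_2y:
            raise ValueError("retention_1y_to_5y must be <= retention_1y_to_2y")
        if self.post5y_mode not in ("retain_all", "retain_13pct"):
            raise ValueError("post5y_mode must be 'retain_all' or 'retain_13pct'")
        for band, v in self.utilization_3mo_by_band.items():
            if not 0 <= v <= 1:
                raise ValueError(f"utilization_3mo_by_band[{band}]={v} outside [0, 1]")
        return self


class TransitionSchedule(BaseModel):
    """Per-stratum state dynamics on the {0.25, 1, 2, 3, 5}-year grid.

    ``transitions_y1_to_y5`` holds one row-stochastic 3x3 matrix per
    interval (3mo->1y, 1->2y, 2->3y, 3->5y); after year 5 only the
    per-state annual mortality acts.  Shipped defaults are calibrated
    against the stratum anchors, not copied from literature.
    """

    dist_3mo_by_stratum: dict[str, StateDistribution]
    transitions_y1_to_y5: dict[str, list[list[list[float]]]]
    mortality_post5y: dict[str, dict[str, float]]

    @model_validator(mode="after")
    def _stochastic(self) -> "TransitionSchedule":
        for stratum in STRATA:
            if stratum not in self.dist_3mo_by_stratum:
                raise ValueError(f"dist_3mo_by_stratum missing stratum '{stratum}'")
            mats = self.transitions_y1_to_y5.get(stratum)
            if mats is None or len(mats) != len(INTERVALS):
                raise ValueError(
                    f"transitions_y1_to_y5[{stratum}] must hold {len(INTERVALS)} interval matrices"
                )
            for k, mat in enumerate(mats):
                m = np.asarray(mat, dtype=float)
                if m.shape != (3, 3):
                    raise ValueError(f"matrix {k} for '{stratum}' is not 3x3")
                if np.any(m < -1e-12):
                    raise ValueError(f"matrix {k} for '{stratum}' has negative entries")
                rowsums = m.sum(axis=1)
                if np.any(rowsums > 1 + 1e-9):
                    raise ValueError(f"matrix {k} for '{stratum}': outflow exceeds 1")
                if np.any(np.abs(rowsums - 1) > 1e-9):
                    raise ValueError(f"matrix {k} for '{stratum}': rows must sum to 1")
                if abs(m[2, 2] - 1) > 1e-12 or abs(m[2, 0]) > 1e-12 or abs(m[2, 1]) > 1e-12:
                    raise ValueError(f"matrix {k} for '{stratum}': dead must be absorbing")
            mort = self.mortality_post5y.get(stratum, {})
            for band in ("independent", "dependent"):
                v = mort.get(band)
                if v is None or not 0 <= v <= 1:
                    raise ValueError(f"mortality_post5y[{stratum}][{band}] must be in [0, 1]")
        return self

    def matrices(self, stratum: str) -> list[np.ndarray]:
        return [np.asarray(m, dtype=float) for m in self.transitions_y1_to_y5[stratum]]


class StratumAnchor(BaseModel):
    total_cost: float
    qaly: float


class CalibrationAnchors(BaseModel):
    """Published stratum totals the engine is pinned to.

    ``year1`` and ``year5`` costs are cumulative from admission; the
    ``year30`` cost figures are the years-5-to-30 *increments* (only that
    reading satisfies the cohort-total identity within a dollar).
    ``qaly`` entries are point-in-time cohort utilities at the horizon.
    """

    n_by_stratum: dict[str, int] = Field(default_factory=lambda: {"ci": 35, "no_ci": 65})
    year1: dict[str, StratumAnchor] = Field(
        default_factory=lambda: {
            "ci": StratumAnchor(total_cost=5_982_964.0, qaly=14.0),
            "no_ci": StratumAnchor(total_cost=7_794_976.0, qaly=42.9),
        }
    )
    year5: dict[str, StratumAnchor] = Field(
        default_factory=lambda: {
            "ci": StratumAnchor(total_cost=9_529_902.30, qaly=13.5),
            "no_ci": StratumAnchor(total_cost=12_303_601.90, qaly=42.6),
        }
    )
    year30: dict[str, StratumAnchor] = Field(
        default_factory=lambda: {
            "ci": StratumAnchor(total_cost=10_112_038.0, qaly=3.08),
            "no_ci": StratumAnchor(total_cost=28_969_455.0, qaly=15.2),
        }
    )
    cohort_total_30y: float = 60_914_997.0  # published 30-year cohort total

    @model_validator(mode="after")
    def _strata_present(self) -> "CalibrationAnchors":
        for table in (self.n_by_stratum, self.year1, self.year5, self.year30):
            for s in STRATA:
                if s not in table:
                    raise ValueError(f"anchor table missing stratum '{s}'")
        if any(n <= 0 for n in self.n_by_stratum.values()):
            raise ValueError("stratum sizes must be positive")
        return self


class WtpThresholds(BaseModel):
    """Willingness-to-pay tiers, USD per QALY; comparison is strict '<'."""

    thresholds: list[float] = Field(default_factory=lambda: [50_000.0, 100_000.0, 150_000.0])

    @model_validator(mode="after")
    def _increasing(self) -> "WtpThresholds":
        if not self.thresholds or any(t <= 0 for t in self.thresholds):
            raise ValueError("thresholds must be positive")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError("thresholds must be strictly increasing")
        return self


class CohortSpec(BaseModel):
    n_patients: int = 100
    p_infarction: float = 0.35

    @model_validator(mode="after")
    def _bounds(self) -> "CohortSpec":
        if self.n_patients <= 0:
            raise ValueError("n_patients must be > 0")
        if not 0 <= self.p_infarction <= 1:
            raise ValueError("p_infarction outside [0, 1]")
        return self


class ScenarioCell(BaseModel):
    """A stored (published) cohort total for one proportion x horizon."""

    p_infarction: float
    horizon: int
    total_cost: float
    total_qaly: float


class RegimenConfig(BaseModel):
    """Catalog entry for the drug-costing module (see interventions)."""

    kind: str = "fixed"  # fixed | albumin | combo | priced
    unit_cost: Optional[float] = None
    units_per_day: Optional[float] = None
    duration_days: Optional[float] = None
    dose_g_per_kg: Optional[float] = None
    weight_kg: Optional[float] = None
    bag_g: Optional[float] = None
    n_doses: Optional[int] = None
    components: Optional[list[str]] = None
    total_cost: Optional[float] = None  # for 'priced' regimens quoted as a lump sum
    notes: str = ""


class ModelConfig(BaseModel):
    utilities: UtilityWeights = Field(default_factory=UtilityWeights)
    costs: CostInputs = Field(default_factory=CostInputs)
    nursing_home: NursingHomeSchedule = Field(default_factory=NursingHomeSchedule)
    transitions: Optional[TransitionSchedule] = None
    anchors: CalibrationAnchors = Field(default_factory=CalibrationAnchors)
    wtp: WtpThresholds = Field(default_factory=WtpThresholds)
    cohort: CohortSpec = Field(default_factory=CohortSpec)
    scenario_rates: list[float] = Field(default_factory=lambda: [0.30, 0.25, 0.20])
    scenario_cells: list[ScenarioCell] = Field(default_factory=list)
    intervention_cost_grid: list[float] = Field(
        default_factory=lambda: [5_000.0, 10_000.0, 15_000.0, 20_000.0]
    )
    discount_rate: float = 0.0  # hook only; published arithmetic uses none
    regimens: dict[str, RegimenConfig] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _bounds(self) -> "ModelConfig":
        if not 0 <= self.discount_rate < 1:
            raise ValueError("discount_rate outside [0, 1)")
        for p in self.scenario_rates:
            if not 0 <= p <= self.cohort.p_infarction:
                raise ValueError(f"scenario rate {p} outside [0, base rate]")
        return self


# published cohort totals for the non-base proportions at 5 and 30 years;
# these cells are not an affine mixture of the stratum anchors, so they are
# carried verbatim rather than recomputed (see docs/methods.md)
_SCENARIO_CELLS = [
    ScenarioCell(p_infarction=0.30, horizon=5, total_cost=21_371_192.0, total_qaly=56.8),
    ScenarioCell(p_infarction=0.25, horizon=5, total_cost=20_976_797.0, total_qaly=57.9),
    ScenarioCell(p_infarction=0.20, horizon=5, total_cost=20_571_518.30, total_qaly=59.4),
    ScenarioCell(p_infarction=0.30, horizon=30, total_cost=60_546_080.0, total_qaly=18.8),
    ScenarioCell(p_infarction=0.25, horizon=30, total_cost=61_075_366.0, total_qaly=19.5),
    ScenarioCell(p_infarction=0.20, horizon=30, total_cost=61_177_403.0, total_qaly=20.2),
]


def _calibrated_defaults(
    anchors: CalibrationAnchors, costs: CostInputs, utilities: UtilityWeights
) -> tuple[TransitionSchedule, dict[str, float]]:
    """Build the default TransitionSchedule + NH band utilizations."""
    strata: dict[str, _calibrate.CalibratedStratum] = {}
    for s in STRATA:
        acute = costs.acute_with_ci if s == "ci" else costs.acute_without_ci
        n = anchors.n_by_stratum[s]
        strata[s] = _calibrate.calibrate_stratum(
            n=n,
            cost_1y_total=anchors.year1[s].total_cost,
            qaly_by_horizon={
                1: anchors.year1[s].qaly,
                5: anchors.year5[s].qaly,
                30: anchors.year30[s].qaly,
            },
            assumptions=_calibrate.DEFAULT_ASSUMPTIONS[s],
            acute_cost=acute,
            annual_mrs02=costs.annual_mrs02,
            annual_mrs35=costs.annual_mrs35,
            nh_annual=costs.nh_annual,
            nh_firstyear_factor=costs.nh_firstyear_factor,
            u_ind=utilities.u_independent,
            u_dep=utilities.u_dependent,
        )
    utilization = _calibrate.solve_band_utilizations(strata)
    schedule = TransitionSchedule(
        dist_3mo_by_stratum={s: strata[s].dists[0.25] for s in STRATA},
        transitions_y1_to_y5={s: [m.tolist() for m in strata[s].matrices] for s in STRATA},
        mortality_post5y={
            s: {
                "independent": strata[s].mortality_post5y,
                "dependent": strata[s].mortality_post5y,
            }
            for s in STRATA
        },
    )
    return schedule, utilization


def default_config() -> ModelConfig:
    """The shipped parameter set: published constants plus calibrated dynamics."""
    anchors = CalibrationAnchors()
    costs = CostInputs()
    utilities = UtilityWeights()
    schedule, utilization = _calibrated_defaults(anchors, costs, utilities)
    from .interventions import default_catalog_config  # late: avoids import cycle

    return ModelConfig(
        utilities=utilities,
        costs=costs,
        nursing_home=NursingHomeSchedule(utilization_3mo_by_band=utilization),
        transitions=schedule,
        anchors=anchors,
        scenario_cells=list(_SCENARIO_CELLS),
        regimens=default_catalog_config(),
    )


def inflation_adjust(amount: float, factor: float) -> float:
    """Scale a dollar amount by a CPI-style inflation/conversion ratio."""
    if factor <= 0:
        raise DomainError(f"inflation factor must be > 0, got {factor}")
    return amount * factor


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(path: str | Path) -> ModelConfig:
    """Load a YAML config; absent keys fall back to the shipped defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        context = ""
        mark = getattr(exc, "problem_mark", None)
        if mark is not None:
            context = f" (line {mark.line + 1}, column {mark.column + 1})"
        raise ConfigFormatError(f"could not parse {path}{context}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigFormatError(f"{path}: top level must be a mapping")
    merged = _deep_merge(default_config().model_dump(), data)
    try:
        return ModelConfig(**merged)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in err["loc"]) for err in exc.errors())
        raise ConfigValidationError(f"{path}: invalid value(s) for {fields}: {exc}") from exc


_SECTION_COMMENTS = {
    "utilities": "Point-in-time utility weights per functional band (mRS 0-2 / 3-5 / dead).",
    "costs": "Unit costs in USD 2025 (acute: NIS 2016-2021; annual care: Shireman-style Medicare estimates; nursing home: Genworth 2025 Cost of Care Survey) and post-hospitalization adjustment factors.",
    "nursing_home": "Nursing-home retention schedule; utilization_3mo_by_band is calibrated, not literature.",
    "transitions": "Cohort state dynamics. CALIBRATED, NOT LITERATURE: back-solved so the stratum anchors are reproduced.",
    "anchors": "Stratum calibration anchors. year30 costs are years-5-to-30 increments.",
    "wtp": "Willingness-to-pay tiers (USD/QALY), strict '<' comparison.",
    "cohort": "Simulated cohort: 100 patients, 35% base infarction rate.",
    "scenario_rates": "Counterfactual infarction proportions (5/10/15 point reductions).",
    "scenario_cells": "Published 5- and 30-year cohort totals for the non-base proportions (stored verbatim; not an affine mixture of the anchors).",
    "intervention_cost_grid": "Per-patient intervention costs evaluated in the ICER grid.",
    "discount_rate": "Annual discount rate for future costs/QALYs; 0 reproduces the published arithmetic.",
    "regimens": "Drug-regimen catalog (NADAC/AWP 2025 unit costs).",
}


def config_to_yaml(config: ModelConfig) -> str:
    """Serialize a config as commented YAML (stable key order)."""
    data = config.model_dump(exclude_none=True)
    parts = ["# sahcue model configuration\n"]
    for key, value in data.items():
        comment = _SECTION_COMMENTS.get(key)
        if comment:
            parts.append(f"# {comment}")
        parts.append(yaml.safe_dump({key: value}, sort_keys=False, default_flow_style=False))
    return "\n".join(parts)


def save_config(config: ModelConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(config_to_yaml(config))
    return path
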