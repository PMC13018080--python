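"""Incremental cost-utility analytics.

The incremental cost-utility ratio for an intervention priced at C per
patient over an n-patient cohort, against a counterfactual that saves S
dollars and gains G QALYs, is ``(n*C - S) / G``.  Negative ratios with a
positive QALY gain mean the intervention is dominant (cost-saving); the
raw negative number is retained in tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd
from pydantic import BaseModel, model_validator

from .economics import ScenarioResult, scenario_totals
from .errors import DomainError, UndefinedIcerError
from .money import round_half_up
from .parameters import CohortSpec, ModelConfig, WtpThresholds

DOMINANT = "dominant"
NOT_CE = "not_ce"


class InterventionSpec(BaseModel):
    """A hypothetical intervention: per-patient price and effect size."""

    cost_per_patient: float
    reduction: float  # absolute reduction in infarction proportion (e.g. 0.10)

    @model_validator(mode="after")
    def _bounds(self) -> "InterventionSpec":
        if self.cost_per_patient < 0:
            raise ValueError("cost_per_patient must be >= 0")
        if self.reduction < 0:
            raise ValueError("reduction must be >= 0")
        return self


@dataclass
class IcerResult:
    horizon: int
    reduction: float
    intervention_cost_per_patient: float
    cost_saved: float
    qaly_gain: float
    icer: Optional[float]  # None when the QALY gain is zero
    wtp_class: str


def cost_saved(base: ScenarioResult, alt: ScenarioResult) -> float:
    """Dollars saved by the counterfactual (negative when it costs more)."""
    if base.horizon != alt.horizon:
        raise DomainError(f"horizon mismatch: {base.horizon} vs {alt.horizon}")
    if base.n_patients != alt.n_patients:
        raise DomainError("cohort size mismatch")
    return base.total_cost - alt.total_cost


def qaly_gained(base: ScenarioResult, alt: ScenarioResult) -> float:
    if base.horizon != alt.horizon:
        raise DomainError(f"horizon mismatch: {base.horizon} vs {alt.horizon}")
    if base.n_patients != alt.n_patients:
        raise DomainError("cohort size mismatch")
    return alt.total_qaly - base.total_qaly


def icer(
    intervention: InterventionSpec, n: int, cost_saved: float, qaly_gain: float
) -> float:
    """Incremental cost-utility ratio, USD per QALY gained."""
    if qaly_gain == 0:
        raise UndefinedIcerError("ICER undefined for zero QALY gain")
    return (n * intervention.cost_per_patient - cost_saved) / qaly_gain


def _class_name(threshold: float) -> str:
    if threshold % 1000 == 0:
        return f"ce_under_{int(threshold) // 1000}k"
    return f"ce_under_{threshold:g}"


def classify_wtp(icer_value: float, qaly_gain: float, thresholds: WtpThresholds) -> str:
    """Willingness-to-pay class under the strict '<' convention."""
    if qaly_gain <= 0:
        return NOT_CE
    if icer_value < 0:
        return DOMINANT
    for t in thresholds.thresholds:
        if icer_value < t:
            return _class_name(t)
    return NOT_CE


def class_rank(wtp_class: str, thresholds: WtpThresholds) -> int:
    """Order classes from most favourable (0 = dominant) to not_ce."""
    order = [DOMINANT, *(_class_name(t) for t in thresholds.thresholds), NOT_CE]
    return order.index(wtp_class)


def evaluate_intervention(
    config: ModelConfig,
    horizon: int,
    reduction: float,
    cost_per_patient: float,
    mode: str = "anchor",
    precision: str = "printed",
) -> IcerResult:
    """One cell of the cost-utility grid.

    ``precision="printed"`` rounds the QALY gain to one decimal before
    the ratio, matching the published table convention; ``"full"`` keeps
    the raw gain.
    """
    n = config.cohort.n_patients
    p_base = config.cohort.p_infarction
    if reduction > p_base:
        raise DomainError(f"reduction {reduction} exceeds base rate {p_base}")
    base = scenario_totals(CohortSpec(n_patients=n, p_infarction=p_base), horizon, config, mode)
    alt = scenario_totals(
        CohortSpec(n_patients=n, p_infarction=p_base - reduction), horizon, config, mode
    )
    saved = cost_saved(base, alt)
    gain = qaly_gained(base, alt)
    if precision == "printed":
        gain = round_half_up(gain, 1)
    elif precision != "full":
        raise DomainError(f"unknown precision '{precision}'")
    spec = InterventionSpec(cost_per_patient=cost_per_patient, reduction=reduction)
    value = icer(spec, n, saved, gain) if gain != 0 else None
    wtp = classify_wtp(value, gain, config.wtp) if value is not None else NOT_CE
    return IcerResult(
        horizon=horizon,
        reduction=reduction,
        intervention_cost_per_patient=cost_per_patient,
        cost_saved=saved,
        qaly_gain=gain,
        icer=value,
        wtp_class=wtp,
    )


def icer_grid(
    config: ModelConfig,
    horizons: Optional[list[int]] = None,
    mode: str = "anchor",
    precision: str = "printed",
) -> pd.DataFrame:
    """Full grid (horizon x reduction) with one ICER/class pair per price."""
    horizons = horizons or [1, 5, 30]
    reductions = [round(config.cohort.p_infarction - p, 10) for p in config.scenario_rates]
    rows = []
    for h in horizons:
        for red in reductions:
            row: dict = {"horizon_years": h, "reduction_pct": round(red * 100)}
            for cost_pp in config.intervention_cost_grid:
                res = evaluate_intervention(config, h, red, cost_pp, mode, precision)
                row["cost_saved"] = res.cost_saved
                row["qaly_gain"] = res.qaly_gain
                row[f"icer_{int(cost_pp)}"] = res.icer
                row[f"wtp_class_{int(cost_pp)}"] = res.wtp_class
            rows.append(row)
    cols = ["horizon_years", "reduction_pct", "cost_saved", "qaly_gain"]
    cols += [c for c in rows[0] if c.startswith("icer_")]
    cols += [c for c in rows[0] if c.startswith("wtp_class_")]
    return pd.DataFrame(rows)[cols]
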