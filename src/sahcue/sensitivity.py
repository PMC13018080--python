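"""One-way deterministic sensitivity analysis (tornado diagram).

Each sweep rescales a single input by a low/high multiplier, recomputes
the ICER at a fixed anchor scenario, and reports the change from the
anchor ICER.  The default anchor is the 5-year horizon, 15% infarction
reduction, $5,000-per-patient intervention: the only scenario that
reproduces the published sensitivity deltas exactly.

Two sweep routes exist. ``qaly_gain`` and ``intervention_cost`` act
directly on the ICER arithmetic and use the anchor-mode (published)
inputs.  ``nh_cost`` and ``longterm_cost_mrs02`` change how savings are
composed, so they rerun the mechanistic cost model with the scaled unit
cost; their deltas are taken against the mechanistic anchor ICER.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cua import InterventionSpec, cost_saved, icer, qaly_gained
from .economics import scenario_totals
from .errors import DomainError
from .money import round_half_up
from .parameters import CohortSpec, ModelConfig

MECHANISTIC_PARAMS = ("nh_cost", "longterm_cost_mrs02")
SWEEP_PARAMS = ("intervention_cost", "nh_cost", "longterm_cost_mrs02", "qaly_gain")

#: default low/high multipliers per parameter
DEFAULT_MULTIPLIERS = {
    "qaly_gain": (0.90, 1.10),
    "intervention_cost": (0.80, 1.20),
    "nh_cost": (0.80, 1.20),
    "longterm_cost_mrs02": (0.80, 1.20),
}


@dataclass(frozen=True)
class AnchorScenario:
    horizon: int = 5
    reduction: float = 0.15
    cost_per_patient: float = 5_000.0


@dataclass
class TornadoEntry:
    parameter: str
    low_multiplier: float
    high_multiplier: float
    low_value: float  # the varied input at the low multiplier
    high_value: float
    anchor_icer: float
    icer_low: float
    icer_high: float

    @property
    def delta_low(self) -> float:
        return self.icer_low - self.anchor_icer

    @property
    def delta_high(self) -> float:
        return self.icer_high - self.anchor_icer

    @property
    def span(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _anchor_inputs(config: ModelConfig, anchor: AnchorScenario, mode: str) -> tuple[int, float, float]:
    """(n, cost_saved, qaly_gain) at the anchor scenario.

    Anchor mode rounds the QALY gain to one decimal, matching the
    published inputs the tornado is pinned to.
    """
    n = config.cohort.n_patients
    p = config.cohort.p_infarction
    base = scenario_totals(CohortSpec(n_patients=n, p_infarction=p), anchor.horizon, config, mode)
    alt = scenario_totals(
        CohortSpec(n_patients=n, p_infarction=p - anchor.reduction), anchor.horizon, config, mode
    )
    saved = cost_saved(base, alt)
    gain = qaly_gained(base, alt)
    if mode == "anchor":
        gain = round_half_up(gain, 1)
    return n, saved, gain


def one_way(
    config: ModelConfig,
    param: str,
    multipliers: tuple[float, float] | None = None,
    anchor: AnchorScenario = AnchorScenario(),
) -> TornadoEntry:
    """Sweep one parameter; all other inputs held constant."""
    if param not in SWEEP_PARAMS:
        raise DomainError(f"unknown sensitivity parameter '{param}' (choose from {SWEEP_PARAMS})")
    lo, hi = multipliers or DEFAULT_MULTIPLIERS[param]
    if lo <= 0 or hi <= 0:
        raise DomainError("multipliers must be positive")
    spec = InterventionSpec(cost_per_patient=anchor.cost_per_patient, reduction=anchor.reduction)
    mode = "mechanistic" if param in MECHANISTIC_PARAMS else "anchor"
    n, saved, gain = _anchor_inputs(config, anchor, mode)
    anchor_icer = icer(spec, n, saved, gain)

    def at(m: float) -> tuple[float, float]:
        if param == "qaly_gain":
            return gain * m, icer(spec, n, saved, gain * m)
        if param == "intervention_cost":
            scaled = InterventionSpec(cost_per_patient=anchor.cost_per_patient * m, reduction=anchor.reduction)
            return scaled.cost_per_patient, icer(scaled, n, saved, gain)
        field = {"nh_cost": "nh_annual", "longterm_cost_mrs02": "annual_mrs02"}[param]
        base_value = getattr(config.costs, field)
        scaled_cfg = config.model_copy(
            update={"costs": config.costs.model_copy(update={field: base_value * m})}
        )
        _, saved_m, gain_m = _anchor_inputs(scaled_cfg, anchor, mode)
        return base_value * m, icer(spec, n, saved_m, gain_m)

    low_value, icer_low = at(lo)
    high_value, icer_high = at(hi)
    return TornadoEntry(
        parameter=param,
        low_multiplier=lo,
        high_multiplier=hi,
        low_value=low_value,
        high_value=high_value,
        anchor_icer=anchor_icer,
        icer_low=icer_low,
        icer_high=icer_high,
    )


def tornado_table(entries: list[TornadoEntry]) -> list[TornadoEntry]:
    """Order entries for plotting: widest span first, ties alphabetical."""
    if not entries:
        raise DomainError("tornado table requires at least one entry")
    return sorted(entries, key=lambda e: (-e.span, e.parameter))


def run_tornado(config: ModelConfig, anchor: AnchorScenario = AnchorScenario()) -> list[TornadoEntry]:
    """All default one-way sweeps at the anchor, tornado-ordered."""
    return tornado_table([one_way(config, p, anchor=anchor) for p in SWEEP_PARAMS])


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "low_mult": e.low_multiplier,
                "high_mult": e.high_multiplier,
                "low_value": e.low_value,
                "high_value": e.high_value,
                "anchor_icer": e.anchor_icer,
                "icer_low": e.icer_low,
                "icer_high": e.icer_high,
                "delta_low": e.delta_low,
                "delta_high": e.delta_high,
                "span": e.span,
            }
            for e in entries
        ]
    )
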