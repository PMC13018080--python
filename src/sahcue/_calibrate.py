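"""Closed-form back-solution of the default transition schedule.

The literature sources behind the 3-month mRS mixes, the year-1..5
transition rates, and the long-run mortality are cited but not tabulated
in the inputs this engine ships with.  What *is* available are stratum
anchors: total cost and point-in-time QALYs for the infarction and
no-infarction strata at 1, 5 and 30 years.  This module back-solves a
transition schedule that reproduces those anchors exactly where the
algebra permits:

* the 1- and 5-year state mixes are solved from the stratum QALY anchors
  given an assumed death-fraction path (two utilities, one alive
  constraint -> unique mix);
* post-5-year mortality is uniform across the two alive bands and solved
  so the 30-year point QALY anchor is hit exactly;
* 3-month nursing-home occupancy is solved from the 1-year cost anchor,
  and band-level (mRS 0-2 vs 3-5) utilizations from the two strata
  jointly.

Everything here is deterministic closed-form arithmetic -- no fitting
loops.  The resulting numbers are calibration products, not literature
values, and the shipped config labels them as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import CalibrationError
from .state import StateDistribution

#: evaluation grid up to the plateau: 3 months, then years 1, 2, 3, 5
GRID_EARLY = (0.25, 1.0, 2.0, 3.0, 5.0)

#: (start, end) interval bounds matched to the per-interval matrices
INTERVALS = tuple(zip(GRID_EARLY[:-1], GRID_EARLY[1:]))

POST5Y_YEARS = 25  # years 6..30


@dataclass(frozen=True)
class StratumAssumptions:
    """Assumed (not solvable from anchors) pieces of one stratum's path."""

    dist_3mo: tuple[float, float, float]  # independent, dependent, dead
    f_dead_1y: float
    f_dead_5y: float


# Chosen once as clinically plausible shapes consistent with the anchors:
# infarction patients carry heavy early mortality and dependence; the
# no-infarction stratum is mostly independent with low early mortality.
DEFAULT_ASSUMPTIONS = {
    "ci": StratumAssumptions(dist_3mo=(0.26, 0.50, 0.24), f_dead_1y=0.32, f_dead_5y=0.38),
    "no_ci": StratumAssumptions(dist_3mo=(0.72, 0.20, 0.08), f_dead_1y=0.09, f_dead_5y=0.105),
}


@dataclass
class CalibratedStratum:
    dists: dict[float, StateDistribution]  # keyed by grid time
    matrices: list[np.ndarray]  # one 3x3 per interval in INTERVALS
    mortality_post5y: float  # uniform annual death probability after year 5
    nh_occupancy_3mo: float


@dataclass
class CalibrationResult:
    strata: dict[str, CalibratedStratum]
    nh_utilization_by_band: dict[str, float] = field(default_factory=dict)


def solve_mix(qaly_per_patient: float, f_dead: float, u_ind: float, u_dep: float) -> tuple[float, float]:
    """State mix (f_independent, f_dependent) from a point QALY and death fraction."""
    alive = 1.0 - f_dead
    f_ind = (qaly_per_patient - u_dep * alive) / (u_ind - u_dep)
    f_dep = alive - f_ind
    if not (-1e-12 <= f_ind <= alive + 1e-12 and f_dep >= -1e-12):
        raise CalibrationError(
            f"QALY anchor {qaly_per_patient} incompatible with f_dead={f_dead}: "
            f"solved mix ({f_ind:.4f}, {f_dep:.4f})"
        )
    return max(f_ind, 0.0), max(f_dep, 0.0)


def interval_matrix(d0: StateDistribution, d1: StateDistribution) -> np.ndarray:
    """Minimal-movement row-stochastic matrix mapping d0 onto d1.

    Mortality is applied uniformly to both alive bands, then a single net
    flow between independent and dependent closes the gap.  Dead is
    absorbing.
    """
    z0, z1 = d0.f_dead, d1.f_dead
    if z1 < z0 - 1e-12:
        raise CalibrationError("death fraction must be non-decreasing")
    alive0 = 1.0 - z0
    h = 0.0 if alive0 <= 0 else (z1 - z0) / alive0
    s = 1.0 - h
    i_surv = d0.f_independent * s
    p_surv = d0.f_dependent * s
    i1 = d1.f_independent
    if i1 >= i_surv:  # net recovery: dependent -> independent
        r = 0.0 if p_surv <= 0 else (i1 - i_surv) / p_surv
        rows = [[s, 0.0, h], [s * r, s * (1.0 - r), h], [0.0, 0.0, 1.0]]
    else:  # net deterioration: independent -> dependent
        r = (i_surv - i1) / i_surv
        rows = [[s * (1.0 - r), s * r, h], [0.0, s, h], [0.0, 0.0, 1.0]]
    if r > 1.0 + 1e-9:
        raise CalibrationError(f"interval requires movement rate {r:.4f} > 1")
    return np.array(rows)


def calibrate_stratum(
    *,
    n: int,
    cost_1y_total: float,
    qaly_by_horizon: dict[int, float],  # totals for the stratum at 1, 5, 30 years
    assumptions: StratumAssumptions,
    acute_cost: float,
    annual_mrs02: float,
    annual_mrs35: float,
    nh_annual: float,
    nh_firstyear_factor: float,
    u_ind: float,
    u_dep: float,
) -> CalibratedStratum:
    q1 = qaly_by_horizon[1] / n
    q5 = qaly_by_horizon[5] / n
    q30 = qaly_by_horizon[30] / n

    fd1, fd5 = assumptions.f_dead_1y, assumptions.f_dead_5y
    i1, _ = solve_mix(q1, fd1, u_ind, u_dep)
    i5, _ = solve_mix(q5, fd5, u_ind, u_dep)

    # death fraction and independent fraction interpolate linearly in time
    # across the sparse 1..5y grid; dependent closes each point to 1
    dists: dict[float, StateDistribution] = {
        0.25: StateDistribution(
            f_independent=assumptions.dist_3mo[0],
            f_dependent=assumptions.dist_3mo[1],
            f_dead=assumptions.dist_3mo[2],
        )
    }
    for t in (1.0, 2.0, 3.0, 5.0):
        w = (t - 1.0) / 4.0
        fd = fd1 + (fd5 - fd1) * w
        fi = i1 + (i5 - i1) * w
        dists[t] = StateDistribution(f_independent=fi, f_dependent=1.0 - fd - fi, f_dead=fd)

    matrices = [interval_matrix(dists[a], dists[b]) for a, b in INTERVALS]

    if q5 <= 0:
        raise CalibrationError("5-year QALY anchor must be positive")
    survival_ratio = q30 / q5
    if not 0 < survival_ratio <= 1:
        raise CalibrationError(f"30y/5y QALY ratio {survival_ratio:.4f} outside (0, 1]")
    mortality = 1.0 - survival_ratio ** (1.0 / POST5Y_YEARS)

    d1 = dists[1.0]
    disab_1y = d1.f_independent * annual_mrs02 + d1.f_dependent * annual_mrs35
    occ_3mo = (cost_1y_total / n - acute_cost - disab_1y) / (nh_annual * nh_firstyear_factor)
    if not 0 <= occ_3mo <= dists[0.25].f_alive + 1e-9:
        raise CalibrationError(
            f"solved 3-month nursing-home occupancy {occ_3mo:.4f} outside [0, alive]"
        )

    return CalibratedStratum(
        dists=dists, matrices=matrices, mortality_post5y=mortality, nh_occupancy_3mo=occ_3mo
    )


def solve_band_utilizations(strata: dict[str, CalibratedStratum]) -> dict[str, float]:
    """Band-level 3-month NH utilizations from the two strata's occupancies."""
    a = np.array(
        [
            [strata["ci"].dists[0.25].f_independent, strata["ci"].dists[0.25].f_dependent],
            [strata["no_ci"].dists[0.25].f_independent, strata["no_ci"].dists[0.25].f_dependent],
        ]
    )
    b = np.array([strata["ci"].nh_occupancy_3mo, strata["no_ci"].nh_occupancy_3mo])
    u = np.linalg.solve(a, b)
    if not np.all((u >= -1e-9) & (u <= 1 + 1e-9)):
        raise CalibrationError(f"band utilizations {u} outside [0, 1]")
    return {"independent": float(np.clip(u[0], 0, 1)), "dependent": float(np.clip(u[1], 0, 1))}
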