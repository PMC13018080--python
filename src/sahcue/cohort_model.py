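"""Cohort state trajectories and nursing-home occupancy.

The cohort is split once, at admission, into an infarction ("ci") and a
no-infarction ("no_ci") stratum.  Each stratum starts from its 3-month
state mix, moves through per-interval transition matrices on the sparse
{3 months, 1, 2, 3, 5 year} grid, and after year 5 is subject to annual
mortality only (the independent:dependent split of survivors is frozen
-- functional transitions plateau).  Nursing-home occupancy is a second
track seeded at 3 months and thinned by the retention schedule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from ._calibrate import GRID_EARLY, INTERVALS
from .errors import DomainError
from .parameters import CohortSpec, NursingHomeSchedule, TransitionSchedule
from .state import StateDistribution

MAX_HORIZON = 30


@dataclass
class StateTrajectory:
    """One stratum's state mix (and optional NH occupancy) over time."""

    stratum: str
    n_patients: float
    time_points: list[float]
    distributions: list[StateDistribution]
    nh_occupancy: Optional[list[float]] = None

    def at(self, t: float) -> StateDistribution:
        for tp, d in zip(self.time_points, self.distributions):
            if abs(tp - t) < 1e-9:
                return d
        raise DomainError(f"time {t} not on trajectory grid {self.time_points}")

    def occupancy_at(self, t: float) -> float:
        if self.nh_occupancy is None:
            raise DomainError("trajectory carries no nursing-home track")
        for tp, occ in zip(self.time_points, self.nh_occupancy):
            if abs(tp - t) < 1e-9:
                return occ
        raise DomainError(f"time {t} not on trajectory grid")


def time_grid(horizon: int) -> list[float]:
    """Evaluation grid: {0.25, 1, 2, 3, 5} then annually to the horizon."""
    if not (isinstance(horizon, (int, np.integer)) and 1 <= horizon <= MAX_HORIZON):
        raise DomainError(f"horizon must be an integer in [1, {MAX_HORIZON}], got {horizon}")
    grid = [t for t in GRID_EARLY if t <= horizon]
    if horizon == 4:  # off the sparse grid; carried as an interpolated point
        grid.append(4.0)
    grid.extend(float(t) for t in range(6, horizon + 1))
    return grid


def _evolve(d0: StateDistribution, schedule: TransitionSchedule, stratum: str, horizon: int) -> list[StateDistribution]:
    mats = schedule.matrices(stratum)
    by_time: dict[float, np.ndarray] = {0.25: d0.as_array()}
    v = d0.as_array()
    for (t0, t1), m in zip(INTERVALS, mats):
        v = v @ m
        by_time[t1] = v
    mort = schedule.mortality_post5y[stratum]
    mi, md = mort["independent"], mort["dependent"]
    for t in range(6, MAX_HORIZON + 1):
        fi, fp, fd = v
        v = np.array([fi * (1 - mi), fp * (1 - md), fd + fi * mi + fp * md])
        by_time[float(t)] = v
    out = []
    for t in time_grid(horizon):
        if t == 4.0:  # linear interpolation between the 3- and 5-year grid points
            arr = 0.5 * (by_time[3.0] + by_time[5.0])
        else:
            arr = by_time[t]
        out.append(StateDistribution.from_array(arr))
    return out


def nursing_home_occupancy(
    initial_3mo: float,
    nhs: NursingHomeSchedule,
    times: list[float],
    alive: Optional[list[float]] = None,
) -> list[float]:
    """Occupancy (cohort fraction) at each requested time point.

    Retention is piecewise geometric through the 1-, 2- and 5-year
    retention anchors; after year 5 the ``post5y_mode`` rule applies.
    Occupancy is capped at the alive fraction when one is supplied.
    """
    if not 0 <= initial_3mo <= 1:
        raise DomainError(f"initial occupancy {initial_3mo} outside [0, 1]")
    r1 = nhs.retention_3mo_to_1y
    r2, r5 = nhs.retention_1y_to_2y, nhs.retention_1y_to_5y

    def retention(t: float) -> float:
        if t <= 0.25:
            return 1.0
        if t <= 1.0:
            return r1 ** ((t - 0.25) / 0.75)
        if t <= 2.0:
            return r1 * r2 ** (t - 1.0)
        if t <= 5.0:
            return r1 * r2 * (r5 / r2) ** ((t - 2.0) / 3.0)
        raise AssertionError

    out: list[float] = []
    alive_at = dict(zip(times, alive)) if alive is not None else {}
    occ5 = initial_3mo * r1 * r5
    alive5 = alive_at.get(5.0, 1.0)
    prev = None
    for t in times:
        if t <= 5.0:
            occ = initial_3mo * retention(t)
        elif nhs.post5y_mode == "retain_all":
            # no further discharges; deaths thin the resident pool
            occ = occ5 * (alive_at.get(t, 1.0) / alive5 if alive5 > 0 else 0.0)
        else:  # retain_13pct
            occ = (prev if prev is not None else occ5) * nhs.annual_rate_post5y
        if t in alive_at:
            occ = min(occ, alive_at[t])
        out.append(occ)
        prev = occ
    return out


def simulate_cohort(
    spec: CohortSpec,
    schedule: TransitionSchedule,
    horizon: int,
    nhs: Optional[NursingHomeSchedule] = None,
) -> dict[str, StateTrajectory]:
    """Per-stratum trajectories for a cohort split by infarction status.

    When a nursing-home schedule with band utilizations is supplied, each
    stratum's occupancy track is seeded from its 3-month mRS mix.
    """
    grid = time_grid(horizon)
    out: dict[str, StateTrajectory] = {}
    for stratum, frac in (("ci", spec.p_infarction), ("no_ci", 1 - spec.p_infarction)):
        d0 = schedule.dist_3mo_by_stratum[stratum]
        dists = _evolve(d0, schedule, stratum, horizon)
        occupancy = None
        if nhs is not None and nhs.utilization_3mo_by_band:
            occ0 = (
                nhs.utilization_3mo_by_band.get("independent", 0.0) * d0.f_independent
                + nhs.utilization_3mo_by_band.get("dependent", 0.0) * d0.f_dependent
            )
            occupancy = nursing_home_occupancy(occ0, nhs, grid, alive=[d.f_alive for d in dists])
        out[stratum] = StateTrajectory(
            stratum=stratum,
            n_patients=spec.n_patients * frac,
            time_points=grid,
            distributions=dists,
            nh_occupancy=occupancy,
        )
    return out


def trajectory_frame(trajectories: dict[str, StateTrajectory]) -> pd.DataFrame:
    """Long-format export: one row per stratum x time point."""
    rows = []
    for stratum, traj in trajectories.items():
        for i, t in enumerate(traj.time_points):
            d = traj.distributions[i]
            rows.append(
                {
                    "time_years": t,
                    "f_independent": d.f_independent,
                    "f_dependent": d.f_dependent,
                    "f_dead": d.f_dead,
                    "nh_occupancy": traj.nh_occupancy[i] if traj.nh_occupancy else np.nan,
                    "stratum": stratum,
                }
            )
    return pd.DataFrame(rows)
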