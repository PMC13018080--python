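"""Cohort dynamics: conservation, monotone mortality, plateau, NH retention."""

import numpy as np
import pytest

from conftest import brute_force_trajectory, random_schedule
from sahcue.cohort_model import nursing_home_occupancy, simulate_cohort, time_grid
from sahcue.economics import point_qaly
from sahcue.errors import DomainError
from sahcue.parameters import CohortSpec, NursingHomeSchedule, TransitionSchedule
from sahcue.state import StateDistribution

IDENTITY = np.eye(3).tolist()


def constant_schedule(dist):
    """No movement, no mortality: the distribution should never change."""
    return TransitionSchedule(
        dist_3mo_by_stratum={"ci": dist, "no_ci": dist},
        transitions_y1_to_y5={s: [IDENTITY] * 4 for s in ("ci", "no_ci")},
        mortality_post5y={s: {"independent": 0.0, "dependent": 0.0} for s in ("ci", "no_ci")},
    )


class TestSimulateCohort:
    def test_identity_dynamics_hold_distribution_constant(self):
        d = StateDistribution(f_independent=0.5, f_dependent=0.3, f_dead=0.2)
        trajs = simulate_cohort(CohortSpec(), constant_schedule(d), horizon=30)
        for traj in trajs.values():
            for dist in traj.distributions:
                assert dist.as_array() == pytest.approx(d.as_array(), abs=1e-12)

    def test_total_mortality_saturates(self):
        d = StateDistribution(f_independent=0.5, f_dependent=0.3, f_dead=0.2)
        sched = constant_schedule(d).model_copy(
            update={
                "mortality_post5y": {
                    s: {"independent": 1.0, "dependent": 1.0} for s in ("ci", "no_ci")
                }
            }
        )
        traj = simulate_cohort(CohortSpec(), sched, horizon=30)["ci"]
        for t, dist in zip(traj.time_points, traj.distributions):
            if t >= 6:
                assert dist.f_dead == pytest.approx(1.0, abs=1e-12)

    def test_calibrated_ci_year1_point_utility(self, config):
        """The infarction stratum's 1-year per-patient utility is 14.0/35 = 0.400."""
        traj = simulate_cohort(config.cohort, config.transitions, horizon=1)["ci"]
        from sahcue.parameters import UtilityWeights

        assert point_qaly(traj.at(1.0), UtilityWeights(), n=1) == pytest.approx(0.400, abs=1e-9)

    def test_outflow_above_one_rejected(self):
        bad = [[0.8, 0.5, 0.1], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        with pytest.raises(ValueError, match="outflow|sum"):
            TransitionSchedule(
                dist_3mo_by_stratum={
                    s: StateDistribution(f_independent=1.0, f_dependent=0.0, f_dead=0.0)
                    for s in ("ci", "no_ci")
                },
                transitions_y1_to_y5={s: [bad] + [IDENTITY] * 3 for s in ("ci", "no_ci")},
                mortality_post5y={s: {"independent": 0.0, "dependent": 0.0} for s in ("ci", "no_ci")},
            )

    def test_bad_horizon_rejected(self):
        with pytest.raises(DomainError):
            time_grid(0)
        with pytest.raises(DomainError):
            time_grid(31)


class TestTrajectoryProperties:
    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_and_monotone_death(self, seed):
        rng = np.random.default_rng(seed)
        sched = random_schedule(rng)
        trajs = simulate_cohort(CohortSpec(), sched, horizon=30)
        for traj in trajs.values():
            dead = [d.f_dead for d in traj.distributions]
            for d in traj.distributions:
                assert d.f_independent + d.f_dependent + d.f_dead == pytest.approx(1.0, abs=1e-12)
            assert all(b >= a - 1e-12 for a, b in zip(dead, dead[1:]))

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_matrix_evolution(self, seed):
        """Step-by-step evolution equals explicit matrix products (1e-10)."""
        rng = np.random.default_rng(1000 + seed)
        sched = random_schedule(rng)
        trajs = simulate_cohort(CohortSpec(), sched, horizon=30)
        for stratum, traj in trajs.items():
            expected = brute_force_trajectory(sched, stratum, traj.time_points)
            got = np.array([d.as_array() for d in traj.distributions])
            assert np.max(np.abs(got - expected)) < 1e-10

    def test_plateau_ratio_constant_after_year5(self, config):
        """Survivors' independent:dependent split is frozen once transitions plateau."""
        trajs = simulate_cohort(config.cohort, config.transitions, horizon=30)
        for traj in trajs.values():
            ratios = [
                d.f_independent / d.f_alive
                for t, d in zip(traj.time_points, traj.distributions)
                if t >= 5 and d.f_alive > 0
            ]
            assert np.ptp(ratios) < 1e-12


class TestNursingHomeOccupancy:
    GRID = [0.25, 1.0, 2.0, 3.0, 5.0]

    def test_zero_initial_stays_zero(self):
        occ = nursing_home_occupancy(0.0, NursingHomeSchedule(), self.GRID)
        assert occ == [0.0] * len(self.GRID)

    def test_published_retention_points(self):
        occ = dict(zip(self.GRID, nursing_home_occupancy(0.10, NursingHomeSchedule(), self.GRID)))
        assert occ[1.0] == pytest.approx(0.070, abs=1e-12)
        assert occ[2.0] == pytest.approx(0.10 * 0.70 * 0.61, abs=1e-12)
        assert occ[5.0] == pytest.approx(0.0252, abs=1e-12)

    def test_year3_is_geometric_between_2y_and_5y(self):
        occ = dict(zip(self.GRID, nursing_home_occupancy(0.10, NursingHomeSchedule(), self.GRID)))
        expected = 0.10 * 0.70 * 0.61 * (0.36 / 0.61) ** (1 / 3)
        assert occ[3.0] == pytest.approx(expected, rel=1e-12)

    def test_occupancy_monotone_nonincreasing_after_year1(self):
        occ = nursing_home_occupancy(0.3, NursingHomeSchedule(), self.GRID)
        tail = occ[1:]
        assert all(b <= a + 1e-12 for a, b in zip(tail, tail[1:]))

    def test_occupancy_never_exceeds_alive(self, config):
        trajs = simulate_cohort(
            config.cohort, config.transitions, horizon=30, nhs=config.nursing_home
        )
        for traj in trajs.values():
            for d, occ in zip(traj.distributions, traj.nh_occupancy):
                assert occ <= d.f_alive + 1e-12

    def test_retain_13pct_mode_decays(self, config):
        nhs = config.nursing_home.model_copy(update={"post5y_mode": "retain_13pct"})
        times = [0.25, 1.0, 2.0, 3.0, 5.0, 6.0, 7.0]
        occ = dict(zip(times, nursing_home_occupancy(0.2, nhs, times)))
        assert occ[6.0] == pytest.approx(occ[5.0] * 0.13, rel=1e-12)
        assert occ[7.0] == pytest.approx(occ[6.0] * 0.13, rel=1e-12)

    def test_initial_out_of_range_rejected(self):
        with pytest.raises(DomainError):
            nursing_home_occupancy(1.2, NursingHomeSchedule(), self.GRID)
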