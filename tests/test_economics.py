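"""Cost accumulation, point-in-time QALYs, anchors, and scenario totals."""

import numpy as np
import pytest

from sahcue.cohort_model import StateTrajectory
from sahcue.economics import (
    acute_cost,
    calibrate,
    disability_cost,
    nursing_home_cost,
    point_qaly,
    residual_report,
    scenario_frame,
    scenario_totals,
)
from sahcue.errors import CalibrationError, ConfigurationError, DomainError
from sahcue.parameters import CalibrationAnchors, CohortSpec, CostInputs, StratumAnchor, UtilityWeights
from sahcue.state import StateDistribution


def flat_trajectory(dist, n, occupancy=None, horizon=1):
    times = [0.25, 1.0] if horizon == 1 else [0.25, 1.0, 2.0, 3.0, 5.0]
    return StateTrajectory(
        stratum="ci",
        n_patients=n,
        time_points=times,
        distributions=[dist] * len(times),
        nh_occupancy=[occupancy] * len(times) if occupancy is not None else None,
    )


ALL_INDEPENDENT = StateDistribution(f_independent=1.0, f_dependent=0.0, f_dead=0.0)
ALL_DEPENDENT = StateDistribution(f_independent=0.0, f_dependent=1.0, f_dead=0.0)
ALL_DEAD = StateDistribution(f_independent=0.0, f_dependent=0.0, f_dead=1.0)


class TestAcuteCost:
    def test_stratum_values(self, config):
        assert acute_cost("ci", config.costs) == 122_200.96
        assert acute_cost("no_ci", config.costs) == 89_997.00

    def test_zero_scaled_costs(self):
        zeroed = CostInputs(acute_with_ci=0.0)
        assert acute_cost("ci", zeroed) == 0.0

    def test_unknown_stratum(self, config):
        with pytest.raises(DomainError):
            acute_cost("both", config.costs)


class TestDisabilityCost:
    def test_hundred_independent_patients_one_year(self, config):
        traj = flat_trajectory(ALL_INDEPENDENT, n=100)
        assert disability_cost(traj, config.costs, (0.0, 1.0)) == pytest.approx(1_429_380.00)

    def test_ten_dependent_patients_one_year(self, config):
        traj = flat_trajectory(ALL_DEPENDENT, n=10)
        assert disability_cost(traj, config.costs, (0.0, 1.0)) == pytest.approx(156_333.00)

    def test_all_dead_costs_nothing(self, config):
        traj = flat_trajectory(ALL_DEAD, n=100, horizon=5)
        assert disability_cost(traj, config.costs, (0.0, 5.0)) == 0.0

    def test_years_2_to_5_block_uses_expansion_factor(self, config):
        traj = flat_trajectory(ALL_INDEPENDENT, n=1, horizon=5)
        block = disability_cost(traj, config.costs, (1.0, 5.0))
        assert block == pytest.approx(1.33 * 3 * 14_293.80)

    def test_interval_outside_trajectory_rejected(self, config):
        traj = flat_trajectory(ALL_INDEPENDENT, n=1)
        with pytest.raises(DomainError):
            disability_cost(traj, config.costs, (0.0, 5.0))


class TestNursingHomeCost:
    def test_zero_occupancy(self, config):
        traj = flat_trajectory(ALL_DEPENDENT, n=100, occupancy=0.0)
        assert nursing_home_cost(traj, config.costs, (0.0, 1.0)) == 0.0

    def test_first_year_applies_discharge_factor(self, config):
        # 10 residents at the 3-month seed, cohort of 100
        traj = flat_trajectory(ALL_DEPENDENT, n=100, occupancy=0.10)
        assert nursing_home_cost(traj, config.costs, (0.0, 1.0)) == pytest.approx(974_652.50)

    def test_unit_factors_recover_annual_rate(self, config):
        costs = config.costs.model_copy(update={"nh_firstyear_factor": 1.0})
        traj = flat_trajectory(ALL_DEPENDENT, n=1, occupancy=1.0)
        assert nursing_home_cost(traj, costs, (0.0, 1.0)) == pytest.approx(114_665.00)

    def test_negative_occupancy_rejected(self, config):
        traj = flat_trajectory(ALL_DEPENDENT, n=1, occupancy=-0.1)
        with pytest.raises(DomainError):
            nursing_home_cost(traj, config.costs, (0.0, 1.0))


class TestPointQaly:
    def test_bounds_and_examples(self):
        u = UtilityWeights()
        assert point_qaly(ALL_INDEPENDENT, u, 100) == pytest.approx(74.0)
        assert point_qaly(ALL_DEAD, u, 100) == 0.0

    def test_monotone_in_independent_fraction(self):
        u = UtilityWeights()
        qalys = [
            point_qaly(
                StateDistribution(f_independent=fi, f_dependent=0.8 - fi, f_dead=0.2), u, 100
            )
            for fi in np.linspace(0, 0.8, 9)
        ]
        assert all(b > a for a, b in zip(qalys, qalys[1:]))


class TestCalibrate:
    def test_per_patient_stratum_values(self, config):
        cal = calibrate(config.anchors)
        assert cal.per_patient_cost[1]["ci"] == pytest.approx(5_982_964 / 35)
        assert cal.per_patient_cost[1]["ci"] == pytest.approx(170_941.83, abs=0.01)
        assert cal.per_patient_qaly[1]["no_ci"] == pytest.approx(0.66)

    def test_thirty_year_identity(self, config):
        cal = calibrate(config.anchors)
        assert abs(cal.identity_residual) <= 1.0

    def test_year1_perturbation_shifts_only_per_patient(self, config):
        anchors = config.anchors.model_copy(deep=True)
        anchors.year1["ci"] = StratumAnchor(
            total_cost=anchors.year1["ci"].total_cost + 1_000_000, qaly=anchors.year1["ci"].qaly
        )
        cal = calibrate(anchors)  # identity involves only 5y/30y figures
        base = calibrate(config.anchors)
        shift = cal.per_patient_cost[1]["ci"] - base.per_patient_cost[1]["ci"]
        assert shift == pytest.approx(1_000_000 / 35)

    def test_identity_violation_raises(self, config):
        anchors = config.anchors.model_copy(deep=True)
        anchors.year5["ci"] = StratumAnchor(
            total_cost=anchors.year5["ci"].total_cost + 1e6, qaly=anchors.year5["ci"].qaly
        )
        with pytest.raises(CalibrationError):
            calibrate(anchors)


class TestScenarioTotals:
    def test_base_case_one_year(self, config):
        res = scenario_totals(CohortSpec(), 1, config)
        assert res.total_cost == pytest.approx(13_777_940, abs=1)
        assert res.total_qaly == pytest.approx(56.9, abs=1e-9)

    @pytest.mark.parametrize(
        "p,cost,qaly",
        [(0.30, 13_522_844, 58.2), (0.25, 13_267_749, 59.5), (0.20, 13_012_653, 60.8)],
    )
    def test_one_year_scenario_cells(self, config, p, cost, qaly):
        res = scenario_totals(CohortSpec(p_infarction=p), 1, config)
        assert res.total_cost == pytest.approx(cost, abs=2)
        assert round(res.total_qaly, 1) == qaly

    def test_degenerate_single_stratum_mixture(self, config):
        res = scenario_totals(CohortSpec(p_infarction=0.0), 1, config)
        assert res.total_cost == pytest.approx(100 * 7_794_976 / 65)
        assert res.total_qaly == pytest.approx(100 * 0.66)

    def test_one_year_totals_affine_in_p(self, config):
        costs = [
            scenario_totals(CohortSpec(p_infarction=p), 1, config).total_cost
            for p in (0.10, 0.20, 0.30)
        ]
        assert costs[1] == pytest.approx((costs[0] + costs[2]) / 2, rel=1e-12)

    def test_stored_five_and_thirty_year_cells(self, config):
        assert scenario_totals(CohortSpec(p_infarction=0.20), 5, config).total_cost == pytest.approx(
            20_571_518.30
        )
        assert scenario_totals(CohortSpec(p_infarction=0.25), 30, config).total_qaly == 19.5

    def test_cumulative_cost_nondecreasing_in_horizon(self, config):
        for p in (0.35, 0.30, 0.25, 0.20):
            totals = [
                scenario_totals(CohortSpec(p_infarction=p), h, config).total_cost
                for h in (1, 5, 30)
            ]
            assert totals[0] <= totals[1] <= totals[2]

    def test_unknown_horizon_without_anchors(self, config):
        with pytest.raises(ConfigurationError):
            scenario_totals(CohortSpec(), 7, config)

    def test_stratum_breakdown_sums_to_total(self, config):
        res = scenario_totals(CohortSpec(), 5, config)
        assert res.per_stratum is not None
        assert sum(s.cost for s in res.per_stratum.values()) == pytest.approx(res.total_cost)


class TestMechanisticMode:
    def test_base_case_year1_matches_anchors_exactly(self, config):
        res = scenario_totals(CohortSpec(), 1, config, mode="mechanistic")
        assert res.total_cost == pytest.approx(13_777_940, abs=1)
        assert res.total_qaly == pytest.approx(56.9, abs=1e-9)

    def test_qalys_match_anchors_at_every_horizon(self, config):
        for h, expected in ((1, 56.9), (5, 56.1), (30, 18.28)):
            res = scenario_totals(CohortSpec(), h, config, mode="mechanistic")
            assert res.total_qaly == pytest.approx(expected, abs=1e-9)

    def test_residual_report_documents_cost_deviation(self, config):
        """Later-horizon mechanistic costs deviate from anchors by a bounded,
        reported residual; 1-year residuals are zero by calibration."""
        report = residual_report(config)
        y1 = report[report.horizon_years == 1]
        assert np.allclose(y1.cost_residual, 0, atol=1e-6)
        assert np.allclose(report.qaly_residual, 0, atol=1e-12)
        y5 = report[report.horizon_years == 5]
        assert (y5.cost_residual.abs() / y5.cost_anchor < 0.06).all()


class TestScenarioFrame:
    def test_grid_cardinality_and_columns(self, config):
        frame = scenario_frame(config)
        assert len(frame) == 12  # 4 proportions x 3 horizons
        assert {"p_infarction", "horizon_years", "total_cost", "total_qaly"} <= set(frame.columns)
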