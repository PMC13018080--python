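import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sahcue.parameters import TransitionSchedule, default_config
from sahcue.state import StateDistribution

settings.register_profile(
    "default", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return default_config()


def random_schedule(rng: np.random.Generator) -> TransitionSchedule:
    """A valid random 3-state schedule (dead absorbing, rows stochastic)."""

    def stochastic_matrix():
        m = rng.dirichlet(np.ones(3), size=2)
        return np.vstack([m, [0.0, 0.0, 1.0]]).tolist()

    def dist():
        v = rng.dirichlet(np.ones(3))
        return StateDistribution(f_independent=v[0], f_dependent=v[1], f_dead=v[2])

    return TransitionSchedule(
        dist_3mo_by_stratum={"ci": dist(), "no_ci": dist()},
        transitions_y1_to_y5={
            s: [stochastic_matrix() for _ in range(4)] for s in ("ci", "no_ci")
        },
        mortality_post5y={
            s: {"independent": float(rng.uniform(0, 1)), "dependent": float(rng.uniform(0, 1))}
            for s in ("ci", "no_ci")
        },
    )


def brute_force_trajectory(schedule: TransitionSchedule, stratum: str, grid) -> np.ndarray:
    """Independent oracle: explicit matrix products on the same grid."""
    v0 = schedule.dist_3mo_by_stratum[stratum].as_array()
    mats = [np.asarray(m, float) for m in schedule.transitions_y1_to_y5[stratum]]
    mort = schedule.mortality_post5y[stratum]
    mi, md = mort["independent"], mort["dependent"]
    annual = np.array([[1 - mi, 0, mi], [0, 1 - md, md], [0, 0, 1]])
    interval_ends = [1.0, 2.0, 3.0, 5.0]
    out = []
    for t in grid:
        if t == 0.25:
            out.append(v0)
            continue
        prod = np.eye(3)
        for end, m in zip(interval_ends, mats):
            if end <= t:
                prod = prod @ m
        if t > 5:
            prod = prod @ np.linalg.matrix_power(annual, int(t) - 5)
        out.append(v0 @ prod)
    return np.array(out)
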