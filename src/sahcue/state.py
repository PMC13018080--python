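"""Three-state functional-status distribution.

The whole economic model runs on a collapsed modified Rankin Scale:
functionally independent (mRS 0-2), functionally dependent (mRS 3-5),
and dead (mRS 6).
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, model_validator

#: canonical state order used by every matrix in the package
STATES = ("independent", "dependent", "dead")

SUM_TOL = 1e-12


class StateDistribution(BaseModel):
    """Fractions of a cohort in each functional band at one time point."""

    f_independent: float
    f_dependent: float
    f_dead: float

    @model_validator(mode="after")
    def _check(self) -> "StateDistribution":
        for name in ("f_independent", "f_dependent", "f_dead"):
            v = getattr(self, name)
            if not -SUM_TOL <= v <= 1 + SUM_TOL:
                raise ValueError(f"{name}={v} outside [0, 1]")
        total = self.f_independent + self.f_dependent + self.f_dead
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"state fractions sum to {total}, not 1")
        return self

    @property
    def f_alive(self) -> float:
        return self.f_independent + self.f_dependent

    def as_array(self) -> np.ndarray:
        return np.array([self.f_independent, self.f_dependent, self.f_dead])

    @classmethod
    def from_array(cls, v: np.ndarray) -> "StateDistribution":
        return cls(f_independent=float(v[0]), f_dependent=float(v[1]), f_dead=float(v[2]))
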