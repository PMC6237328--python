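"""Net transition rates: keeping risk-factor prevalence stationary.

The consistency experiment requires the age- and sex-specific
risk-factor prevalence to stay constant over calendar time while
individuals age.  The "net transition" estimator computes, for each age,
the minimal probabilities of moving between *adjacent* ordered states
(never|current|former, or BMI bands) that carry the age-``a`` prevalence
vector exactly onto the age-``a+1`` one.

For each boundary k between adjacent ordered states, the signed net flow
is the change in cumulative prevalence of states 1..k:
``F_k(a) - F_k(a+1)``.  A positive flow moves mass from state k to k+1;
a negative flow moves it back.  Notably, when the share of the first
state *rises* with age (as for never-smoking women with strong
generational patterns), the estimator must convert current smokers back
into never smokers — a flow that does not exist in real life but is
forced by stationarity.  This artifact is intentional and must not be
"corrected": mortality is deliberately ignored when estimating the
transitions, so simulated prevalence may drift slightly from the
schedule at high ages once risk-dependent mortality operates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ratetable import SEXES, sex_index
from .scenario import RiskFactor

_ROW_SUM_TOL = 1e-12


@dataclass
class TransitionSchedule:
    """Row-stochastic matrices T(a) per (sex, age) over risk states.

    ``matrices[s, a, i, j]`` is the probability of moving from state i
    to state j between ages a and a+1.  ``T(a_max)`` is the identity
    (there is no a+1 target).  Off-diagonal mass sits only on adjacent
    ordered states.
    """

    states: tuple[str, ...]
    matrices: np.ndarray  # (2, a_max+1, n, n)

    @property
    def a_max(self) -> int:
        return self.matrices.shape[1] - 1

    def matrix(self, sex: str, age: int) -> np.ndarray:
        return self.matrices[sex_index(sex), age]

    def to_frame(self) -> pd.DataFrame:
        n = len(self.states)
        recs = []
        for si, sex in enumerate(SEXES):
            for a in range(self.a_max + 1):
                for i in range(n):
                    for j in range(n):
                        p = self.matrices[si, a, i, j]
                        if p != 0.0:
                            recs.append((sex, a, self.states[i], self.states[j], p))
        return pd.DataFrame(
            recs, columns=["sex", "age", "from_state", "to_state", "probability"]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def estimate_net_transitions(risk_factor: RiskFactor) -> TransitionSchedule:
    """Estimate the net transition schedule holding prevalence stationary.

    Guarantees ``prev(a) @ T(a) == prev(a+1)`` exactly (to rounding) at
    every age.  Raises if a required flow exceeds the mass of its source
    state ("infeasible net flow").
    """
    states = risk_factor.states
    n = len(states)
    prev = risk_factor.prevalence_array()  # (n, 2, A+1)
    a_max = prev.shape[2] - 1
    mats = np.tile(np.eye(n), (2, a_max + 1, 1, 1))

    for si, sex in enumerate(SEXES):
        p = prev[:, si, :]  # (n, A+1)
        cum = np.cumsum(p, axis=0)
        for a in range(a_max):
            flows = cum[:-1, a] - cum[:-1, a + 1]  # boundary k: states k|k+1
            T = np.eye(n)
            for k, f in enumerate(flows):
                if f > 0:  # mass moves k -> k+1
                    src = p[k, a]
                    if f > src * (1.0 + 1e-12):
                        raise ValueError(
                            f"infeasible net flow at ({sex}, age {a}, boundary "
                            f"{states[k]}|{states[k + 1]}): flow {f:g} exceeds "
                            f"source mass {src:g}"
                        )
                    q = f / src
                    T[k, k + 1] += q
                    T[k, k] -= q
                elif f < 0:  # mass moves k+1 -> k
                    src = p[k + 1, a]
                    if -f > src * (1.0 + 1e-12):
                        raise ValueError(
                            f"infeasible net flow at ({sex}, age {a}, boundary "
                            f"{states[k]}|{states[k + 1]}): flow {-f:g} exceeds "
                            f"source mass {src:g}"
                        )
                    q = -f / src
                    T[k + 1, k] += q
                    T[k + 1, k + 1] -= q
            if np.any(np.diag(T) < -1e-12):
                i = int(np.argmin(np.diag(T)))
                raise ValueError(
                    f"infeasible net flow at ({sex}, age {a}): combined outflow "
                    f"from state {states[i]} exceeds its mass"
                )
            mats[si, a] = np.clip(T, 0.0, 1.0)
            # exact row-stochastic repair of rounding
            mats[si, a] /= mats[si, a].sum(axis=1, keepdims=True)
    return TransitionSchedule(states=states, matrices=mats)


def stationarity_residual(schedule: TransitionSchedule, risk_factor: RiskFactor) -> float:
    """Max over (sex, age) of the L1 distance between ``prev(a) @ T(a)``
    and ``prev(a+1)``.  By construction ``estimate_net_transitions``
    yields a residual at rounding level (<= 1e-12)."""
    prev = risk_factor.prevalence_array()
    a_max = prev.shape[2] - 1
    if schedule.a_max != a_max or len(schedule.states) != prev.shape[0]:
        raise ValueError("schedule and prevalence shapes disagree")
    worst = 0.0
    for si in range(2):
        for a in range(a_max):
            got = prev[:, si, a] @ schedule.matrices[si, a]
            worst = max(worst, float(np.abs(got - prev[:, si, a + 1]).sum()))
    return worst
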