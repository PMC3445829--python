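"""Monte-Carlo trial simulator.

The evaluation engine is exact, so simulation is not needed to compute
operating characteristics; this module provides an independent cross-check
oracle for that engine and a generator of demonstration datasets.  Trials
are drawn directly from the two-stage binomial model: X1 ~ Bin(n1, pi),
and X2 ~ Bin(n2', pi) whenever X1 clears the futility boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import TwoStageDesign

__all__ = ["SimulatedTrialSet", "simulate_trials"]


@dataclass(frozen=True)
class SimulatedTrialSet:
    design: TwoStageDesign
    n2_actual: int
    pi: float
    n_trials: int
    seed: int
    m: np.ndarray
    x1: np.ndarray
    x2: np.ndarray  # -1 where the trial stopped at stage 1

    @property
    def s(self) -> np.ndarray:
        return np.where(self.m == 2, self.x1 + self.x2, self.x1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial_id": np.arange(self.n_trials),
                "m": self.m,
                "x1": self.x1,
                "x2": np.where(self.m == 2, self.x2, pd.NA),
                "s": self.s,
            }
        )


def simulate_trials(
    design: TwoStageDesign,
    n2_actual: int,
    pi: float,
    n_trials: int,
    seed: int,
) -> SimulatedTrialSet:
    """Draw ``n_trials`` independent trials; reproducible for a fixed seed."""
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    rng = np.random.default_rng(seed)
    x1 = rng.binomial(design.n1, pi, size=n_trials)
    cont = x1 > design.r1
    x2 = np.full(n_trials, -1, dtype=np.int64)
    x2[cont] = rng.binomial(n2_actual, pi, size=int(cont.sum()))
    m = np.where(cont, 2, 1)
    return SimulatedTrialSet(
        design=design,
        n2_actual=n2_actual,
        pi=pi,
        n_trials=n_trials,
        seed=seed,
        m=m,
        x1=x1,
        x2=x2,
    )
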