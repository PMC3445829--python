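"""One-sided p-values for H0: pi <= pi0 after a two-stage trial.

The sequential design makes "at least as extreme" ambiguous; each p-value
corresponds to one ordering of the (M, S) outcome space:

* ``naive_pvalue`` — pretends S is a plain binomial count on the attained
  total sample size (sums over impossible sample paths with X1 <= r1).
* ``mle_order_pvalue`` — orders outcomes by the sample proportion.
* ``stagewise_pvalue`` — stage-wise (equivalently UMVUE) ordering: any
  continuation is more extreme than any early stop.  Its test reproduces the
  design's own decision boundary exactly.
* ``conditional_pvalue`` — tail of S given the trial reached stage 2.
* ``koyama_chen_pvalue`` — conditional-power ordering for trials whose
  attained second-stage size differs from plan; identical to the stage-wise
  p-value when n2' = n2 (its planned-size definition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .design import TrialOutcome, TwoStageDesign, outcome_distribution
from .adaptation import conditional_power_vec, solve_equivalent_pi

__all__ = [
    "PValueSet",
    "naive_pvalue",
    "mle_order_pvalue",
    "stagewise_pvalue",
    "conditional_pvalue",
    "koyama_chen_pvalue",
    "pvalues_all",
]


@dataclass(frozen=True)
class PValueSet:
    naive: float
    mle_order: float
    stagewise: float
    conditional: float
    koyama_chen: float

    def as_dict(self) -> dict[str, float]:
        return {
            "naive": self.naive,
            "mle_order": self.mle_order,
            "stagewise": self.stagewise,
            "conditional": self.conditional,
            "koyama_chen": self.koyama_chen,
        }


def naive_pvalue(outcome: TrialOutcome, n1: int, n2_actual: int, pi0: float) -> float:
    """Binomial tail ignoring the stopping rule (all x1 from 0 to n1)."""
    s = outcome.s
    if outcome.m == 1:
        return float(binom.sf(s - 1, n1, pi0))
    x1 = np.arange(0, n1 + 1)
    return float(np.sum(binom.pmf(x1, n1, pi0) * binom.sf(s - x1 - 1, n2_actual, pi0)))


def mle_order_pvalue(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, pi0: float
) -> float:
    """Mass of all outcomes whose sample proportion is >= the observed one."""
    obs = outcome.s / n1 if outcome.m == 1 else outcome.s / (n1 + n2_actual)
    space, probs = outcome_distribution(n1, r1, n2_actual, pi0)
    ntp = n1 + n2_actual
    total = 0.0
    for (m, s), p in zip(space, probs):
        est = s / n1 if m == 1 else s / ntp
        if est >= obs - 1e-12:
            total += p
    return float(min(1.0, total))


def stagewise_pvalue(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, pi0: float
) -> float:
    return _stagewise_upper_tail(outcome.m, outcome.s, n1, r1, n2_actual, pi0)


def _stagewise_upper_tail(
    m: int, s: int, n1: int, r1: int, n2_actual: int, pi0: float
) -> float:
    """Pr_pi0(outcome at least as extreme in stage-wise order)."""
    if m == 1:
        return float(binom.sf(s - 1, n1, pi0))
    x1 = np.arange(r1 + 1, n1 + 1)
    return float(np.sum(binom.pmf(x1, n1, pi0) * binom.sf(s - x1 - 1, n2_actual, pi0)))


def conditional_pmf(n1: int, r1: int, n2_actual: int, pi: float) -> tuple[np.ndarray, np.ndarray]:
    """pmf of S given M=2: values s = r1+1..n1+n2' and their probabilities."""
    space, probs = outcome_distribution(n1, r1, n2_actual, pi)
    cont = probs[r1 + 1:]
    denom = float(binom.sf(r1, n1, pi))
    return np.arange(r1 + 1, n1 + n2_actual + 1), cont / denom


def conditional_pvalue(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, pi0: float
) -> float:
    """Upper tail of S given M=2; reduces to the stage-1 tail after a stop."""
    if outcome.m == 1:
        return float(binom.sf(outcome.s - 1, n1, pi0))
    values, probs = conditional_pmf(n1, r1, n2_actual, pi0)
    return float(min(1.0, probs[values >= outcome.s].sum()))


def koyama_chen_pvalue(
    x1: int, x2: int, design: TwoStageDesign, n2_actual: int, pi0: float
) -> float:
    """Unconditional p-value under the conditional-power ordering.

    The observed second-stage tail Pr_pi0(X2' >= x2) on the attained size is
    translated into an equivalent response rate pi* through the planned
    conditional power A(x1, n2, .), and the p-value aggregates A(., n2, pi*)
    over all continuation paths.  With the planned size attained this is
    defined as the stage-wise p-value (the two orderings agree at the planned
    size by construction of the method).

    Conventions at the edges: a first stage already over the final boundary
    (x1 > rt) has conditional power one whatever pi, and is scored as maximal
    evidence (pi* -> 0); x2 = 0 gives an observed tail of one, hence pi* -> 1
    and a p-value equal to the continuation probability Pr_pi0(X1 > r1).
    """
    n1, n2, r1, rt = design.n1, design.n2, design.r1, design.rt
    if not r1 < x1 <= n1:
        raise ValueError(f"continuation requires r1 < x1 <= n1, got x1={x1}")
    s = x1 + x2
    if n2_actual == n2:
        return _stagewise_upper_tail(2, s, n1, r1, n2_actual, pi0)
    if x1 > rt:
        pi_star = 0.0
    else:
        target = float(binom.sf(x2 - 1, n2_actual, pi0))
        pi_star = solve_equivalent_pi(x1, design, target)
    xs = np.arange(r1 + 1, n1 + 1)
    a = conditional_power_vec(xs, n2, rt, pi_star)
    return float(min(1.0, np.sum(binom.pmf(xs, n1, pi0) * a)))


def pvalues_all(
    outcome: TrialOutcome, design: TwoStageDesign, pi0: float, n2_actual: int | None = None
) -> PValueSet:
    """All five p-values for one outcome.

    After an early stop the stage-wise, conditional and conditional-power
    p-values all equal the first-stage binomial tail.
    """
    n2p = n2_actual if n2_actual is not None else (
        outcome.n2_actual if outcome.n2_actual is not None else design.n2
    )
    n1, r1 = design.n1, design.r1
    outcome.validate_against(n1, r1)
    ps = stagewise_pvalue(outcome, n1, r1, n2p, pi0)
    if outcome.m == 1:
        pk = ps
    else:
        pk = koyama_chen_pvalue(outcome.x1, outcome.x2, design, n2p, pi0)
    return PValueSet(
        naive=naive_pvalue(outcome, n1, n2p, pi0),
        mle_order=mle_order_pvalue(outcome, n1, r1, n2p, pi0),
        stagewise=ps,
        conditional=conditional_pvalue(outcome, n1, r1, n2p, pi0),
        koyama_chen=pk,
    )
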