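"""Conditional-power machinery for attained second-stage sample sizes.

When accrual over- or under-shoots the planned n2 non-informatively, the
final boundary rt no longer controls the type-I error.  The fix keeps the
conditional type-I error of the original design: given x1 first-stage
responses, the planned design would wrongly reject stage 2 with probability
A(x1, n2, pi0) (the conditional power at pi0), so the attained-size rule
rejects exactly when the attained second-stage tail Pr_pi0(X2' >= x2) does
not exceed that budget.  The resulting unconditional type-I error can only
shrink.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import beta as beta_dist
from scipy.stats import binom

from .design import TwoStageDesign

__all__ = [
    "AdjustedRule",
    "conditional_power",
    "solve_equivalent_pi",
    "adjusted_critical_value",
    "adjusted_type1_error",
    "conditional_power_vec",
]

_BRACKET = (1e-12, 1.0 - 1e-12)


@dataclass(frozen=True)
class AdjustedRule:
    """Attained-size stage-2 rejection rule for one first-stage result.

    ``r2_adjusted`` is the minimal number of second-stage responses that
    rejects; ``n2_actual + 1`` encodes "never reject".
    """

    x1: int
    n2_actual: int
    r2_adjusted: int
    conditional_alpha: float


def conditional_power(x1: int, n2: int, rt: int, pi: float) -> float:
    """Probability of crossing the final boundary given x1: Pr_pi(X2 > rt - x1)."""
    k = rt - x1 + 1  # responses still needed
    if k <= 0:
        return 1.0
    if k > n2:
        return 0.0
    return float(binom.sf(k - 1, n2, pi))


def solve_equivalent_pi(x1: int, design: TwoStageDesign, target: float) -> float:
    """Response rate pi* at which the planned conditional power equals ``target``.

    A(x1, n2, .) is strictly increasing on (0, 1) whenever 0 < rt - x1 + 1 <=
    n2, and equals the regularized incomplete beta function in pi, so the
    inverse is a beta quantile.  Targets outside the attainable range are
    clamped to the corresponding endpoint.
    """
    n2, rt = design.n2, design.rt
    k = rt - x1 + 1
    if k <= 0:
        # conditional power is one regardless of pi: maximal evidence
        return 0.0
    if k > n2 or target >= 1.0:
        return 1.0
    if target <= 0.0:
        return 0.0
    # Pr_p(X2 >= k) = I_p(k, n2 - k + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(beta_dist.ppf(target, k, n2 - k + 1))
    if not np.isfinite(p):  # boost quantile can give up at extreme tails
        lo, hi = _BRACKET
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if float(binom.sf(k - 1, n2, mid)) < target:
                lo = mid
            else:
                hi = mid
        p = 0.5 * (lo + hi)
    return min(1.0, max(0.0, p))


def conditional_power_vec(x1: np.ndarray, n2: int, rt: int, pi: float) -> np.ndarray:
    """Vectorised conditional power over an array of first-stage counts."""
    k = rt - x1 + 1
    a = np.where(k <= 0, 1.0, binom.sf(np.clip(k, 1, n2 + 1) - 1, n2, pi))
    return np.where(k > n2, 0.0, a)


def adjusted_critical_value(
    x1: int, design: TwoStageDesign, n2_actual: int, pi0: float
) -> AdjustedRule:
    """Smallest x2 whose attained-size tail fits in the planned conditional
    type-I error budget A(x1, n2, pi0)."""
    n1, n2, r1, rt = design.n1, design.n2, design.r1, design.rt
    if not r1 < x1 <= n1:
        raise ValueError(f"continuation requires r1 < x1 <= n1, got x1={x1}")
    budget = conditional_power(x1, n2, rt, pi0)
    for x2 in range(n2_actual + 1):
        if float(binom.sf(x2 - 1, n2_actual, pi0)) <= budget:
            return AdjustedRule(x1=x1, n2_actual=n2_actual, r2_adjusted=x2, conditional_alpha=budget)
    return AdjustedRule(
        x1=x1, n2_actual=n2_actual, r2_adjusted=n2_actual + 1, conditional_alpha=budget
    )


def adjusted_type1_error(design: TwoStageDesign, n2_actual: int, pi0: float) -> float:
    """Unconditional type-I error of the attained-size rule at pi0."""
    total = 0.0
    for x1 in range(design.r1 + 1, design.n1 + 1):
        rule = adjusted_critical_value(x1, design, n2_actual, pi0)
        tail = float(binom.sf(rule.r2_adjusted - 1, n2_actual, pi0)) if rule.r2_adjusted <= n2_actual else 0.0
        total += float(binom.pmf(x1, design.n1, pi0)) * tail
    return total
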