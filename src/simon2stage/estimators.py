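"""Point estimators of the response rate after a two-stage trial.

Data-dependent stopping makes the sample proportion (MLE) negatively biased:
trials that stop early freeze a low first-stage proportion with no chance of
correction.  The estimators here take different routes around that optional
sampling effect:

* ``mle`` — the raw sample proportion S/N.
* ``whitehead_estimator`` — bias-adjusted: solves p + b(p) = MLE.
* ``guo_estimator`` — one-step bias subtraction: MLE - b(MLE).
* ``umvue`` — Rao-Blackwellisation of X1/n1 given the sufficient statistic
  (M, S); exactly unbiased, and still valid when the attained second-stage
  size differs from plan because it never uses the stage-2 boundary.
* ``umvcue`` — Rao-Blackwellisation of X2/n2' given (M=2, S); exactly
  unbiased conditionally on reaching stage 2.
* ``conditional_mle`` — maximises the likelihood of the truncated model
  given X1 > r1.
* ``median_estimator`` — the response rate at which the trial's p-value is
  one half (median-unbiased flavour, used by the conditional-power method
  for attained sample sizes).

All estimators depend on the data through (m, s) only, except the median
estimator for modified second-stage sizes, which needs (x1, x2) separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import binom

from .design import TrialOutcome, TwoStageDesign, outcome_distribution

__all__ = [
    "EstimateSet",
    "mle",
    "bias_of_mle",
    "whitehead_estimator",
    "guo_estimator",
    "umvue",
    "umvcue",
    "conditional_mle",
    "median_estimator",
    "estimate_all",
]

_BRACKET = (1e-9, 1.0 - 1e-9)
_XTOL = 1e-10


@dataclass(frozen=True)
class EstimateSet:
    """All point estimates for one observed outcome."""

    mle: float
    whitehead: float
    guo: float
    umvue: float
    conditional_mle: float
    umvcue: float
    median: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mle": self.mle,
            "whitehead": self.whitehead,
            "guo": self.guo,
            "umvue": self.umvue,
            "conditional_mle": self.conditional_mle,
            "umvcue": self.umvcue,
            "median": self.median,
        }


def mle(outcome: TrialOutcome, n1: int) -> float:
    """Sample proportion: s/n1 after an early stop, s/(n1+n2') otherwise."""
    if outcome.m == 1:
        return outcome.s / n1
    return outcome.s / (n1 + outcome.n2_actual)


def bias_of_mle(n1: int, r1: int, n2_actual: int, pi: float) -> float:
    """Exact bias b(pi) of the sample proportion under the stopping rule."""
    space, probs = outcome_distribution(n1, r1, n2_actual, pi)
    ntp = n1 + n2_actual
    est = np.array([s / n1 if m == 1 else s / ntp for m, s in space])
    return float(est @ probs) - pi


def whitehead_estimator(outcome: TrialOutcome, n1: int, r1: int, n2_actual: int) -> float:
    """Bias-adjusted estimate: the root of p + b(p) = MLE.

    b can be non-monotone, so the root is bracketed by a sign-change scan on a
    fixed grid before bisection; with no sign change the boundary value coming
    closest to solving the equation is returned.
    """
    target = mle(outcome, n1)

    def g(p: float) -> float:
        return p + bias_of_mle(n1, r1, n2_actual, p) - target

    grid = np.linspace(_BRACKET[0], _BRACKET[1], 201)
    vals = np.array([g(p) for p in grid])
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_change) == 0:
        return float(grid[np.argmin(np.abs(vals))])
    i = int(sign_change[0])
    root = brentq(g, grid[i], grid[i + 1], xtol=1e-8)
    return float(min(1.0, max(0.0, root)))


def guo_estimator(outcome: TrialOutcome, n1: int, r1: int, n2_actual: int) -> float:
    """One-step bias correction: MLE - b(MLE), clamped to [0, 1]."""
    e = mle(outcome, n1)
    return float(min(1.0, max(0.0, e - bias_of_mle(n1, r1, n2_actual, e))))


def umvue(outcome: TrialOutcome, n1: int, r1: int, n2_actual: int) -> float:
    """Uniformly minimum variance unbiased estimator.

    E[X1/n1 | (M, S)]: for continuations a ratio of truncated convolution
    sums, computed in exact integer arithmetic.
    """
    if outcome.m == 1:
        return outcome.s / n1
    s = outcome.s
    lo = max(r1 + 1, s - n2_actual)
    hi = min(s, n1)
    num = sum(math.comb(n1 - 1, x1 - 1) * math.comb(n2_actual, s - x1) for x1 in range(lo, hi + 1))
    den = sum(math.comb(n1, x1) * math.comb(n2_actual, s - x1) for x1 in range(lo, hi + 1))
    return num / den


def umvcue(outcome: TrialOutcome, n1: int, r1: int, n2_actual: int) -> float:
    """Minimum variance estimator unbiased given the trial reached stage 2.

    E[X2/n2' | M=2, S]; the first-stage proportion s/n1 (equal to the UMVUE)
    is reported when the trial stopped early.
    """
    if outcome.m == 1:
        return outcome.s / n1
    s = outcome.s
    lo = max(r1 + 1, s - n2_actual)
    hi = min(s, n1)
    num = sum(
        math.comb(n1, x1) * math.comb(n2_actual - 1, s - x1 - 1)
        for x1 in range(lo, hi + 1)
        if s - x1 >= 1
    )
    den = sum(math.comb(n1, x1) * math.comb(n2_actual, s - x1) for x1 in range(lo, hi + 1))
    return num / den


def conditional_mle(outcome: TrialOutcome, n1: int, r1: int, n2_actual: int) -> float:
    """MLE of the truncated model given continuation (X1 > r1).

    Maximises s*log(p) + (nt'-s)*log(1-p) - log Pr_p(X1 > r1); depends on the
    data only through s.  Falls back to the plain MLE s/n1 after an early stop.
    """
    if outcome.m == 1:
        return outcome.s / n1
    s = outcome.s
    ntp = n1 + n2_actual

    def nll(p: float) -> float:
        return -(
            s * math.log(p)
            + (ntp - s) * math.log1p(-p)
            - math.log(float(binom.sf(r1, n1, p)))
        )

    res = minimize_scalar(nll, bounds=_BRACKET, method="bounded", options={"xatol": _XTOL})
    p = float(res.x)
    # bounded Brent can sit at an interior stationary point when the optimum
    # is on the boundary; compare against the bracket ends explicitly
    for edge in _BRACKET:
        if nll(edge) < nll(p):
            p = edge
    return float(min(1.0, max(0.0, p)))


def median_estimator(
    outcome: TrialOutcome, design: TwoStageDesign, n2_actual: int
) -> float:
    """Response rate at which the trial's p-value equals one half.

    For continuations this inverts the conditional-power (attained-n2)
    p-value, which coincides with the stage-wise p-value when n2' = n2.  The
    construction is undefined after an early stop, where — as for the other
    estimators that exist only for continuations — the unconditional sample
    proportion s/n1 is reported.
    """
    from .pvalues import koyama_chen_pvalue  # local import to avoid a cycle

    if outcome.m == 1:
        return outcome.s / design.n1

    def g(p: float) -> float:
        return koyama_chen_pvalue(outcome.x1, outcome.x2, design, n2_actual, p) - 0.5

    lo, hi = _BRACKET
    if g(lo) >= 0.0:
        return 0.0
    if g(hi) <= 0.0:  # pragma: no cover - p-value reaches 1 as pi -> 1
        return 1.0
    return float(brentq(g, lo, hi, xtol=1e-8))


def estimate_all(
    outcome: TrialOutcome, design: TwoStageDesign, n2_actual: int | None = None
) -> EstimateSet:
    """Compute every estimator for one outcome of a design."""
    n2p = n2_actual if n2_actual is not None else (
        outcome.n2_actual if outcome.n2_actual is not None else design.n2
    )
    n1, r1 = design.n1, design.r1
    outcome.validate_against(n1, r1)
    return EstimateSet(
        mle=mle(outcome, n1),
        whitehead=whitehead_estimator(outcome, n1, r1, n2p),
        guo=guo_estimator(outcome, n1, r1, n2p),
        umvue=umvue(outcome, n1, r1, n2p),
        conditional_mle=conditional_mle(outcome, n1, r1, n2p),
        umvcue=umvcue(outcome, n1, r1, n2p),
        median=median_estimator(outcome, design, n2p),
    )
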