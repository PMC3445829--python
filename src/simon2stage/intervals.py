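"""Two-sided (1 - 2*alpha) confidence intervals after a two-stage trial.

Each interval inverts a family of one-sided tail tests; they differ in which
outcome distribution and which ordering of the outcome space they use:

* ``naive_exact_ci`` — Clopper-Pearson on the pooled count, ignoring the
  stopping rule.
* ``exact_stagewise_ci`` — equal-tail inversion of the stage-wise ordering
  tails of (M, S); the standard exact interval for group-sequential designs.
* ``midp_stagewise_ci`` — same tails with half-weight on the observed
  outcome, trading guaranteed coverage for less conservatism.
* ``conditional_exact_ci`` / ``conditional_midp_ci`` — Clopper-Pearson-type
  and mid-p inversion of the distribution of S given the trial reached
  stage 2.
* ``conditional_score_cc_ci`` — inversion of the standardized score of the
  truncated (given X1 > r1) likelihood, continuity-corrected by default.
* ``koyama_chen_ci`` — equal-tail inversion of the conditional-power
  ordering p-value for attained second-stage sizes; identical to the exact
  stage-wise interval when n2' = n2.

With the one-sided level alpha = 0.05 these are the usual "90% CI" of
phase II reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist
from scipy.stats import binom, norm

from .adaptation import conditional_power_vec, solve_equivalent_pi
from .design import TrialOutcome, TwoStageDesign, outcome_pmf

__all__ = [
    "ConfidenceInterval",
    "naive_exact_ci",
    "exact_stagewise_ci",
    "midp_stagewise_ci",
    "conditional_exact_ci",
    "conditional_score_cc_ci",
    "conditional_midp_ci",
    "koyama_chen_ci",
    "intervals_all",
]

_BRACKET = (1e-9, 1.0 - 1e-9)
_XTOL = 1e-8


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float
    method: str

    def contains(self, pi: float) -> bool:
        return self.lower <= pi <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _solve_increasing(f, alpha: float) -> float:
    """Root of an increasing tail function; degenerate tails pin the bound."""
    lo, hi = _BRACKET
    if f(lo) >= alpha:
        return 0.0
    if f(hi) <= alpha:
        return 1.0
    return float(brentq(f_minus(f, alpha), lo, hi, xtol=_XTOL))


def _solve_decreasing(f, alpha: float) -> float:
    lo, hi = _BRACKET
    if f(hi) >= alpha:
        return 1.0
    if f(lo) <= alpha:
        return 0.0
    return float(brentq(f_minus(f, alpha), lo, hi, xtol=_XTOL))


def f_minus(f, alpha: float):
    return lambda p: f(p) - alpha


# ---------------------------------------------------------------------------
# tail functions in the stage-wise ordering
# ---------------------------------------------------------------------------

def _upper_tail(m: int, s: int, n1: int, r1: int, n2p: int, pi: float) -> float:
    """Pr_pi(outcome >= observed) in stage-wise order."""
    if m == 1:
        return float(binom.sf(s - 1, n1, pi))
    x1 = np.arange(r1 + 1, n1 + 1)
    return float(np.sum(binom.pmf(x1, n1, pi) * binom.sf(s - x1 - 1, n2p, pi)))


def _lower_tail(m: int, s: int, n1: int, r1: int, n2p: int, pi: float) -> float:
    """Pr_pi(outcome <= observed) in stage-wise order."""
    if m == 1:
        return float(binom.cdf(s, n1, pi))
    x1 = np.arange(r1 + 1, n1 + 1)
    return float(
        binom.cdf(r1, n1, pi)
        + np.sum(binom.pmf(x1, n1, pi) * binom.cdf(s - x1, n2p, pi))
    )


def naive_exact_ci(s: int, n: int, alpha: float = 0.05) -> ConfidenceInterval:
    """Clopper-Pearson equal-tail interval on s successes out of n."""
    if not 0 <= s <= n:
        raise ValueError(f"need 0 <= s <= n, got s={s}, n={n}")
    lower = 0.0 if s == 0 else float(beta_dist.ppf(alpha, s, n - s + 1))
    upper = 1.0 if s == n else float(beta_dist.ppf(1.0 - alpha, s + 1, n - s))
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "naive_exact")


def exact_stagewise_ci(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, alpha: float = 0.05
) -> ConfidenceInterval:
    m, s = outcome.m, outcome.s
    lower = _solve_increasing(lambda p: _upper_tail(m, s, n1, r1, n2_actual, p), alpha)
    upper = _solve_decreasing(lambda p: _lower_tail(m, s, n1, r1, n2_actual, p), alpha)
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "stagewise")


def midp_stagewise_ci(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, alpha: float = 0.05
) -> ConfidenceInterval:
    """Stage-wise interval with half-weight on the observed outcome."""
    m, s = outcome.m, outcome.s

    def up(p: float) -> float:
        return _upper_tail(m, s, n1, r1, n2_actual, p) - 0.5 * outcome_pmf(
            n1, r1, n2_actual, m, s, p
        )

    def low(p: float) -> float:
        return _lower_tail(m, s, n1, r1, n2_actual, p) - 0.5 * outcome_pmf(
            n1, r1, n2_actual, m, s, p
        )

    lower = _solve_increasing(up, alpha)
    upper = _solve_decreasing(low, alpha)
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "midp")


# ---------------------------------------------------------------------------
# conditional (given M=2) intervals
# ---------------------------------------------------------------------------

def _cond_tails(s: int, n1: int, r1: int, n2p: int, pi: float) -> tuple[float, float, float]:
    """(upper tail, lower tail, point mass) of S given M=2."""
    denom = float(binom.sf(r1, n1, pi))
    x1 = np.arange(r1 + 1, n1 + 1)
    pmf1 = binom.pmf(x1, n1, pi)
    up = float(np.sum(pmf1 * binom.sf(s - x1 - 1, n2p, pi))) / denom
    low = float(np.sum(pmf1 * binom.cdf(s - x1, n2p, pi))) / denom
    point = float(np.sum(pmf1 * binom.pmf(s - x1, n2p, pi))) / denom
    return up, low, point


def conditional_exact_ci(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, alpha: float = 0.05
) -> ConfidenceInterval:
    """Clopper-Pearson-type inversion of the conditional law of S given M=2.

    After an early stop the conditional construction is undefined and the
    stage-wise interval (which then reduces to the first-stage construction)
    is returned.
    """
    if outcome.m == 1:
        return ConfidenceInterval(
            *_stagewise_bounds(outcome, n1, r1, n2_actual, alpha),
            1.0 - 2 * alpha,
            "conditional_exact",
        )
    s = outcome.s
    lower = _solve_increasing(lambda p: _cond_tails(s, n1, r1, n2_actual, p)[0], alpha)
    upper = _solve_decreasing(lambda p: _cond_tails(s, n1, r1, n2_actual, p)[1], alpha)
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "conditional_exact")


def conditional_midp_ci(
    outcome: TrialOutcome, n1: int, r1: int, n2_actual: int, alpha: float = 0.05
) -> ConfidenceInterval:
    if outcome.m == 1:
        return ConfidenceInterval(
            *_stagewise_bounds(outcome, n1, r1, n2_actual, alpha),
            1.0 - 2 * alpha,
            "conditional_midp",
        )
    s = outcome.s

    def up(p: float) -> float:
        u, _, point = _cond_tails(s, n1, r1, n2_actual, p)
        return u - 0.5 * point

    def low(p: float) -> float:
        _, l, point = _cond_tails(s, n1, r1, n2_actual, p)
        return l - 0.5 * point

    lower = _solve_increasing(up, alpha)
    upper = _solve_decreasing(low, alpha)
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "conditional_midp")


def _stagewise_bounds(outcome, n1, r1, n2p, alpha) -> tuple[float, float]:
    ci = exact_stagewise_ci(outcome, n1, r1, n2p, alpha)
    return ci.lower, ci.upper


def _truncated_x1_moments(n1: int, r1: int, pi: float) -> tuple[float, float]:
    """Mean and variance of X1 given X1 > r1."""
    x1 = np.arange(r1 + 1, n1 + 1)
    w = binom.pmf(x1, n1, pi)
    w = w / w.sum()
    mean = float(np.sum(w * x1))
    var = float(np.sum(w * (x1 - mean) ** 2))
    return mean, var


def conditional_score_cc_ci(
    outcome: TrialOutcome,
    n1: int,
    r1: int,
    n2_actual: int,
    alpha: float = 0.05,
    continuity_correction: bool = True,
) -> ConfidenceInterval:
    """Score interval of the truncated likelihood given continuation.

    The score statistic of the conditional model standardizes s around
    E[S | M=2] = E[X1 | X1 > r1] + n2'*p with the matching variance; the
    continuity correction shifts s by one half towards the centre.  With no
    root in (0, 1) the bound is clamped to the boundary.
    """
    if outcome.m == 1:
        return ConfidenceInterval(
            *_stagewise_bounds(outcome, n1, r1, n2_actual, alpha),
            1.0 - 2 * alpha,
            "conditional_score",
        )
    s = outcome.s
    z = float(norm.ppf(1.0 - alpha))
    cc = 0.5 if continuity_correction else 0.0

    def moments(p: float) -> tuple[float, float]:
        m1, v1 = _truncated_x1_moments(n1, r1, p)
        return m1 + n2_actual * p, v1 + n2_actual * p * (1.0 - p)

    def g_lower(p: float) -> float:  # decreasing in p
        mu, var = moments(p)
        return (s - cc - mu) - z * np.sqrt(var)

    def g_upper(p: float) -> float:  # decreasing in p
        mu, var = moments(p)
        return (s + cc - mu) + z * np.sqrt(var)

    lower = _solve_decreasing_to_zero(g_lower)
    upper = _solve_decreasing_to_zero(g_upper)
    name = "conditional_score" if continuity_correction else "conditional_score_nocc"
    return ConfidenceInterval(min(lower, upper), max(lower, upper), 1.0 - 2 * alpha, name)


def _solve_decreasing_to_zero(g) -> float:
    lo, hi = _BRACKET
    if g(lo) <= 0.0:
        return 0.0
    if g(hi) >= 0.0:
        return 1.0
    return float(brentq(g, lo, hi, xtol=_XTOL))


# ---------------------------------------------------------------------------
# attained-n2 (conditional power ordering) interval
# ---------------------------------------------------------------------------

def _kc_upper_tail(x1: int, x2: int, design: TwoStageDesign, n2p: int, pi: float) -> float:
    n1, n2, r1, rt = design.n1, design.n2, design.r1, design.rt
    if x1 > rt:
        return float(binom.sf(rt, n1, pi))
    if x2 == 0:
        return float(binom.sf(r1, n1, pi))
    target = float(binom.sf(x2 - 1, n2p, pi))
    pi_star = solve_equivalent_pi(x1, design, target)
    xs = np.arange(r1 + 1, n1 + 1)
    a = conditional_power_vec(xs, n2, rt, pi_star)
    return float(np.sum(binom.pmf(xs, n1, pi) * a))


def _kc_lower_tail(x1: int, x2: int, design: TwoStageDesign, n2p: int, pi: float) -> float:
    """Pr_pi(outcome <= observed) in the conditional-power ordering.

    Interim results already past the final boundary are tied at maximal
    evidence and ordered among themselves by x2 (declared convention for
    degenerate paths).
    """
    n1, n2, r1, rt = design.n1, design.n2, design.r1, design.rt
    if x2 == n2p:
        return 1.0
    if x1 > rt:
        return float(binom.cdf(rt, n1, pi)) + float(binom.sf(rt, n1, pi)) * float(
            binom.cdf(x2, n2p, pi)
        )
    target = float(binom.sf(x2, n2p, pi))  # strict tail: outcomes beyond observed
    pi_star = solve_equivalent_pi(x1, design, target)
    xs = np.arange(r1 + 1, n1 + 1)
    a = conditional_power_vec(xs, n2, rt, pi_star)
    return float(binom.cdf(r1, n1, pi) + np.sum(binom.pmf(xs, n1, pi) * (1.0 - a)))


def koyama_chen_ci(
    x1: int, x2: int, design: TwoStageDesign, n2_actual: int, alpha: float = 0.05
) -> ConfidenceInterval:
    """Equal-tail inversion of the conditional-power ordering.

    With the planned second-stage size attained the ordering coincides with
    the stage-wise one and the exact stage-wise interval is returned.
    """
    design_outcome = TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=n2_actual)
    if n2_actual == design.n2:
        lo, hi = _stagewise_bounds(design_outcome, design.n1, design.r1, n2_actual, alpha)
        return ConfidenceInterval(lo, hi, 1.0 - 2 * alpha, "koyama_chen")
    lower = _solve_increasing(lambda p: _kc_upper_tail(x1, x2, design, n2_actual, p), alpha)
    upper = _solve_decreasing(lambda p: _kc_lower_tail(x1, x2, design, n2_actual, p), alpha)
    return ConfidenceInterval(lower, upper, 1.0 - 2 * alpha, "koyama_chen")


def intervals_all(
    outcome: TrialOutcome,
    design: TwoStageDesign,
    alpha: float = 0.05,
    n2_actual: int | None = None,
) -> list[ConfidenceInterval]:
    """All seven intervals for one outcome."""
    n2p = n2_actual if n2_actual is not None else (
        outcome.n2_actual if outcome.n2_actual is not None else design.n2
    )
    n1, r1 = design.n1, design.r1
    outcome.validate_against(n1, r1)
    n_total = n1 if outcome.m == 1 else n1 + n2p
    out = [
        naive_exact_ci(outcome.s, n_total, alpha),
        exact_stagewise_ci(outcome, n1, r1, n2p, alpha),
        midp_stagewise_ci(outcome, n1, r1, n2p, alpha),
        conditional_exact_ci(outcome, n1, r1, n2p, alpha),
        conditional_score_cc_ci(outcome, n1, r1, n2p, alpha),
        conditional_midp_ci(outcome, n1, r1, n2p, alpha),
    ]
    if outcome.m == 2:
        out.append(koyama_chen_ci(outcome.x1, outcome.x2, design, n2p, alpha))
    else:
        ci = exact_stagewise_ci(outcome, n1, r1, n2p, alpha)
        out.append(ConfidenceInterval(ci.lower, ci.upper, ci.level, "koyama_chen"))
    return out
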