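"""Two-stage single-arm binomial designs and their exact outcome distribution.

A Simon-type two-stage trial enrols ``n1`` patients, stops for futility when
the number of first-stage responses ``X1`` is at most ``r1``, and otherwise
enrols ``n2`` further patients.  The null hypothesis (response rate at most
``pi0``) is rejected when the trial reaches stage 2 and the total number of
responses ``S = X1 + X2`` exceeds the final boundary ``rt``.  The stopping
stage ``M`` together with ``S`` is a complete sufficient statistic for the
response rate, and every operating characteristic of the trial is an exact
finite sum over the support of ``(M, S)``.

The attained second-stage sample size ``n2'`` may differ from the planned
``n2`` (non-informative over- or under-accrual); all distributional helpers
therefore take the attained size.  The decision boundaries belong to the
planned design only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.stats import binom

__all__ = [
    "DesignSpec",
    "TwoStageDesign",
    "TrialOutcome",
    "outcome_space",
    "outcome_pmf",
    "outcome_distribution",
    "joint_path_pmf",
    "design_operating_chars",
    "find_optimal_design",
    "find_minimax_design",
    "NoFeasibleDesignError",
]


@dataclass(frozen=True)
class DesignSpec:
    """Hypotheses and error rates defining the testing problem.

    ``pi0`` is the highest response rate of no further interest, ``pi1`` the
    smallest promising rate; ``alpha`` and ``beta`` bound the one-sided type I
    and type II error rates.
    """

    pi0: float
    pi1: float
    alpha: float = 0.05
    beta: float = 0.10

    def __post_init__(self) -> None:
        if not 0.0 < self.pi0 < self.pi1 < 1.0:
            raise ValueError(f"need 0 < pi0 < pi1 < 1, got pi0={self.pi0}, pi1={self.pi1}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")

    @property
    def delta(self) -> float:
        return self.pi1 - self.pi0


@dataclass(frozen=True)
class TwoStageDesign:
    """Decision rule of a two-stage design: stop iff X1 <= r1, reject iff S > rt."""

    n1: int
    n2: int
    r1: int
    rt: int

    def __post_init__(self) -> None:
        if not 0 <= self.r1 < self.n1:
            raise ValueError(f"need 0 <= r1 < n1, got r1={self.r1}, n1={self.n1}")
        if not self.r1 <= self.rt < self.nt:
            raise ValueError(f"need r1 <= rt < n1+n2, got rt={self.rt}")
        if self.n2 < 1:
            raise ValueError(f"n2 must be >= 1, got {self.n2}")

    @property
    def nt(self) -> int:
        return self.n1 + self.n2


@dataclass(frozen=True)
class TrialOutcome:
    """Observed result of one trial.

    Stage-wise methods need only ``(m, s)``; the conditional-power methods for
    attained sample sizes additionally need ``x1`` and ``x2`` separately, so
    both are retained when the trial continued.
    """

    m: int
    x1: int
    x2: int | None = None
    n2_actual: int | None = None
    s: int = field(init=False)

    def __post_init__(self) -> None:
        if self.m not in (1, 2):
            raise ValueError(f"stage m must be 1 or 2, got {self.m}")
        if self.m == 2:
            if self.x2 is None or self.n2_actual is None:
                raise ValueError("stage-2 outcomes need x2 and n2_actual")
            if self.n2_actual < 1:
                raise ValueError(f"n2_actual must be >= 1, got {self.n2_actual}")
            if not 0 <= self.x2 <= self.n2_actual:
                raise ValueError(f"x2={self.x2} outside [0, {self.n2_actual}]")
            object.__setattr__(self, "s", self.x1 + self.x2)
        else:
            object.__setattr__(self, "s", self.x1)

    def validate_against(self, n1: int, r1: int) -> None:
        """Check consistency with the stopping rule of a design."""
        if self.m == 1 and not 0 <= self.x1 <= r1:
            raise ValueError(f"m=1 requires 0 <= x1 <= r1={r1}, got x1={self.x1}")
        if self.m == 2 and not r1 < self.x1 <= n1:
            raise ValueError(f"m=2 requires r1 < x1 <= n1, got x1={self.x1}")


class NoFeasibleDesignError(RuntimeError):
    """No design within the search bound satisfies the error constraints."""


# ---------------------------------------------------------------------------
# Exact outcome distribution
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _binom_pmf_vec(n: int, p: float) -> np.ndarray:
    return binom.pmf(np.arange(n + 1), n, p)


def outcome_space(n1: int, r1: int, n2_actual: int) -> list[tuple[int, int]]:
    """Support of (M, S): stage-1 stops with 0 <= s <= r1, continuations with
    r1+1 <= s <= n1 + n2'."""
    _check_design_quantities(n1, r1, n2_actual)
    return [(1, s) for s in range(r1 + 1)] + [
        (2, s) for s in range(r1 + 1, n1 + n2_actual + 1)
    ]


def _check_design_quantities(n1: int, r1: int, n2_actual: int) -> None:
    if not 0 <= r1 < n1:
        raise ValueError(f"need 0 <= r1 < n1, got r1={r1}, n1={n1}")
    if n2_actual < 1:
        raise ValueError(f"n2_actual must be >= 1, got {n2_actual}")


def outcome_pmf(n1: int, r1: int, n2_actual: int, m: int, s: int, pi: float) -> float:
    """Exact probability of observing stage ``m`` with ``s`` total responses.

    For a continuation the mass is the convolution of the truncated stage-1
    binomial (X1 > r1) with the attained stage-2 binomial.
    """
    _check_design_quantities(n1, r1, n2_actual)
    if not 0.0 <= pi <= 1.0:
        raise ValueError(f"pi must be in [0, 1], got {pi}")
    if m == 1:
        if not 0 <= s <= r1:
            raise ValueError(f"(m=1, s={s}) outside the outcome space (0..{r1})")
        return float(binom.pmf(s, n1, pi))
    if m == 2:
        if not r1 + 1 <= s <= n1 + n2_actual:
            raise ValueError(
                f"(m=2, s={s}) outside the outcome space ({r1 + 1}..{n1 + n2_actual})"
            )
        lo = max(r1 + 1, s - n2_actual)
        hi = min(s, n1)
        if lo > hi:
            return 0.0
        x1 = np.arange(lo, hi + 1)
        return float(
            np.sum(binom.pmf(x1, n1, pi) * binom.pmf(s - x1, n2_actual, pi))
        )
    raise ValueError(f"stage m must be 1 or 2, got {m}")


def outcome_distribution(
    n1: int, r1: int, n2_actual: int, pi: float
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """All outcomes and their probabilities in one pass (vectorised convolution)."""
    _check_design_quantities(n1, r1, n2_actual)
    space = outcome_space(n1, r1, n2_actual)
    b1 = _binom_pmf_vec(n1, pi)
    b2 = _binom_pmf_vec(n2_actual, pi)
    stage1 = b1[: r1 + 1]
    cont = np.convolve(b1[r1 + 1:], b2)  # mass on s = r1+1 .. n1+n2'
    probs = np.concatenate([stage1, cont])
    return space, probs


def joint_path_pmf(
    n1: int, r1: int, n2_actual: int, pi: float
) -> dict[tuple[int, int | None], float]:
    """Exhaustive path-level table: {(x1, None): p} for stops, {(x1, x2): p}
    for continuations.  Marginalising x1 + x2 = s reproduces the (M, S) pmf."""
    _check_design_quantities(n1, r1, n2_actual)
    b1 = _binom_pmf_vec(n1, pi)
    b2 = _binom_pmf_vec(n2_actual, pi)
    table: dict[tuple[int, int | None], float] = {}
    for x1 in range(r1 + 1):
        table[(x1, None)] = float(b1[x1])
    for x1 in range(r1 + 1, n1 + 1):
        for x2 in range(n2_actual + 1):
            table[(x1, x2)] = float(b1[x1] * b2[x2])
    return table


# ---------------------------------------------------------------------------
# Operating characteristics and design search
# ---------------------------------------------------------------------------

def design_operating_chars(design: TwoStageDesign, pi: float) -> tuple[float, float, float]:
    """(PET, rejection probability, expected sample size) at response rate pi.

    PET is the probability of early termination Pr(X1 <= r1); the expected
    sample size is n1 + (1 - PET) * n2.
    """
    pet = float(binom.cdf(design.r1, design.n1, pi))
    b1 = _binom_pmf_vec(design.n1, pi)
    cont = np.convolve(b1[design.r1 + 1:], _binom_pmf_vec(design.n2, pi))
    # cont[k] is Pr(M=2, S = r1+1+k); reject when S > rt
    k0 = design.rt - design.r1  # first rejecting index
    reject = float(cont[k0:].sum()) if k0 < len(cont) else 0.0
    expected_n = design.n1 + (1.0 - pet) * design.n2
    return pet, reject, expected_n


def _min_rt_and_power(
    n1: int, r1: int, n2: int, pi0: float, pi1: float, alpha: float
) -> tuple[int, float, float] | None:
    """Smallest final boundary controlling the type-I error, with its attained
    error rates.  Returns (rt, type1, power) or None when even the strictest
    boundary exceeds alpha."""
    b1_0 = _binom_pmf_vec(n1, pi0)[r1 + 1:]
    cont0 = np.convolve(b1_0, _binom_pmf_vec(n2, pi0))
    # tail0[k] = Pr_pi0(M=2, S > r1+k) for k = 0..len(cont0)
    tail0 = np.concatenate([np.cumsum(cont0[::-1])[::-1], [0.0]])
    ok = np.nonzero(tail0 <= alpha)[0]
    if len(ok) == 0:  # pragma: no cover - tail0 ends at 0, always has a hit
        return None
    k = int(ok[0])
    rt = r1 + k
    if rt >= n1 + n2:
        return None
    b1_1 = _binom_pmf_vec(n1, pi1)[r1 + 1:]
    cont1 = np.convolve(b1_1, _binom_pmf_vec(n2, pi1))
    power = float(cont1[k:].sum())
    return rt, float(tail0[k]), power


def _search_designs(spec: DesignSpec, n_max: int, criterion: str) -> TwoStageDesign:
    pi0, pi1, alpha, beta = spec.pi0, spec.pi1, spec.alpha, spec.beta
    best: TwoStageDesign | None = None
    best_key: tuple[float, ...] | None = None
    for n1 in range(1, n_max):
        if criterion == "optimal" and best_key is not None and n1 >= best_key[0]:
            break  # expected N is at least n1
        if criterion == "minimax" and best_key is not None and n1 + 1 > best_key[0]:
            break  # nt is at least n1 + 1
        cdf0 = binom.cdf(np.arange(n1), n1, pi0)
        cdf1 = binom.cdf(np.arange(n1), n1, pi1)
        for r1 in range(n1):
            pet1 = float(cdf1[r1])
            if pet1 > beta:
                break  # stopping too often under pi1; larger r1 only worse
            pet0 = float(cdf0[r1])
            for n2 in range(1, n_max - n1 + 1):
                en = n1 + (1.0 - pet0) * n2
                nt = n1 + n2
                if criterion == "optimal" and best_key is not None and en >= best_key[0]:
                    break  # expected N increases with n2
                if criterion == "minimax" and best_key is not None and nt > best_key[0]:
                    break
                found = _min_rt_and_power(n1, r1, n2, pi0, pi1, alpha)
                if found is None:
                    continue
                rt, _type1, power = found
                if power < 1.0 - beta:
                    continue
                key = (en, nt, n1) if criterion == "optimal" else (nt, en, n1)
                if best_key is None or key < best_key:
                    best = TwoStageDesign(n1=n1, n2=n2, r1=r1, rt=rt)
                    best_key = key
    if best is None:
        raise NoFeasibleDesignError(
            f"no feasible two-stage design with nt <= {n_max} for {spec}"
        )
    return best


def find_optimal_design(spec: DesignSpec, n_max: int = 150) -> TwoStageDesign:
    """Simon's 'optimal' design: minimal expected sample size under pi0 among
    designs meeting the alpha and power constraints."""
    return _search_designs(spec, n_max, "optimal")


def find_minimax_design(spec: DesignSpec, n_max: int = 150) -> TwoStageDesign:
    """Simon's 'minimax' design: minimal total sample size nt, ties broken by
    minimal expected sample size under pi0."""
    return _search_designs(spec, n_max, "minimax")
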