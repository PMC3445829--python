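"""Exact operating characteristics of every inference method.

Because the outcome space of a two-stage binomial trial is finite, the
sampling distribution of any estimator, p-value or confidence interval is an
exact finite mixture: evaluate the method on every outcome and weight by the
outcome probability.  No simulation is involved; bias, RMSE, rejection and
coverage probabilities are exact up to root-finding tolerances.

Methods that depend on the data only through (M, S) are enumerated on the
(M, S) space; the conditional-power methods for attained sample sizes depend
on (x1, x2) separately and are enumerated on the path space.  Conditional
operating characteristics renormalize the weights over continuations
(M = 2).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import estimators as est
from . import intervals as ci_mod
from . import pvalues as pv
from .design import TrialOutcome, TwoStageDesign, outcome_distribution

__all__ = [
    "ESTIMATOR_IDS",
    "TEST_IDS",
    "CI_IDS",
    "OperatingPoint",
    "estimator_bias_rmse",
    "rejection_probability",
    "coverage_probability",
    "scenario_table",
]

ESTIMATOR_IDS = ("mle", "whitehead", "guo", "umvue", "conditional_mle", "umvcue", "median")
TEST_IDS = ("naive", "mle_order", "stagewise", "conditional", "koyama_chen")
CI_IDS = (
    "naive_exact",
    "stagewise",
    "midp",
    "conditional_exact",
    "conditional_score",
    "conditional_midp",
    "koyama_chen",
)

# methods that need (x1, x2) rather than (m, s) when the attained n2 differs
_PATH_ESTIMATORS = frozenset({"median"})
_PATH_TESTS = frozenset({"koyama_chen"})
_PATH_CIS = frozenset({"koyama_chen"})


@dataclass(frozen=True)
class OperatingPoint:
    pi: float
    delta_n2: int
    conditional: bool
    method: str
    metric: str
    value: float


def _outcomes(design: TwoStageDesign, n2p: int) -> list[TrialOutcome]:
    """(M, S)-level outcomes; stage-2 entries carry a representative x1."""
    n1, r1 = design.n1, design.r1
    out = [TrialOutcome(m=1, x1=s) for s in range(r1 + 1)]
    for s in range(r1 + 1, n1 + n2p + 1):
        x1 = min(max(r1 + 1, s - n2p), n1)
        out.append(TrialOutcome(m=2, x1=x1, x2=s - x1, n2_actual=n2p))
    return out


def _paths(design: TwoStageDesign, n2p: int) -> list[TrialOutcome]:
    n1, r1 = design.n1, design.r1
    out = [TrialOutcome(m=1, x1=s) for s in range(r1 + 1)]
    out.extend(
        TrialOutcome(m=2, x1=x1, x2=x2, n2_actual=n2p)
        for x1 in range(r1 + 1, n1 + 1)
        for x2 in range(n2p + 1)
    )
    return out


def _path_weights(design: TwoStageDesign, n2p: int, pi: float) -> np.ndarray:
    n1, r1 = design.n1, design.r1
    b1 = binom.pmf(np.arange(n1 + 1), n1, pi)
    b2 = binom.pmf(np.arange(n2p + 1), n2p, pi)
    stop = b1[: r1 + 1]
    cont = np.outer(b1[r1 + 1:], b2).ravel()
    return np.concatenate([stop, cont])


def _stage_mask(outcomes: list[TrialOutcome]) -> np.ndarray:
    return np.array([o.m == 2 for o in outcomes])


_cache: dict[tuple, np.ndarray] = {}


def _estimates_vector(
    design: TwoStageDesign, n2p: int, estimator_id: str
) -> tuple[list[TrialOutcome], np.ndarray, bool]:
    """Estimator evaluated on each outcome (or path), cached per design."""
    path_level = estimator_id in _PATH_ESTIMATORS and n2p != design.n2
    key = ("est", design, n2p, estimator_id, path_level)
    outcomes = _paths(design, n2p) if path_level else _outcomes(design, n2p)
    if key not in _cache:
        n1, r1 = design.n1, design.r1
        fns = {
            "mle": lambda o: est.mle(o, n1),
            "whitehead": lambda o: est.whitehead_estimator(o, n1, r1, n2p),
            "guo": lambda o: est.guo_estimator(o, n1, r1, n2p),
            "umvue": lambda o: est.umvue(o, n1, r1, n2p),
            "conditional_mle": lambda o: est.conditional_mle(o, n1, r1, n2p),
            "umvcue": lambda o: est.umvcue(o, n1, r1, n2p),
            "median": lambda o: est.median_estimator(o, design, n2p),
        }
        try:
            fn = fns[estimator_id]
        except KeyError:
            raise ValueError(f"unknown estimator {estimator_id!r}") from None
        _cache[key] = np.array([fn(o) for o in outcomes])
    return outcomes, _cache[key], path_level


def estimator_bias_rmse(
    design: TwoStageDesign,
    delta_n2: int,
    pi: float,
    estimator_id: str,
    conditional: bool = False,
) -> tuple[float, float]:
    """Exact bias and RMSE of one estimator at true response rate pi."""
    n2p = design.n2 + delta_n2
    outcomes, values, path_level = _estimates_vector(design, n2p, estimator_id)
    w = (
        _path_weights(design, n2p, pi)
        if path_level
        else outcome_distribution(design.n1, design.r1, n2p, pi)[1]
    )
    if conditional:
        mask = _stage_mask(outcomes)
        w = np.where(mask, w, 0.0)
        total = w.sum()
        if total == 0.0:
            return float("nan"), float("nan")
        w = w / total
    err = values - pi
    bias = float(w @ err)
    rmse = float(np.sqrt(w @ err**2))
    return bias, rmse


def _pvalues_vector(
    design: TwoStageDesign, n2p: int, test_id: str, pi0: float
) -> tuple[list[TrialOutcome], np.ndarray, bool]:
    path_level = test_id in _PATH_TESTS and n2p != design.n2
    key = ("pv", design, n2p, test_id, pi0, path_level)
    outcomes = _paths(design, n2p) if path_level else _outcomes(design, n2p)
    if key not in _cache:
        n1, r1 = design.n1, design.r1

        def one(o: TrialOutcome) -> float:
            if test_id == "naive":
                return pv.naive_pvalue(o, n1, n2p, pi0)
            if test_id == "mle_order":
                return pv.mle_order_pvalue(o, n1, r1, n2p, pi0)
            if test_id == "stagewise":
                return pv.stagewise_pvalue(o, n1, r1, n2p, pi0)
            if test_id == "conditional":
                return pv.conditional_pvalue(o, n1, r1, n2p, pi0)
            if test_id == "koyama_chen":
                if o.m == 1:
                    return pv.stagewise_pvalue(o, n1, r1, n2p, pi0)
                return pv.koyama_chen_pvalue(o.x1, o.x2, design, n2p, pi0)
            raise ValueError(f"unknown test {test_id!r}")

        _cache[key] = np.array([one(o) for o in outcomes])
    return outcomes, _cache[key], path_level


def rejection_probability(
    design: TwoStageDesign,
    delta_n2: int,
    pi: float,
    test_id: str,
    pi0: float,
    alpha: float = 0.05,
    conditional: bool = False,
) -> float:
    """Exact probability that the test rejects (p-value <= alpha) at rate pi."""
    n2p = design.n2 + delta_n2
    outcomes, pvals, path_level = _pvalues_vector(design, n2p, test_id, pi0)
    w = (
        _path_weights(design, n2p, pi)
        if path_level
        else outcome_distribution(design.n1, design.r1, n2p, pi)[1]
    )
    reject = pvals <= alpha
    if conditional:
        mask = _stage_mask(outcomes)
        denom = w[mask].sum()
        if denom == 0.0:
            return float("nan")
        return float(w[mask & reject].sum() / denom)
    return float(w[reject].sum())


def _ci_vector(
    design: TwoStageDesign, n2p: int, ci_id: str, alpha: float
) -> tuple[list[TrialOutcome], np.ndarray, bool]:
    path_level = ci_id in _PATH_CIS and n2p != design.n2
    key = ("ci", design, n2p, ci_id, alpha, path_level)
    outcomes = _paths(design, n2p) if path_level else _outcomes(design, n2p)
    if key not in _cache:
        n1, r1 = design.n1, design.r1

        def one(o: TrialOutcome) -> tuple[float, float]:
            if ci_id == "naive_exact":
                n_total = n1 if o.m == 1 else n1 + n2p
                c = ci_mod.naive_exact_ci(o.s, n_total, alpha)
            elif ci_id == "stagewise":
                c = ci_mod.exact_stagewise_ci(o, n1, r1, n2p, alpha)
            elif ci_id == "midp":
                c = ci_mod.midp_stagewise_ci(o, n1, r1, n2p, alpha)
            elif ci_id == "conditional_exact":
                c = ci_mod.conditional_exact_ci(o, n1, r1, n2p, alpha)
            elif ci_id == "conditional_score":
                c = ci_mod.conditional_score_cc_ci(o, n1, r1, n2p, alpha)
            elif ci_id == "conditional_midp":
                c = ci_mod.conditional_midp_ci(o, n1, r1, n2p, alpha)
            elif ci_id == "koyama_chen":
                if o.m == 1:
                    c = ci_mod.exact_stagewise_ci(o, n1, r1, n2p, alpha)
                else:
                    c = ci_mod.koyama_chen_ci(o.x1, o.x2, design, n2p, alpha)
            else:
                raise ValueError(f"unknown confidence interval {ci_id!r}")
            return c.lower, c.upper

        _cache[key] = np.array([one(o) for o in outcomes])
    return outcomes, _cache[key], path_level


def coverage_probability(
    design: TwoStageDesign,
    delta_n2: int,
    pi: float,
    ci_id: str,
    alpha: float = 0.05,
    conditional: bool = False,
) -> float:
    """Exact probability that the (1-2*alpha) interval contains pi."""
    n2p = design.n2 + delta_n2
    outcomes, bounds, path_level = _ci_vector(design, n2p, ci_id, alpha)
    w = (
        _path_weights(design, n2p, pi)
        if path_level
        else outcome_distribution(design.n1, design.r1, n2p, pi)[1]
    )
    covered = (bounds[:, 0] <= pi) & (pi <= bounds[:, 1])
    if conditional:
        mask = _stage_mask(outcomes)
        denom = w[mask].sum()
        if denom == 0.0:
            return float("nan")
        return float(w[mask & covered].sum() / denom)
    return float(w[covered].sum())


def scenario_table(
    designs: TwoStageDesign | list[TwoStageDesign],
    pi0: float,
    pi_grid: list[float] | np.ndarray,
    delta_n2_list: list[int] = (0,),
    estimators: tuple[str, ...] = ESTIMATOR_IDS,
    tests: tuple[str, ...] = TEST_IDS,
    cis: tuple[str, ...] = CI_IDS,
    alpha: float = 0.05,
    conditional: bool = False,
) -> pd.DataFrame:
    """Cross-product driver over designs, stage-2 size changes and true rates.

    Returns a long-format table with columns design, delta_n2, pi, method,
    metric, value — one row per operating characteristic per cell.
    """
    if isinstance(designs, TwoStageDesign):
        designs = [designs]
    rows: list[dict] = []
    for design, dn2, pi in product(designs, delta_n2_list, pi_grid):
        label = f"{design.n1},{design.n2},{design.r1},{design.rt}"
        pi = float(pi)
        for eid in estimators:
            bias, rmse = estimator_bias_rmse(design, dn2, pi, eid, conditional)
            rows.append(dict(design=label, delta_n2=dn2, pi=pi, method=eid, metric="bias", value=bias))
            rows.append(dict(design=label, delta_n2=dn2, pi=pi, method=eid, metric="rmse", value=rmse))
        for tid in tests:
            rej = rejection_probability(design, dn2, pi, tid, pi0, alpha, conditional)
            rows.append(dict(design=label, delta_n2=dn2, pi=pi, method=tid, metric="rejection", value=rej))
        for cid in cis:
            cov = coverage_probability(design, dn2, pi, cid, alpha, conditional)
            rows.append(dict(design=label, delta_n2=dn2, pi=pi, method=cid, metric="coverage", value=cov))
    df = pd.DataFrame(rows)
    return df.sort_values(["design", "delta_n2", "pi", "metric", "method"]).reset_index(drop=True)
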