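"""Full inference report for one observed trial, with JSON round-tripping."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .adaptation import AdjustedRule, adjusted_critical_value
from .design import TrialOutcome, TwoStageDesign, design_operating_chars
from .estimators import EstimateSet, estimate_all
from .intervals import ConfidenceInterval, intervals_all
from .pvalues import PValueSet, pvalues_all

__all__ = ["InferenceReport", "run_analyze", "write_table"]

logger = logging.getLogger("simon2stage")


@dataclass(frozen=True)
class InferenceReport:
    design: TwoStageDesign
    pi0: float
    alpha: float
    outcome: TrialOutcome
    n2_actual: int
    estimates: EstimateSet
    pvalues: PValueSet
    intervals: list[ConfidenceInterval]
    adjusted_rule: AdjustedRule | None
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "design": {
                "n1": self.design.n1,
                "n2": self.design.n2,
                "r1": self.design.r1,
                "rt": self.design.rt,
            },
            "pi0": self.pi0,
            "alpha": self.alpha,
            "outcome": {
                "m": self.outcome.m,
                "x1": self.outcome.x1,
                "x2": self.outcome.x2,
                "s": self.outcome.s,
                "n2_actual": self.n2_actual,
            },
            "estimates": self.estimates.as_dict(),
            "pvalues": self.pvalues.as_dict(),
            "intervals": {
                ci.method: {"lower": ci.lower, "upper": ci.upper, "level": ci.level}
                for ci in self.intervals
            },
            "provenance": self.provenance,
        }
        if self.adjusted_rule is not None:
            d["adjusted_rule"] = {
                "x1": self.adjusted_rule.x1,
                "n2_actual": self.adjusted_rule.n2_actual,
                "r2_adjusted": self.adjusted_rule.r2_adjusted,
                "conditional_alpha": self.adjusted_rule.conditional_alpha,
                "original_r2": self.design.rt - self.adjusted_rule.x1 + 1,
            }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_analyze(config: dict) -> InferenceReport:
    """Compute every estimate, p-value and interval for one observed trial.

    ``config`` keys: n1, n2, r1, rt, x1, pi0 and optionally x2, n2_actual,
    alpha.  The outcome is validated against the design's stopping rule
    before anything is computed.
    """
    design = TwoStageDesign(
        n1=int(config["n1"]), n2=int(config["n2"]),
        r1=int(config["r1"]), rt=int(config["rt"]),
    )
    pi0 = float(config["pi0"])
    alpha = float(config.get("alpha", 0.05))
    x1 = int(config["x1"])
    x2 = config.get("x2")
    if x2 is None:
        outcome = TrialOutcome(m=1, x1=x1)
        n2_actual = int(config.get("n2_actual") or design.n2)
        logger.warning(
            "trial stopped at stage 1: median estimator and conditional "
            "intervals use first-stage conventions"
        )
    else:
        n2_actual = int(config.get("n2_actual") or design.n2)
        outcome = TrialOutcome(m=2, x1=x1, x2=int(x2), n2_actual=n2_actual)
    outcome.validate_against(design.n1, design.r1)

    estimates = estimate_all(outcome, design, n2_actual)
    pvalues = pvalues_all(outcome, design, pi0, n2_actual)
    intervals = intervals_all(outcome, design, alpha, n2_actual)
    adjusted = None
    if outcome.m == 2 and n2_actual != design.n2:
        adjusted = adjusted_critical_value(x1, design, n2_actual, pi0)
    pet0, reject0, en0 = design_operating_chars(design, pi0)
    provenance = {
        "version": __version__,
        "config_hash": _config_hash(config),
        "attained_alpha": reject0,
        "pet_pi0": pet0,
        "expected_n_pi0": en0,
    }
    return InferenceReport(
        design=design,
        pi0=pi0,
        alpha=alpha,
        outcome=outcome,
        n2_actual=n2_actual,
        estimates=estimates,
        pvalues=pvalues,
        intervals=intervals,
        adjusted_rule=adjusted,
        provenance=provenance,
    )


def write_table(rows: pd.DataFrame, path: str, fmt: str = "csv") -> None:
    """Write an operating-characteristics table deterministically.

    CSV is RFC-4180; "jsonl" writes one JSON object per row.  Row order is
    fixed by (design, delta_n2, pi, metric, method) so identical configs
    produce byte-identical files.
    """
    order = [c for c in ("design", "delta_n2", "pi", "metric", "method") if c in rows.columns]
    if order:
        rows = rows.sort_values(order).reset_index(drop=True)
    if fmt == "csv":
        rows.to_csv(path, index=False, lineterminator="\r\n")
    elif fmt == "jsonl":
        with open(path, "w") as fh:
            for rec in rows.to_dict(orient="records"):
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
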