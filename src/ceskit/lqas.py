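"""Lot quality assurance sampling (LQAS) decision rules.

A lot (here, a supervisory area) of sample size ``n`` is classified as
reaching a coverage threshold when at least ``d`` of the ``n`` sampled
individuals report treatment.  The operating characteristic is binomial:

    P(classify at/above | true coverage p) = P(X >= d),  X ~ Bin(n, p)

with the two error rates

    alpha = P(classify below | p = p_upper) = 1 - P(X >= d | p_upper)
    beta  = P(classify at/above | p = p_lower) = P(X >= d | p_lower)

``find_decision_rule`` searches d for rules keeping both below given
caps (10% is the conventional target).  ``classify_strata`` applies a
rule per supervisory area of a stratified LQAS sample, excluding
"not sure" responses first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .samplers import RESPONSE_NOT_SURE, RESPONSE_YES, SurveySample

__all__ = ["LQASRule", "oc_probability", "error_rates", "find_decision_rule",
           "decision_table", "classify_strata", "DEFAULT_THRESHOLD_GAP"]

# smallest p_upper - p_lower gap admitting an n=19 rule with alpha, beta < 10%
# at all of the conventional 65/75/80% programme thresholds
DEFAULT_THRESHOLD_GAP = 0.30


@dataclass(frozen=True)
class LQASRule:
    """A decision rule (n, d) for thresholds (p_upper, p_lower) with its
    exact binomial error rates."""

    n: int
    d: int
    p_upper: float
    p_lower: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not 0 <= self.d <= self.n:
            raise ValueError("need 0 <= d <= n")
        if not 0.0 < self.p_lower < self.p_upper < 1.0:
            raise ValueError("need 0 < p_lower < p_upper < 1")


def oc_probability(n: int, d: int, p: float) -> float:
    """P(X >= d) for X ~ Binomial(n, p), via the stable survival function."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if d < 0:
        raise ValueError("d must be >= 0")
    if d == 0:
        return 1.0
    if d > n:
        return 0.0
    return float(binom.sf(d - 1, n, p))


def error_rates(n: int, d: int, p_upper: float, p_lower: float) -> tuple[float, float]:
    """(alpha, beta) of the rule: misclassify-below risk at p_upper and
    misclassify-above risk at p_lower."""
    alpha = 1.0 - oc_probability(n, d, p_upper)
    beta = oc_probability(n, d, p_lower)
    return alpha, beta


def decision_table(n: int, p_upper: float, p_lower: float) -> pd.DataFrame:
    """Full (d, alpha, beta) table for d = 0..n."""
    rows = []
    for d in range(n + 1):
        alpha, beta = error_rates(n, d, p_upper, p_lower)
        rows.append({"d": d, "alpha": alpha, "beta": beta})
    return pd.DataFrame(rows)


def find_decision_rule(
    n: int,
    p_upper: float,
    p_lower: float | None = None,
    max_alpha: float = 0.10,
    max_beta: float = 0.10,
) -> LQASRule | None:
    """Smallest-alpha admissible rule (ties broken toward smaller d), or
    None when no decision value satisfies both error caps.

    ``p_lower`` defaults to ``p_upper - DEFAULT_THRESHOLD_GAP``; 0.30 is
    the smallest gap for which n = 19 admits a rule with both errors
    below 10% at the conventional programme thresholds (0.65/0.75/0.80),
    per exhaustive search over d.
    """
    if p_lower is None:
        p_lower = p_upper - DEFAULT_THRESHOLD_GAP
    if not 0.0 < p_lower < p_upper < 1.0:
        raise ValueError("need 0 < p_lower < p_upper < 1")
    best = None
    for d in range(n + 1):
        alpha, beta = error_rates(n, d, p_upper, p_lower)
        if alpha <= max_alpha and beta <= max_beta:
            if best is None or alpha < best[0]:
                best = (alpha, beta, d)
    if best is None:
        return None
    alpha, beta, d = best
    return LQASRule(n=n, d=d, p_upper=p_upper, p_lower=p_lower, alpha=alpha, beta=beta)


def classify_strata(sample: SurveySample, rule: LQASRule, drug: str) -> pd.DataFrame:
    """Per-SA classification of a stratified LQAS sample.

    "Not sure" responses are removed before counting; an SA whose valid
    sample size differs from the rule's n is still classified but flagged
    ``undersized`` rather than silently padded.
    """
    if sample.design != "slqas":
        raise ValueError("classification applies to stratified LQAS samples")
    resp = sample.responses[drug]
    valid = resp != RESPONSE_NOT_SURE
    rows = []
    for sa in np.unique(sample.stratum):
        m = (sample.stratum == sa) & valid
        n_valid = int(m.sum())
        n_treated = int((resp[m] == RESPONSE_YES).sum())
        rows.append(
            {
                "sa_id": int(sa),
                "n_valid": n_valid,
                "n_treated": n_treated,
                "classification": "at_or_above" if n_treated >= rule.d else "below",
                "undersized": n_valid != rule.n,
            }
        )
    return pd.DataFrame(rows)
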