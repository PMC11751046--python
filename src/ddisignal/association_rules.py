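"""Association-rule metrics for drug-pair -> AE rules and detection thresholds.

Metrics for the rule ``drug1 & drug2 -> AE`` over an analysis set of T
reports:

* support      = n(drug1 & drug2 & AE) / T
* confidence   = support / support(drug1 & drug2)
* lift         = confidence / support(AE)
* conviction   = (1 - support(AE)) / (1 - confidence)

Detection keeps rules with lift > 1 (strict), conviction > 1 (strict) and
n111 >= 3 (inclusive), then removes redundant pair rules that do not improve
on either constituent single-drug rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

from .contingency import ContingencyTable4x2, TableBuilder, TripleCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "RuleMetrics",
    "RuleThresholds",
    "rule_metrics",
    "conviction_from_confidence_lift",
    "apply_thresholds",
    "single_drug_confidences",
    "remove_redundant",
]


@dataclass(frozen=True)
class RuleMetrics:
    support: float
    confidence: float
    lift: float
    conviction: float
    n111: int
    support_ae: float
    support_pair: float


@dataclass(frozen=True)
class RuleThresholds:
    """lift and conviction are exclusive bounds; min_n111 is inclusive."""

    min_lift: float = 1.0
    min_conviction: float = 1.0
    min_n111: int = 3

    def __post_init__(self):
        if self.min_lift <= 0 or self.min_conviction <= 0 or self.min_n111 <= 0:
            raise ValueError("thresholds must be positive")


def _conviction(confidence: float, support_ae: float) -> float:
    if confidence < 1.0:
        return (1.0 - support_ae) / (1.0 - confidence)
    # certain rule: infinite conviction unless the AE is itself certain
    return math.inf if support_ae < 1.0 else 1.0


def conviction_from_confidence_lift(confidence: float, lift: float) -> float:
    """Recover conviction from confidence and lift alone.

    Uses support(AE) = confidence / lift, so
    conviction = (1 - confidence/lift) / (1 - confidence).  Handy for
    checking published rule tables that omit the AE marginal.
    """
    if lift <= 0:
        raise ValueError("lift must be positive")
    return _conviction(confidence, confidence / lift)


def rule_metrics(table: ContingencyTable4x2) -> RuleMetrics:
    """Compute the four rule metrics from a triple's contingency table.

    T is the number of reports in the analysis set (``n+++``).  Degenerate
    denominators yield NaN (support_pair = 0) or the documented sentinels,
    never an exception; an empty analysis set is a domain error.
    """
    total = table.nppp
    if total == 0:
        raise ValueError("empty analysis set (n+++ = 0)")
    support = table.n111 / total
    support_pair = table.n11p / total
    support_ae = table.npp1 / total
    confidence = support / support_pair if support_pair > 0 else math.nan
    if support_ae > 0 and support_pair > 0:
        lift = confidence / support_ae
    else:
        lift = math.nan
    conviction = _conviction(confidence, support_ae) if support_pair > 0 else math.nan
    return RuleMetrics(
        support=support,
        confidence=confidence,
        lift=lift,
        conviction=conviction,
        n111=table.n111,
        support_ae=support_ae,
        support_pair=support_pair,
    )


def apply_thresholds(
    metrics: Sequence[Tuple[TripleCandidate, RuleMetrics]],
    thresholds: RuleThresholds = RuleThresholds(),
) -> List[Tuple[TripleCandidate, RuleMetrics]]:
    """Keep rules with lift > min_lift, conviction > min_conviction, n111 >= min_n111.

    NaN metrics (degenerate marginals) never pass; they are logged and
    skipped.
    """
    kept = []
    for cand, m in metrics:
        if math.isnan(m.lift) or math.isnan(m.conviction):
            logger.info("skipping rule with degenerate marginals: %s", cand)
            continue
        if (
            m.lift > thresholds.min_lift
            and m.conviction > thresholds.min_conviction
            and m.n111 >= thresholds.min_n111
        ):
            kept.append((cand, m))
    return kept


def single_drug_confidences(
    builder: TableBuilder,
    pairs: Sequence[Tuple[str, str]],
) -> Dict[Tuple[str, str], float]:
    """Confidence of each single-drug rule drug -> AE over the same report set."""
    out: Dict[Tuple[str, str], float] = {}
    for drug, ae in pairs:
        n_both, n_drug = builder.drug_ae_count(drug, ae)
        out[(drug, ae)] = n_both / n_drug if n_drug > 0 else 0.0
    return out


def remove_redundant(
    rules: Sequence[Tuple[TripleCandidate, RuleMetrics]],
    single_conf: Mapping[Tuple[str, str], float],
) -> Tuple[List[Tuple[TripleCandidate, RuleMetrics]], List[Tuple[TripleCandidate, str]]]:
    """Drop pair rules that do not improve on either single-drug rule.

    A pair rule is redundant when confidence(drug -> AE) for either
    constituent drug alone is >= the pair rule's confidence.  Duplicate
    orderings cannot occur because candidates are canonical.  Returns
    (kept, removals) where each removal carries a human-readable reason.
    """
    kept: List[Tuple[TripleCandidate, RuleMetrics]] = []
    removals: List[Tuple[TripleCandidate, str]] = []
    seen = set()
    for cand, m in rules:
        key = (cand.drug1, cand.drug2, cand.ae)
        if key in seen:
            removals.append((cand, "duplicate candidate"))
            continue
        seen.add(key)
        c1 = single_conf.get((cand.drug1, cand.ae), 0.0)
        c2 = single_conf.get((cand.drug2, cand.ae), 0.0)
        if c1 >= m.confidence:
            removals.append((cand, f"dominated by {cand.drug1}"))
        elif c2 >= m.confidence:
            removals.append((cand, f"dominated by {cand.drug2}"))
        else:
            kept.append((cand, m))
    for cand, reason in removals:
        logger.info("redundant rule removed (%s): %s", reason, cand)
    return kept, removals
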