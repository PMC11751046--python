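"""End-to-end signal detection: candidates -> both detectors -> intersection.

A triple is a signal only when it passes the association-rule thresholds
(after redundancy removal) AND its omega shrinkage lower bound is positive.
Detection runs overall and within sex / age strata; reports with unknown sex
or missing age are kept overall and excluded only from the affected strata.
No multiple-testing adjustment is applied; the omega lower bound is the
conservatism mechanism.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .association_rules import (
    RuleMetrics,
    RuleThresholds,
    apply_thresholds,
    remove_redundant,
    rule_metrics,
    single_drug_confidences,
)
from .contingency import TableBuilder, TripleCandidate, enumerate_candidates
from .omega_shrinkage import OmegaResult, expected_count_e111, omega_result
from .report_model import Report, Sex

logger = logging.getLogger(__name__)

__all__ = [
    "StratumSpec",
    "Signal",
    "DetectionResult",
    "PAPER_STRATA",
    "OVERALL",
    "detect_signals",
    "stratified_signals",
    "descriptive_summary",
    "DescriptiveSummary",
    "signals_to_frame",
    "format_signal_report",
]

AGE_CUTOFF = 60.0  # age == 60 routes to the "60 and above" stratum


@dataclass(frozen=True)
class StratumSpec:
    """A subgroup filter: optional sex and/or age band ('<60' or '>=60')."""

    label: str
    sex: Optional[Sex] = None
    age_band: Optional[str] = None

    def __post_init__(self):
        if self.age_band not in (None, "<60", ">=60"):
            raise ValueError(f"age_band must be '<60' or '>=60', got {self.age_band!r}")

    def subset(self, reports: Sequence[Report]) -> List[Report]:
        out = []
        for r in reports:
            if self.sex is not None and r.sex is not self.sex:
                continue  # unknown sex never enters a sex stratum
            if self.age_band is not None:
                if r.age is None:
                    continue
                if self.age_band == "<60" and not r.age < AGE_CUTOFF:
                    continue
                if self.age_band == ">=60" and not r.age >= AGE_CUTOFF:
                    continue
            out.append(r)
        return out


OVERALL = StratumSpec("overall")
MALE = StratumSpec("male", sex=Sex.MALE)
FEMALE = StratumSpec("female", sex=Sex.FEMALE)
AGE_GE60 = StratumSpec("age>=60", age_band=">=60")
AGE_LT60 = StratumSpec("age<60", age_band="<60")

PAPER_STRATA = (OVERALL, MALE, FEMALE, AGE_GE60, AGE_LT60)


@dataclass(frozen=True)
class Signal:
    """A triple passing both detectors in a stratum, carrying both metric sets."""

    drug1: str
    drug2: str
    ae: str
    rule: RuleMetrics
    omega: OmegaResult
    stratum: str

    def __post_init__(self):
        if self.rule.n111 != self.omega.n111:
            raise ValueError("rule and omega built from different tables (n111 mismatch)")


@dataclass
class DetectionResult:
    """Intersection signals plus the full per-detector side outputs."""

    stratum: str
    n_reports: int
    candidates: List[TripleCandidate] = field(default_factory=list)
    rule_metrics: List[Tuple[TripleCandidate, RuleMetrics]] = field(default_factory=list)
    rule_signals: List[Tuple[TripleCandidate, RuleMetrics]] = field(default_factory=list)
    rule_removals: List[Tuple[TripleCandidate, str]] = field(default_factory=list)
    omega_results: List[Tuple[TripleCandidate, OmegaResult]] = field(default_factory=list)
    omega_signals: List[Tuple[TripleCandidate, OmegaResult]] = field(default_factory=list)
    signals: List[Signal] = field(default_factory=list)


def detect_signals(
    reports: Sequence[Report],
    thresholds: RuleThresholds = RuleThresholds(),
    omega_model: str = "noren_excess",
    stratum: StratumSpec = OVERALL,
) -> DetectionResult:
    """Run both detectors on identical tables for one stratum.

    Candidates are enumerated within the stratum subset (min_n111 from the
    rule thresholds), both detectors evaluate the same contingency tables,
    and the intersection is returned sorted by omega025 descending.
    """
    subset = stratum.subset(reports)
    result = DetectionResult(stratum=stratum.label, n_reports=len(subset))
    if not subset:
        logger.warning("stratum %r is empty; no signals", stratum.label)
        return result

    candidates = enumerate_candidates(subset, min_n111=thresholds.min_n111)
    result.candidates = candidates
    if not candidates:
        return result

    builder = TableBuilder(subset)
    tables = {cand: builder.build(cand) for cand in candidates}

    metrics = [(cand, rule_metrics(tables[cand])) for cand in candidates]
    result.rule_metrics = metrics
    passed = apply_thresholds(metrics, thresholds)
    needed = [(c.drug1, c.ae) for c, _ in passed] + [(c.drug2, c.ae) for c, _ in passed]
    kept, removals = remove_redundant(passed, single_drug_confidences(builder, needed))
    result.rule_signals = kept
    result.rule_removals = removals

    omega_all = []
    for cand in candidates:
        table = tables[cand]
        omega_all.append((cand, omega_result(table.n111, expected_count_e111(table, omega_model))))
    omega_all.sort(key=lambda it: (-it[1].omega025, it[0].drug1, it[0].drug2, it[0].ae))
    result.omega_results = omega_all
    result.omega_signals = [(c, o) for c, o in omega_all if o.is_signal]

    rule_by_triple = {(c.drug1, c.drug2, c.ae): m for c, m in kept}
    signals = []
    for cand, omega in omega_all:
        key = (cand.drug1, cand.drug2, cand.ae)
        if omega.is_signal and key in rule_by_triple:
            signals.append(Signal(cand.drug1, cand.drug2, cand.ae,
                                  rule=rule_by_triple[key], omega=omega,
                                  stratum=stratum.label))
    result.signals = signals  # inherits omega025-descending order
    logger.info(
        "stratum %s: %d candidates, %d rule signals, %d omega signals, %d intersection",
        stratum.label, len(candidates), len(kept), len(result.omega_signals), len(signals),
    )
    return result


def stratified_signals(
    reports: Sequence[Report],
    thresholds: RuleThresholds = RuleThresholds(),
    omega_model: str = "noren_excess",
    strata: Sequence[StratumSpec] = PAPER_STRATA,
) -> Dict[str, DetectionResult]:
    """Run detect_signals independently per stratum (candidates recomputed within)."""
    return {
        s.label: detect_signals(reports, thresholds, omega_model, stratum=s)
        for s in strata
    }


# ---------------------------------------------------------------------------
# descriptive summaries

@dataclass
class DescriptiveSummary:
    drug_frequency: pd.DataFrame
    ae_frequency: pd.DataFrame
    pair_ae_frequency: pd.DataFrame
    combination_sizes: pd.DataFrame
    demographics: pd.DataFrame
    n_reports: int
    n_combinations: int


def descriptive_summary(reports: Sequence[Report], top_n: int = 10) -> DescriptiveSummary:
    """Frequency tables over drug-AE combinations, plus demographics.

    A "combination" is one (report drug set, AE) pair: a report with k AEs
    contributes k combinations, each carrying the report's full drug set.
    Percentages are relative to the total combination count.
    """
    n_combinations = 0
    drug_counts: Counter = Counter()
    ae_counts: Counter = Counter()
    pair_ae_counts: Counter = Counter()
    size_counts: Counter = Counter()
    soc_by_ae: dict = {}

    for r in reports:
        soc_by_ae.update(r.soc_map)
        n_drugs = len(r.drugs)
        bucket = "1" if n_drugs == 1 else ("2" if n_drugs == 2 else ">=3")
        sorted_drugs = sorted(r.drugs)
        for ae in r.aes:
            n_combinations += 1
            size_counts[bucket] += 1
            for d in r.drugs:
                drug_counts[d] += 1
            ae_counts[ae] += 1
            for i in range(len(sorted_drugs)):
                for j in range(i + 1, len(sorted_drugs)):
                    pair_ae_counts[(sorted_drugs[i], sorted_drugs[j], ae)] += 1

    def top_frame(counter, cols):
        rows = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))[:top_n]
        return rows

    drug_rows = [
        {"drug": d, "frequency": n, "percentage": round(100.0 * n / n_combinations, 2) if n_combinations else 0.0}
        for d, n in top_frame(drug_counts, None)
    ]
    ae_rows = [
        {"ae": a, "frequency": n,
         "percentage": round(100.0 * n / n_combinations, 2) if n_combinations else 0.0,
         "category": soc_by_ae.get(a, "")}
        for a, n in top_frame(ae_counts, None)
    ]
    pair_rows = [
        {"drug1": k[0], "drug2": k[1], "ae": k[2], "frequency": n}
        for k, n in top_frame(pair_ae_counts, None)
    ]
    size_rows = [
        {"n_drugs": b, "combinations": size_counts.get(b, 0),
         "percentage": round(100.0 * size_counts.get(b, 0) / n_combinations, 2) if n_combinations else 0.0}
        for b in ("1", "2", ">=3")
    ]

    sex_counts = Counter(r.sex.value for r in reports)
    age_known = [r for r in reports if r.age is not None]
    demo_rows = [
        {"group": "male", "reports": sex_counts.get("male", 0)},
        {"group": "female", "reports": sex_counts.get("female", 0)},
        {"group": "sex unknown", "reports": sex_counts.get("unknown", 0)},
        {"group": "age>=60", "reports": sum(1 for r in age_known if r.age >= AGE_CUTOFF)},
        {"group": "age<60", "reports": sum(1 for r in age_known if r.age < AGE_CUTOFF)},
        {"group": "age missing", "reports": len(reports) - len(age_known)},
    ]

    return DescriptiveSummary(
        drug_frequency=pd.DataFrame(drug_rows),
        ae_frequency=pd.DataFrame(ae_rows),
        pair_ae_frequency=pd.DataFrame(pair_rows),
        combination_sizes=pd.DataFrame(size_rows),
        demographics=pd.DataFrame(demo_rows),
        n_reports=len(reports),
        n_combinations=n_combinations,
    )


# ---------------------------------------------------------------------------
# output formatting

def signals_to_frame(signals: Sequence[Signal]) -> pd.DataFrame:
    """Full-precision machine-readable signal table."""
    rows = []
    for s in signals:
        rows.append({
            "stratum": s.stratum, "drug1": s.drug1, "drug2": s.drug2, "ae": s.ae,
            "n111": s.rule.n111, "e111": s.omega.e111,
            "omega": s.omega.omega, "omega025": s.omega.omega025,
            "support": s.rule.support, "confidence": s.rule.confidence,
            "lift": s.rule.lift, "conviction": s.rule.conviction,
        })
    return pd.DataFrame(rows)


def format_signal_report(signals: Sequence[Signal]) -> str:
    """Human-readable table (combination, ADR, n111, omega025, lift, conviction,
    confidence) with 2-decimal rounding."""
    header = ["Combination of drugs", "ADR", "n111", "Omega0.025", "Lift", "Conviction", "Confidence"]
    lines = ["\t".join(header)]
    for s in signals:
        lines.append("\t".join([
            f"{s.drug1} and {s.drug2}", s.ae, str(s.rule.n111),
            f"{s.omega.omega025:.2f}", f"{s.rule.lift:.2f}",
            f"{s.rule.conviction:.2f}" if s.rule.conviction != float("inf") else "inf",
            f"{s.rule.confidence:.2f}",
        ]))
    return "\n".join(lines)
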