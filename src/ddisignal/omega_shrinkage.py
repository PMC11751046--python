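"""Omega shrinkage measure for drug-drug interaction surveillance.

For a triple's 4x2 table the statistic is

    omega     = log2((n111 + 0.5) / (e111 + 0.5))
    omega025  = omega - z / (ln 2 * sqrt(n111)),   z = phi^-1(0.975)

where e111 is the expected number of both-drug target-AE reports under a
no-interaction model.  The +0.5 shrinkage pulls small-count cells toward the
null, and omega025 > 0 (strict) flags a signal.

Two e111 models are available:

* ``noren_excess`` (default): combine the observed AE risks in the
  only-drug1, only-drug2 and neither rows on the excess-risk scale,
  solving 1/(1-g111) = 1/(1-f101) + 1/(1-f011) - 1/(1-f001) and taking
  e111 = n11+ * g111.
* ``independence``: e111 = n11+ * (n++1 / n+++), i.e. the marginal AE rate
  applied to the both-exposed row.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import pandas as pd

from .contingency import ContingencyTable4x2, TableBuilder, TripleCandidate

logger = logging.getLogger(__name__)

__all__ = [
    "Z_975",
    "OMEGA_MODELS",
    "OmegaResult",
    "expected_count_e111",
    "omega_statistic",
    "omega_lower_bound",
    "omega_result",
    "scan_omega",
    "omega_to_frame",
]

#: 97.5% standard-normal quantile, fixed (not recomputed) for reproducibility
Z_975 = 1.959964

OMEGA_MODELS = ("noren_excess", "independence")

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class OmegaResult:
    n111: int
    e111: float
    omega: float
    omega025: float
    z: float = Z_975

    @property
    def is_signal(self) -> bool:
        return self.omega025 > 0.0


def expected_count_e111(table: ContingencyTable4x2, model: str = "noren_excess") -> float:
    """Expected both-drug target-AE count under the chosen no-interaction model.

    ``noren_excess`` falls back to the independence value whenever any
    comparator row margin (n10+, n01+, n00+) is zero; g111 is clamped into
    [0, 1].
    """
    if model not in OMEGA_MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {OMEGA_MODELS}")
    if table.nppp == 0:
        raise ValueError("empty table: all margins zero")

    independence = table.n11p * (table.npp1 / table.nppp)
    if model == "independence":
        return independence

    if table.n10p == 0 or table.n01p == 0 or table.n00p == 0:
        return independence
    f101 = table.n101 / table.n10p
    f011 = table.n011 / table.n01p
    f001 = table.n001 / table.n00p
    if f101 >= 1.0 or f011 >= 1.0:
        g111 = 1.0
    elif f001 >= 1.0:
        # excess equation has no finite solution; degenerate background
        return independence
    else:
        s = 1.0 / (1.0 - f101) + 1.0 / (1.0 - f011) - 1.0 / (1.0 - f001)
        g111 = 1.0 - 1.0 / s if s >= 1.0 else 0.0
    g111 = min(max(g111, 0.0), 1.0)
    return table.n11p * g111


def omega_statistic(n111: int, e111: float) -> float:
    """log2 of the shrunk observed-to-expected ratio."""
    if n111 < 0 or e111 < 0:
        raise ValueError("n111 and e111 must be non-negative")
    return math.log2((n111 + 0.5) / (e111 + 0.5))


def omega_lower_bound(omega: float, n111: int) -> float:
    """2.5% credibility lower bound; undefined (no signal) at n111 = 0."""
    if n111 < 0:
        raise ValueError("n111 must be non-negative")
    if n111 == 0:
        logger.info("omega lower bound undefined at n111=0; reporting -inf (no signal)")
        return -math.inf
    return omega - Z_975 / (_LN2 * math.sqrt(n111))


def omega_result(n111: int, e111: float) -> OmegaResult:
    omega = omega_statistic(n111, e111)
    return OmegaResult(n111=n111, e111=e111, omega=omega,
                       omega025=omega_lower_bound(omega, n111))


def scan_omega(
    reports: Sequence,
    candidates: Sequence[TripleCandidate],
    model: str = "noren_excess",
) -> List[Tuple[TripleCandidate, OmegaResult]]:
    """One OmegaResult per candidate, sorted by omega025 descending.

    Ties break on (drug1, drug2, ae) so output order is deterministic.
    """
    builder = TableBuilder(reports)
    out = []
    for cand in candidates:
        table = builder.build(cand)
        e111 = expected_count_e111(table, model=model)
        out.append((cand, omega_result(table.n111, e111)))
    out.sort(key=lambda item: (-item[1].omega025, item[0].drug1, item[0].drug2, item[0].ae))
    return out


def omega_to_frame(items: Sequence[Tuple[TripleCandidate, OmegaResult]], model: str) -> pd.DataFrame:
    rows = []
    for cand, res in items:
        rows.append({
            "drug1": cand.drug1, "drug2": cand.drug2, "ae": cand.ae,
            "n111": res.n111, "e111": res.e111,
            "omega": res.omega, "omega025": res.omega025,
            "model": model, "signal": res.is_signal,
        })
    return pd.DataFrame(rows)
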