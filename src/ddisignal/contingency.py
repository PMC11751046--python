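"""Candidate (drug1, drug2, AE) triples and their 4x2 contingency tables.

Each report contributes to exactly one exposure row -- {both drugs, only
drug1, only drug2, neither} -- and one AE column -- {target AE present, only
other AEs}.  Counting is at report level: a report carrying the target AE
plus other AEs still counts once, in the target column.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "TripleCandidate",
    "ContingencyTable4x2",
    "TableBuilder",
    "enumerate_candidates",
    "build_table",
    "tables_to_frame",
]


@dataclass(frozen=True, order=True)
class TripleCandidate:
    """An unordered drug pair plus a target AE, with its co-report count.

    ``drug1 < drug2`` lexicographically so each unordered pair has a single
    canonical representation.
    """

    drug1: str
    drug2: str
    ae: str
    n111: int = 0

    def __post_init__(self):
        if self.drug1 >= self.drug2:
            raise ValueError(f"pair not canonical: {self.drug1!r} >= {self.drug2!r}")
        if self.n111 < 0:
            raise ValueError("n111 must be non-negative")

    @classmethod
    def make(cls, drug_a: str, drug_b: str, ae: str, n111: int = 0) -> "TripleCandidate":
        """Build with automatic canonical ordering of the pair."""
        d1, d2 = sorted((drug_a, drug_b))
        return cls(d1, d2, ae, n111)


@dataclass(frozen=True)
class ContingencyTable4x2:
    """The eight cells of the 4x2 exposure-by-AE table for one triple.

    Cell ``n_ijk``: i = drug1 present, j = drug2 present, k = target AE
    present (1) or only other AEs (0).
    """

    n111: int
    n110: int
    n101: int
    n100: int
    n011: int
    n010: int
    n001: int
    n000: int

    def __post_init__(self):
        if any(c < 0 for c in self.cells):
            raise ValueError("cell counts must be non-negative")

    @property
    def cells(self) -> Tuple[int, ...]:
        return (self.n111, self.n110, self.n101, self.n100,
                self.n011, self.n010, self.n001, self.n000)

    # exposure-row margins
    @property
    def n11p(self) -> int:
        return self.n111 + self.n110

    @property
    def n10p(self) -> int:
        return self.n101 + self.n100

    @property
    def n01p(self) -> int:
        return self.n011 + self.n010

    @property
    def n00p(self) -> int:
        return self.n001 + self.n000

    # AE-column margins
    @property
    def npp1(self) -> int:
        return self.n111 + self.n101 + self.n011 + self.n001

    @property
    def npp0(self) -> int:
        return self.n110 + self.n100 + self.n010 + self.n000

    @property
    def nppp(self) -> int:
        return sum(self.cells)


class TableBuilder:
    """Vectorized cell counting over a fixed report set.

    Builds one boolean indicator vector per drug and per AE term once, so
    that each subsequent table is eight boolean reductions instead of a
    Python loop over reports.  Use this when scanning many candidates over
    the same analysis set.
    """

    def __init__(self, reports: Sequence):
        self.n_reports = len(reports)
        self._drug: dict = {}
        self._ae: dict = {}
        for idx, report in enumerate(reports):
            for d in report.drugs:
                self._drug.setdefault(d, []).append(idx)
            for a in report.aes:
                self._ae.setdefault(a, []).append(idx)
        self._drug = {k: self._indicator(v) for k, v in self._drug.items()}
        self._ae = {k: self._indicator(v) for k, v in self._ae.items()}
        self._absent = np.zeros(self.n_reports, dtype=bool)

    def _indicator(self, idxs) -> np.ndarray:
        vec = np.zeros(self.n_reports, dtype=bool)
        vec[idxs] = True
        return vec

    def build(self, triple: TripleCandidate) -> ContingencyTable4x2:
        d1 = self._drug.get(triple.drug1, self._absent)
        d2 = self._drug.get(triple.drug2, self._absent)
        ae = self._ae.get(triple.ae, self._absent)
        both = d1 & d2
        only1 = d1 & ~d2
        only2 = d2 & ~d1
        neither = ~(d1 | d2)
        count = np.count_nonzero
        return ContingencyTable4x2(
            n111=int(count(both & ae)), n110=int(count(both & ~ae)),
            n101=int(count(only1 & ae)), n100=int(count(only1 & ~ae)),
            n011=int(count(only2 & ae)), n010=int(count(only2 & ~ae)),
            n001=int(count(neither & ae)), n000=int(count(neither & ~ae)),
        )

    def drug_ae_count(self, drug: str, ae: str) -> Tuple[int, int]:
        """(reports with drug and AE, reports with drug) -- for single-drug rules."""
        d = self._drug.get(drug, self._absent)
        a = self._ae.get(ae, self._absent)
        return int(np.count_nonzero(d & a)), int(np.count_nonzero(d))


def enumerate_candidates(reports: Sequence, min_n111: int = 3) -> List[TripleCandidate]:
    """Tally all unordered drug pairs x AEs over multi-drug reports.

    Returns candidates with ``n111 >= min_n111`` sorted by
    (n111 descending, drug1, drug2, ae).  Report order does not matter.
    """
    counts: Counter = Counter()
    for report in reports:
        if len(report.drugs) < 2:
            continue
        pairs = itertools.combinations(sorted(report.drugs), 2)
        for (d1, d2), ae in itertools.product(list(pairs), report.aes):
            counts[(d1, d2, ae)] += 1
    out = [
        TripleCandidate(d1, d2, ae, n)
        for (d1, d2, ae), n in counts.items()
        if n >= min_n111
    ]
    out.sort(key=lambda c: (-c.n111, c.drug1, c.drug2, c.ae))
    return out


def build_table(reports: Sequence, triple: TripleCandidate) -> ContingencyTable4x2:
    """One-off table for a single triple (symmetric in the drug pair)."""
    return TableBuilder(reports).build(triple)


def tables_to_frame(items: Iterable[Tuple[TripleCandidate, ContingencyTable4x2]]) -> pd.DataFrame:
    """Audit dump: one row per triple with the eight cells and margins."""
    rows = []
    for cand, t in items:
        rows.append({
            "drug1": cand.drug1, "drug2": cand.drug2, "ae": cand.ae,
            "n111": t.n111, "n110": t.n110, "n101": t.n101, "n100": t.n100,
            "n011": t.n011, "n010": t.n010, "n001": t.n001, "n000": t.n000,
            "n11+": t.n11p, "n10+": t.n10p, "n01+": t.n01p, "n00+": t.n00p,
            "n++1": t.npp1, "n+++": t.nppp,
        })
    return pd.DataFrame(rows)
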