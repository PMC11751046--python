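"""Reading, standardization, and cohort filtering of spontaneous ADR reports.

A spontaneous reporting system (SRS) table has one row per report: an opaque
id, reporting year, patient demographics, free-text disease / drug / adverse
event (AE) lists, and a causality grade.  This module turns such delimited
tables into a canonical in-memory list of :class:`Report` objects, applies
user-supplied term dictionaries (the artifact ships no licensed vocabulary),
and applies the cohort inclusion filters with a deterministic audit log.
"""

from __future__ import annotations

import logging
import re
from collections import OrderedDict
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Sex",
    "Causality",
    "Report",
    "TermDictionary",
    "FilterSpec",
    "FilterLog",
    "SchemaError",
    "StandardizationError",
    "load_reports",
    "standardize_terms",
    "apply_inclusion_filters",
    "write_canonical",
    "read_canonical",
    "DEFAULT_SCHEMA",
    "DEFAULT_LIST_DELIMITER",
]

DEFAULT_LIST_DELIMITER = ";"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Causality(str, Enum):
    """Reporter-assessed drug-event relationship, five levels."""

    CERTAIN = "certain"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    UNLIKELY = "unlikely"
    PENDING = "pending"


#: causality grades retained by the study cohort definition
INCLUDED_CAUSALITY = frozenset({Causality.CERTAIN, Causality.PROBABLE, Causality.POSSIBLE})

_SEX_ALIASES = {
    "m": Sex.MALE,
    "male": Sex.MALE,
    "f": Sex.FEMALE,
    "female": Sex.FEMALE,
    "": Sex.UNKNOWN,
    "u": Sex.UNKNOWN,
    "unknown": Sex.UNKNOWN,
    "na": Sex.UNKNOWN,
}

_CAUSALITY_ALIASES = {
    "certain": Causality.CERTAIN,
    "probable": Causality.PROBABLE,
    "possible": Causality.POSSIBLE,
    "unlikely": Causality.UNLIKELY,
    "pending": Causality.PENDING,
    "pending confirmation": Causality.PENDING,
}


class SchemaError(ValueError):
    """A required column cannot be resolved through the schema map."""


class StandardizationError(ValueError):
    """Unmapped terms encountered under ``unmapped_policy='error'``."""


def normalize_term(term: str) -> str:
    """Lowercase, trim, and collapse internal whitespace (dictionary key form)."""
    return re.sub(r"\s+", " ", term.strip()).lower()


@dataclass(frozen=True)
class Report:
    """One spontaneous ADR report after parsing.

    ``ae_soc`` carries the optional system-organ-class style category per AE
    term as a sorted tuple of ``(term, category)`` pairs so the record stays
    hashable.
    """

    report_id: str
    year: Optional[int]
    age: Optional[float]
    sex: Sex
    reporter_category: str
    diseases: frozenset
    drugs: frozenset
    aes: frozenset
    causality: Causality
    ae_soc: tuple = ()

    @property
    def soc_map(self) -> dict:
        return dict(self.ae_soc)

    def has_demographics(self) -> bool:
        return self.age is not None and self.sex is not Sex.UNKNOWN


@dataclass(frozen=True)
class TermDictionary:
    """Raw-term -> (standard term, optional category) lookup.

    Keys are stored in normalized form (lowercase, trimmed, collapsed
    whitespace).  ``unmapped_policy`` is one of ``keep_raw`` (pass the raw
    term through verbatim), ``drop`` (remove it), or ``error`` (raise a
    :class:`StandardizationError` listing the offenders).
    """

    mapping: Mapping[str, tuple]  # normalized raw -> (standard, category|None)
    unmapped_policy: str = "keep_raw"

    def __post_init__(self):
        if self.unmapped_policy not in ("keep_raw", "drop", "error"):
            raise ValueError(f"unknown unmapped_policy: {self.unmapped_policy!r}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple], unmapped_policy: str = "keep_raw") -> "TermDictionary":
        """Build from (raw, standard[, category]) tuples; keys normalized, must be unique."""
        mapping: dict = {}
        for row in pairs:
            raw, standard = row[0], row[1]
            category = row[2] if len(row) > 2 and row[2] not in (None, "") else None
            key = normalize_term(raw)
            if key in mapping and mapping[key] != (standard, category):
                raise ValueError(f"duplicate dictionary key after normalization: {key!r}")
            mapping[key] = (standard, category)
        return cls(mapping=mapping, unmapped_policy=unmapped_policy)

    @classmethod
    def from_table(cls, path, unmapped_policy: str = "keep_raw", sep: Optional[str] = None) -> "TermDictionary":
        """Load a two-or-three-column delimited table (raw, standard[, category])."""
        sep = sep or _infer_sep(path)
        frame = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        return cls.from_pairs(frame.itertuples(index=False, name=None), unmapped_policy=unmapped_policy)

    @classmethod
    def identity(cls) -> "TermDictionary":
        return cls(mapping={}, unmapped_policy="keep_raw")

    def lookup(self, raw: str) -> Optional[tuple]:
        return self.mapping.get(normalize_term(raw))


@dataclass(frozen=True)
class FilterSpec:
    """Cohort inclusion criteria applied in the fixed order
    year -> disease -> causality -> missingness."""

    year_min: int
    year_max: int
    allowed_causality: frozenset = INCLUDED_CAUSALITY
    required_disease_terms: frozenset = frozenset()
    drop_missing: frozenset = frozenset({"drug", "ae"})

    def __post_init__(self):
        if self.year_min > self.year_max:
            raise ValueError(f"year_min {self.year_min} > year_max {self.year_max}")
        if not self.allowed_causality:
            raise ValueError("allowed_causality must be non-empty")
        bad = set(self.drop_missing) - {"drug", "ae", "demographics"}
        if bad:
            raise ValueError(f"unknown drop_missing entries: {sorted(bad)}")


@dataclass
class FilterLog:
    """Per-criterion removal counts, in application order."""

    n_input: int
    removed: "OrderedDict[str, int]" = field(default_factory=OrderedDict)

    @property
    def n_retained(self) -> int:
        return self.n_input - sum(self.removed.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"criterion": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"criterion": "retained", "removed": self.n_retained})
        return pd.DataFrame(rows)


DEFAULT_SCHEMA = {
    "id": "report_id",
    "year": "year",
    "age": "age",
    "sex": "sex",
    "reporter_category": "reporter_category",
    "diseases": "diseases",
    "drugs": "drugs",
    "aes": "aes",
    "causality": "causality",
}

_REQUIRED_FIELDS = ("id", "drugs", "aes", "causality")


def _infer_sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def _split_cell(cell, delimiter: str) -> frozenset:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    parts = (p.strip() for p in str(cell).split(delimiter))
    return frozenset(p for p in parts if p)


def parse_sex(value) -> Sex:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return Sex.UNKNOWN
    return _SEX_ALIASES.get(str(value).strip().lower(), Sex.UNKNOWN)


def parse_causality(value) -> Causality:
    key = str(value).strip().lower()
    try:
        return _CAUSALITY_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized causality grade: {value!r}") from None


def load_reports(
    path,
    schema: Optional[Mapping[str, str]] = None,
    list_delimiter: str = DEFAULT_LIST_DELIMITER,
    sep: Optional[str] = None,
) -> list:
    """Read a delimited report table into a list of :class:`Report`.

    ``schema`` maps logical field names (keys of :data:`DEFAULT_SCHEMA`) to
    the file's column names.  List-valued cells are split on
    ``list_delimiter``, trimmed, and deduplicated.  Missing age/sex are kept
    as missing markers; exclusion happens later in
    :func:`apply_inclusion_filters`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    frame = pd.read_csv(path, sep=sep or _infer_sep(path), dtype=str, keep_default_na=False)

    for logical in _REQUIRED_FIELDS:
        if schema[logical] not in frame.columns:
            raise SchemaError(
                f"required column {schema[logical]!r} (field {logical!r}) not found; "
                f"available: {list(frame.columns)}"
            )

    def col(logical, row):
        name = schema.get(logical)
        if name and name in frame.columns:
            value = row[name]
            return None if value == "" else value
        return None

    reports = []
    for _, row in frame.iterrows():
        year_raw = col("year", row)
        age_raw = col("age", row)
        soc_raw = col("ae_soc", row) if "ae_soc" in schema else None
        reports.append(
            Report(
                report_id=str(col("id", row)),
                year=int(float(year_raw)) if year_raw is not None else None,
                age=float(age_raw) if age_raw is not None else None,
                sex=parse_sex(col("sex", row)),
                reporter_category=str(col("reporter_category", row) or ""),
                diseases=_split_cell(col("diseases", row), list_delimiter),
                drugs=_split_cell(col("drugs", row), list_delimiter),
                aes=_split_cell(col("aes", row), list_delimiter),
                causality=parse_causality(col("causality", row)),
                ae_soc=_parse_soc_cell(soc_raw, list_delimiter),
            )
        )
    logger.info("loaded %d reports from %s", len(reports), path)
    return reports


def _parse_soc_cell(cell, delimiter: str) -> tuple:
    if not cell:
        return ()
    pairs = []
    for item in str(cell).split(delimiter):
        item = item.strip()
        if not item:
            continue
        term, _, category = item.partition("=")
        pairs.append((term.strip(), category.strip()))
    return tuple(sorted(pairs))


def _apply_dictionary(terms: Iterable[str], dictionary: TermDictionary, unmapped_seen: set):
    """Yield (standard, category) for each term under the dictionary's policy."""
    for term in terms:
        hit = dictionary.lookup(term)
        if hit is not None:
            yield hit
        elif dictionary.unmapped_policy == "keep_raw":
            if term not in unmapped_seen:
                unmapped_seen.add(term)
                logger.info("unmapped term kept verbatim: %r", term)
            yield (term, None)
        elif dictionary.unmapped_policy == "drop":
            unmapped_seen.add(term)
        else:
            unmapped_seen.add(term)


def standardize_terms(
    reports: Sequence[Report],
    drug_dict: TermDictionary,
    ae_dict: TermDictionary,
) -> list:
    """Replace drug/AE terms by their standard forms; attach AE categories.

    Deterministic and order-independent over reports.  Under
    ``unmapped_policy='error'`` a single :class:`StandardizationError` lists
    every offending term across the whole input.
    """
    unmapped_drugs: set = set()
    unmapped_aes: set = set()
    out = []
    for report in reports:
        drugs = frozenset(std for std, _ in _apply_dictionary(report.drugs, drug_dict, unmapped_drugs))
        ae_pairs = list(_apply_dictionary(report.aes, ae_dict, unmapped_aes))
        aes = frozenset(std for std, _ in ae_pairs)
        soc = tuple(sorted({(std, cat) for std, cat in ae_pairs if cat is not None}))
        out.append(replace(report, drugs=drugs, aes=aes, ae_soc=soc))

    offenders = []
    if drug_dict.unmapped_policy == "error" and unmapped_drugs:
        offenders += sorted(unmapped_drugs)
    if ae_dict.unmapped_policy == "error" and unmapped_aes:
        offenders += sorted(unmapped_aes)
    if offenders:
        raise StandardizationError(f"unmapped terms: {offenders}")
    n_mapped = sum(len(r.drugs) + len(r.aes) for r in out)
    logger.info(
        "standardized %d reports (%d terms; %d drug / %d AE terms unmapped)",
        len(out), n_mapped, len(unmapped_drugs), len(unmapped_aes),
    )
    return out


def apply_inclusion_filters(reports: Sequence[Report], spec: FilterSpec):
    """Apply cohort criteria in fixed order; return (retained, FilterLog).

    Order: year window -> disease terms -> causality grade -> missingness.
    Each report is counted under the first criterion it fails, so
    ``len(retained) + sum(log.removed.values()) == len(reports)``.
    """
    log = FilterLog(n_input=len(reports))
    current = list(reports)

    def step(name, predicate):
        nonlocal current
        kept = [r for r in current if predicate(r)]
        log.removed[name] = len(current) - len(kept)
        current = kept

    step("year", lambda r: r.year is not None and spec.year_min <= r.year <= spec.year_max)
    if spec.required_disease_terms:
        step("disease", lambda r: bool(r.diseases & spec.required_disease_terms))
    else:
        log.removed["disease"] = 0
    step("causality", lambda r: r.causality in spec.allowed_causality)

    def not_missing(r: Report) -> bool:
        if "drug" in spec.drop_missing and not r.drugs:
            return False
        if "ae" in spec.drop_missing and not r.aes:
            return False
        if "demographics" in spec.drop_missing and not r.has_demographics():
            return False
        return True

    step("missingness", not_missing)
    logger.info(
        "inclusion filters: %d -> %d reports (%s)",
        log.n_input, log.n_retained, dict(log.removed),
    )
    return current, log


# ---------------------------------------------------------------------------
# canonical on-disk round trip (plain CSV; list cells delimiter-joined)

def write_canonical(reports: Sequence[Report], path, list_delimiter: str = DEFAULT_LIST_DELIMITER) -> None:
    rows = []
    for r in reports:
        rows.append({
            "report_id": r.report_id,
            "year": r.year if r.year is not None else "",
            "age": r.age if r.age is not None else "",
            "sex": r.sex.value,
            "reporter_category": r.reporter_category,
            "diseases": list_delimiter.join(sorted(r.diseases)),
            "drugs": list_delimiter.join(sorted(r.drugs)),
            "aes": list_delimiter.join(sorted(r.aes)),
            "ae_soc": list_delimiter.join(f"{t}={c}" for t, c in r.ae_soc),
            "causality": r.causality.value,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_canonical(path, list_delimiter: str = DEFAULT_LIST_DELIMITER) -> list:
    schema = dict(DEFAULT_SCHEMA)
    schema["ae_soc"] = "ae_soc"
    return load_reports(path, schema=schema, list_delimiter=list_delimiter, sep=",")
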