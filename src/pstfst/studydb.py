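"""Data model and I/O for the multi-study P_ST / F_ST comparison database.

One :class:`StudyRecord` is a single extracted observation: one source paper,
one unordered pair of populations, one phenotype, one method of flagging loci
as non-neutral.  The module validates records against the schema invariants,
expands multi-population studies to all pairwise comparisons, averages
replicated observations into one row per (paper x population pair x method)
comparison, and logit-transforms the result into the modeling table the
congruence models consume.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .diffstats import DEFAULT_LOGIT_FLOOR, logit_bounded

__all__ = [
    "SCHEMA_COLUMNS",
    "METHODS",
    "MARKERS",
    "ANALYSIS_GROUPS",
    "StudyRecord",
    "ComparisonRecord",
    "DatabaseReadResult",
    "SchemaError",
    "DatabaseValidationError",
    "read_database",
    "write_database",
    "read_schema_map",
    "expand_pairwise",
    "average_per_comparison",
    "to_model_rows",
    "within_study_rows",
]

#: Canonical column order of the database CSV.
SCHEMA_COLUMNS = (
    "paper_id",
    "species",
    "phenotype_id",
    "pop_a",
    "pop_b",
    "pst",
    "fst_neutral",
    "fst_nonneutral",
    "n_loci_nonneutral",
    "n_loci_total",
    "mean_n_individuals",
    "method",
    "marker",
    "analysis_group",
    "common_garden",
)

#: How the non-neutral loci were identified.
METHODS = ("candidate", "gwas", "outlier")
#: Genetic marker classes (metadata only; F_ST arithmetic is marker-agnostic).
MARKERS = ("msat", "aflp", "snp", "qtl", "haplotype", "window")
#: Software groups used for the F_ST calculation.
ANALYSIS_GROUPS = ("raw", "bayesian", "non_bayesian", "gwas_specific")


class SchemaError(ValueError):
    """The input file's header does not match the canonical schema."""


class DatabaseValidationError(ValueError):
    """One or more rows violate schema invariants."""

    def __init__(self, messages: Sequence[str]):
        self.messages = list(messages)
        super().__init__("; ".join(self.messages))


def _check_proportion(name: str, value: float) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or not math.isfinite(value):
        raise ValueError(f"{name} = {value} outside [0, 1]")
    return value


@dataclass(frozen=True)
class StudyRecord:
    """One extracted paper x population-pair x phenotype x method observation."""

    paper_id: str
    species: str
    phenotype_id: str
    pop_a: str
    pop_b: str
    pst: float
    fst_neutral: Optional[float]  # not every source study reports neutral F_ST
    fst_nonneutral: float
    n_loci_nonneutral: int
    n_loci_total: int
    mean_n_individuals: Optional[float]
    method: str
    marker: str
    analysis_group: str
    common_garden: bool

    def __post_init__(self) -> None:
        if self.pop_a == self.pop_b:
            raise ValueError("pop_a and pop_b must differ")
        _check_proportion("pst", self.pst)
        _check_proportion("fst_nonneutral", self.fst_nonneutral)
        if self.fst_neutral is not None:
            _check_proportion("fst_neutral", self.fst_neutral)
        if self.n_loci_total < 1:
            raise ValueError("n_loci_total must be >= 1")
        if not (0 <= self.n_loci_nonneutral <= self.n_loci_total):
            raise ValueError("n_loci_nonneutral must be between 0 and n_loci_total")
        if self.mean_n_individuals is not None and self.mean_n_individuals <= 0:
            raise ValueError("mean_n_individuals must be > 0")
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.marker not in MARKERS:
            raise ValueError(f"unknown marker {self.marker!r}")
        if self.analysis_group not in ANALYSIS_GROUPS:
            raise ValueError(f"unknown analysis_group {self.analysis_group!r}")
        # canonicalize the unordered pair
        if self.pop_b < self.pop_a:
            a, b = self.pop_a, self.pop_b
            object.__setattr__(self, "pop_a", b)
            object.__setattr__(self, "pop_b", a)

    @property
    def pop_pair(self) -> tuple[str, str]:
        return (self.pop_a, self.pop_b)

    @property
    def prop_nonneutral(self) -> float:
        return self.n_loci_nonneutral / self.n_loci_total


@dataclass(frozen=True)
class ComparisonRecord:
    """One averaged population-level comparison (the global-analysis datapoint).

    Numeric fields are arithmetic means, on the untransformed scale, over the
    StudyRecords sharing (paper, population pair, method, analysis_group);
    replication with distinct methods yields distinct rows.
    """

    paper_id: str
    pop_pair: tuple[str, str]
    method_combo: tuple[str, str]  # (method, analysis_group)
    pst_mean: float
    fst_neutral_mean: Optional[float]
    fst_nonneutral_mean: float
    prop_nonneutral: float
    marker: str
    method: str
    analysis_group: str
    common_garden: bool
    n_contributing: int


@dataclass
class DatabaseReadResult:
    """Validated records plus row-numbered messages for any rejected rows."""

    records: list[StudyRecord]
    rejected: list[str]


_TRUE = {"true", "yes", "y", "1", "t"}
_FALSE = {"false", "no", "n", "0", "f"}


def _parse_bool(raw: str) -> bool:
    low = raw.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"cannot parse boolean {raw!r}")


def _parse_optional_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "" or raw.lower() in ("na", "nan", "none"):
        return None
    return float(raw)


def read_schema_map(path: str | Path) -> dict[str, str]:
    """Read a key-value config mapping canonical column -> source-file column.

    Accepts simple ``canonical: source`` lines (YAML subset).  Canonical names
    absent from the map are assumed to appear verbatim in the source file.
    """
    import yaml

    with open(path) as fh:
        mapping = yaml.safe_load(fh) or {}
    if not isinstance(mapping, dict):
        raise SchemaError(f"schema map {path} must be a flat key-value mapping")
    unknown = set(mapping) - set(SCHEMA_COLUMNS)
    if unknown:
        raise SchemaError(f"schema map names unknown canonical columns: {sorted(unknown)}")
    return {str(k): str(v) for k, v in mapping.items()}


def read_database(
    path: str | Path,
    schema_map: Optional[Mapping[str, str]] = None,
    strict: bool = True,
) -> DatabaseReadResult:
    """Read and validate a comparison database CSV.

    ``schema_map`` renames source columns to the canonical schema before
    validation (so a third-party extraction file can be ingested directly).
    With ``strict=True`` any invalid row raises :class:`DatabaseValidationError`;
    otherwise invalid rows are collected into ``result.rejected`` with
    row-numbered messages and the valid rows are returned.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file")
        header = {name.strip().lower(): name for name in reader.fieldnames}
        rename = dict(schema_map or {})
        colmap: dict[str, str] = {}
        missing = []
        for canon in SCHEMA_COLUMNS:
            source = rename.get(canon, canon).strip().lower()
            if source not in header:
                missing.append(canon)
            else:
                colmap[canon] = header[source]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")

        records: list[StudyRecord] = []
        rejected: list[str] = []
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                records.append(
                    StudyRecord(
                        paper_id=row[colmap["paper_id"]].strip(),
                        species=row[colmap["species"]].strip(),
                        phenotype_id=row[colmap["phenotype_id"]].strip(),
                        pop_a=row[colmap["pop_a"]].strip(),
                        pop_b=row[colmap["pop_b"]].strip(),
                        pst=float(row[colmap["pst"]]),
                        fst_neutral=_parse_optional_float(row[colmap["fst_neutral"]]),
                        fst_nonneutral=float(row[colmap["fst_nonneutral"]]),
                        n_loci_nonneutral=int(row[colmap["n_loci_nonneutral"]]),
                        n_loci_total=int(row[colmap["n_loci_total"]]),
                        mean_n_individuals=_parse_optional_float(
                            row[colmap["mean_n_individuals"]]
                        ),
                        method=row[colmap["method"]].strip().lower(),
                        marker=row[colmap["marker"]].strip().lower(),
                        analysis_group=row[colmap["analysis_group"]].strip().lower(),
                        common_garden=_parse_bool(row[colmap["common_garden"]]),
                    )
                )
            except (ValueError, KeyError) as exc:
                rejected.append(f"row {i}: {exc}")
    if strict and rejected:
        raise DatabaseValidationError(rejected)
    return DatabaseReadResult(records=records, rejected=rejected)


def write_database(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records as a canonical-schema CSV (round-trips with read_database)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEMA_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.paper_id,
                    r.species,
                    r.phenotype_id,
                    r.pop_a,
                    r.pop_b,
                    repr(r.pst),
                    "" if r.fst_neutral is None else repr(r.fst_neutral),
                    repr(r.fst_nonneutral),
                    r.n_loci_nonneutral,
                    r.n_loci_total,
                    "" if r.mean_n_individuals is None else repr(r.mean_n_individuals),
                    r.method,
                    r.marker,
                    r.analysis_group,
                    "yes" if r.common_garden else "no",
                ]
            )


def expand_pairwise(populations: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered pairs of distinct population labels, lexicographic order."""
    labels = sorted(set(populations))
    if len(labels) < 2:
        raise ValueError("at least 2 distinct populations required")
    return list(combinations(labels, 2))


def average_per_comparison(records: Sequence[StudyRecord]) -> list[ComparisonRecord]:
    """Average replicated observations into one row per comparison.

    Grouping key: (paper, unordered population pair, method, analysis_group) —
    a comparison replicated with distinct methods (different software group,
    or a GWAS and an outlier approach) keeps one datapoint per method.  All
    numeric fields are averaged on the untransformed scale; a missing neutral
    F_ST is ignored in its mean (None only if no contributing record has one).
    Factor covariates must agree within a group.
    """
    if not records:
        raise ValueError("no records to average")
    groups: dict[tuple, list[StudyRecord]] = {}
    for r in records:
        key = (r.paper_id, r.pop_pair, r.method, r.analysis_group)
        groups.setdefault(key, []).append(r)

    out: list[ComparisonRecord] = []
    for key in sorted(groups):
        paper_id, pair, method, analysis_group = key
        members = groups[key]
        markers = {m.marker for m in members}
        gardens = {m.common_garden for m in members}
        if len(markers) > 1 or len(gardens) > 1:
            raise ValueError(
                f"conflicting factor covariates in group {key}: "
                f"markers={sorted(markers)}, common_garden={sorted(gardens)}"
            )
        neutral = [m.fst_neutral for m in members if m.fst_neutral is not None]
        out.append(
            ComparisonRecord(
                paper_id=paper_id,
                pop_pair=pair,
                method_combo=(method, analysis_group),
                pst_mean=float(np.mean([m.pst for m in members])),
                fst_neutral_mean=float(np.mean(neutral)) if neutral else None,
                fst_nonneutral_mean=float(np.mean([m.fst_nonneutral for m in members])),
                prop_nonneutral=float(np.mean([m.prop_nonneutral for m in members])),
                marker=members[0].marker,
                method=method,
                analysis_group=analysis_group,
                common_garden=members[0].common_garden,
                n_contributing=len(members),
            )
        )
    return out


def _logit_or_nan(x: Optional[float], floor: float) -> tuple[float, bool]:
    if x is None:
        return (float("nan"), False)
    lv = logit_bounded(x, floor=floor)
    return (lv.value, lv.floor_applied)


def to_model_rows(
    comparisons: Sequence[ComparisonRecord],
    floor: float = DEFAULT_LOGIT_FLOOR,
) -> pd.DataFrame:
    """Logit-transform averaged comparisons into the global modeling table.

    All three differentiation statistics and the proportion of non-neutral
    loci are bounded-logit transformed with the same floor; a proportion of
    exactly 0 is clamped to the floor (and flagged) since its logit is not
    finite.  Missing neutral F_ST becomes NaN and is dropped per-model, not
    globally.
    """
    rows = []
    for c in comparisons:
        l_pst, f_pst = _logit_or_nan(c.pst_mean, floor)
        l_neu, f_neu = _logit_or_nan(c.fst_neutral_mean, floor)
        l_nn, f_nn = _logit_or_nan(c.fst_nonneutral_mean, floor)
        l_prop, f_prop = _logit_or_nan(c.prop_nonneutral, floor)
        rows.append(
            {
                "paper_id": c.paper_id,
                "pop_pair": "|".join(c.pop_pair),
                "method": c.method,
                "analysis_group": c.analysis_group,
                "marker": c.marker,
                "common_garden": c.common_garden,
                "logit_pst": l_pst,
                "logit_fst_neutral": l_neu,
                "logit_fst_nonneutral": l_nn,
                "logit_prop_nonneutral": l_prop,
                "floor_applied": f_pst or f_neu or f_nn or f_prop,
                "n_contributing": c.n_contributing,
            }
        )
    return pd.DataFrame(rows)


def within_study_rows(
    records: Sequence[StudyRecord],
    floor: float = DEFAULT_LOGIT_FLOOR,
) -> pd.DataFrame:
    """Build the within-study modeling table (one row per raw observation).

    Rows are keyed by the paper x phenotype x method combination (``combo_id``);
    unlike the global table these are not averaged across phenotypes, because
    the within-study analysis asks whether individual phenotypes track
    non-neutral F_ST across population pairs.
    """
    rows = []
    for r in records:
        combo = f"{r.paper_id}::{r.phenotype_id}::{r.method}-{r.analysis_group}"
        rows.append(
            {
                "combo_id": combo,
                "paper_id": r.paper_id,
                "phenotype_id": r.phenotype_id,
                "pop_pair": "|".join(r.pop_pair),
                "method": r.method,
                "analysis_group": r.analysis_group,
                "marker": r.marker,
                "common_garden": r.common_garden,
                "logit_pst": logit_bounded(r.pst, floor=floor).value,
                "logit_fst_nonneutral": logit_bounded(r.fst_nonneutral, floor=floor).value,
                "logit_prop_nonneutral": logit_bounded(
                    r.prop_nonneutral, floor=floor
                ).value,
            }
        )
    return pd.DataFrame(rows)
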