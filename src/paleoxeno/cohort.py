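"""Cohort data model and I/O for hair-xenobiotic panels.

The unit of observation is one buried individual with a five-analyte hair
panel: three tea methylxanthines (theobromine, caffeine, theophylline) and
two tobacco markers (nicotine and its metabolite cotinine), each either a
quantified concentration in pg/mg or an explicit non-detect (ND).  ND is a
censoring *state*, never a number; every downstream operation states its
ND policy explicitly.

A 47-individual cohort transcribed from the published per-individual table
ships with the package and is returned by ``load_cohort("builtin")``.
"""

from __future__ import annotations

import csv
import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ANALYTES",
    "METHYLXANTHINES",
    "TOBACCO_ANALYTES",
    "DEFAULT_OUTLIERS",
    "AGE_CLASSES",
    "CensoredConc",
    "AnalyteLimits",
    "DEFAULT_LIMITS",
    "Individual",
    "Cohort",
    "CohortSchemaError",
    "load_cohort",
    "write_cohort",
    "era_of",
    "detected",
    "numeric_panel",
]

ANALYTES = ("theobromine", "caffeine", "theophylline", "nicotine", "cotinine")
METHYLXANTHINES = ("theobromine", "caffeine", "theophylline")
TOBACCO_ANALYTES = ("nicotine", "cotinine")

#: Sample ids flagged as multivariate outliers in the source analysis.
DEFAULT_OUTLIERS = frozenset({14, 29, 31, 41})

SEXES = ("M", "F", "Indet")
AGE_CLASSES = ("0-15", "15-30", "30-50", ">50")
AGE_CLASS_TOKENS = AGE_CLASSES + ("unknown",)
PIPE_TOKENS = ("none", "simple", "special", "imported")
ANTHRACOSIS_TOKENS = ("yes", "yes_with_emphysema", "no", "unassessed")

#: Exact header of the cohort CSV schema.
CSV_COLUMNS = (
    "sample_id",
    "name",
    "dating_start",
    "dating_end",
    "sex",
    "age_class",
    "pipe",
    "shaman",
    "anthracosis",
) + ANALYTES

ND_TOKEN = "ND"

Era = Literal["before_1800", "after_1800"]
NdPolicy = Literal["zero", "drop"]


class CohortSchemaError(ValueError):
    """Raised when a cohort CSV violates the declared schema."""


@dataclass(frozen=True)
class CensoredConc:
    """One analyte measurement: a positive concentration in pg/mg or ND.

    ``value is None`` encodes the non-detect state.
    """

    analyte: str
    value: float | None

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValueError(f"unknown analyte {self.analyte!r}")
        if self.value is not None and not self.value > 0:
            raise ValueError(
                f"{self.analyte}: concentration must be > 0 or ND, got {self.value!r}"
            )

    @property
    def is_nd(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class AnalyteLimits:
    """Detection (LOD) and quantification (LLOQ) limits for one analyte.

    Stored as printed in the validation summary, in ng/mg.  For the three
    methylxanthines the printed LOD (0.05) exceeds the printed LLOQ (0.01),
    which is internally inconsistent; ``lod_exceeds_lloq`` flags this rather
    than silently "fixing" the constants.
    """

    analyte: str
    lod: float
    lloq: float
    unit: str = "ng/mg"

    def __post_init__(self) -> None:
        if self.lod <= 0 or self.lloq <= 0:
            raise ValueError("limits must be positive")

    @property
    def lod_exceeds_lloq(self) -> bool:
        return self.lod > self.lloq


DEFAULT_LIMITS: dict[str, AnalyteLimits] = {
    "theobromine": AnalyteLimits("theobromine", lod=0.05, lloq=0.01),
    "caffeine": AnalyteLimits("caffeine", lod=0.05, lloq=0.01),
    "theophylline": AnalyteLimits("theophylline", lod=0.05, lloq=0.01),
    "nicotine": AnalyteLimits("nicotine", lod=0.01, lloq=0.02),
    "cotinine": AnalyteLimits("cotinine", lod=0.01, lloq=0.02),
}


@dataclass(frozen=True)
class Individual:
    """Metadata and five-analyte panel for one individual."""

    sample_id: int
    name: str
    dating: tuple[int, int]  # [start_AD, end_AD]
    sex: str
    age_class: str
    pipe: str
    shaman: bool
    anthracosis: str
    panel: Mapping[str, CensoredConc]

    def __post_init__(self) -> None:
        start, end = self.dating
        if start > end:
            raise ValueError(f"#{self.sample_id}: dating start {start} > end {end}")
        if self.sex not in SEXES:
            raise ValueError(f"#{self.sample_id}: unknown sex token {self.sex!r}")
        if self.age_class not in AGE_CLASS_TOKENS:
            raise ValueError(
                f"#{self.sample_id}: unknown age class token {self.age_class!r}"
            )
        if self.pipe not in PIPE_TOKENS:
            raise ValueError(f"#{self.sample_id}: unknown pipe token {self.pipe!r}")
        if self.anthracosis not in ANTHRACOSIS_TOKENS:
            raise ValueError(
                f"#{self.sample_id}: unknown anthracosis token {self.anthracosis!r}"
            )
        if tuple(sorted(self.panel)) != tuple(sorted(ANALYTES)):
            raise ValueError(
                f"#{self.sample_id}: panel must contain exactly one entry per analyte"
            )

    def conc(self, analyte: str) -> CensoredConc:
        return self.panel[analyte]


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of individuals with analyte limits and a
    designated outlier set."""

    individuals: tuple[Individual, ...]
    limits: Mapping[str, AnalyteLimits] = field(
        default_factory=lambda: dict(DEFAULT_LIMITS)
    )
    outlier_ids: frozenset[int] = DEFAULT_OUTLIERS

    def __post_init__(self) -> None:
        ids = [ind.sample_id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortSchemaError(f"duplicate sample_id(s): {dupes}")

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals)

    def get(self, sample_id: int) -> Individual:
        for ind in self.individuals:
            if ind.sample_id == sample_id:
                return ind
        raise KeyError(sample_id)

    def without_outliers(self) -> "Cohort":
        kept = tuple(
            ind for ind in self.individuals if ind.sample_id not in self.outlier_ids
        )
        return replace(self, individuals=kept)

    def subset(self, sample_ids: Iterable[int]) -> "Cohort":
        wanted = set(sample_ids)
        kept = tuple(ind for ind in self.individuals if ind.sample_id in wanted)
        return replace(self, individuals=kept)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; ND rendered as NaN (presentation only — the model
        keeps ND as a state)."""
        rows = []
        for ind in self.individuals:
            row: dict[str, object] = {
                "sample_id": ind.sample_id,
                "name": ind.name,
                "dating_start": ind.dating[0],
                "dating_end": ind.dating[1],
                "sex": ind.sex,
                "age_class": ind.age_class,
                "pipe": ind.pipe,
                "shaman": ind.shaman,
                "anthracosis": ind.anthracosis,
            }
            for analyte in ANALYTES:
                c = ind.conc(analyte)
                row[analyte] = np.nan if c.is_nd else c.value
            rows.append(row)
        return pd.DataFrame(rows, columns=list(CSV_COLUMNS))


def _parse_conc(token: str, analyte: str, rownum: int) -> CensoredConc:
    token = token.strip()
    if token == ND_TOKEN:
        return CensoredConc(analyte, None)
    try:
        value = float(token)
    except ValueError:
        raise CohortSchemaError(
            f"row {rownum}: cannot parse {analyte} value {token!r}"
        ) from None
    if value < 0:
        raise CohortSchemaError(
            f"row {rownum}: negative {analyte} concentration {value}"
        )
    if value == 0:
        raise CohortSchemaError(
            f"row {rownum}: zero {analyte} concentration; encode non-detects as 'ND'"
        )
    return CensoredConc(analyte, value)


def _parse_row(row: dict[str, str], rownum: int) -> Individual:
    try:
        sample_id = int(row["sample_id"])
    except ValueError:
        raise CohortSchemaError(
            f"row {rownum}: bad sample_id {row['sample_id']!r}"
        ) from None
    try:
        dating = (int(row["dating_start"]), int(row["dating_end"]))
    except ValueError:
        raise CohortSchemaError(f"row {rownum}: bad dating interval") from None
    sex = row["sex"].strip()
    if sex not in SEXES:
        raise CohortSchemaError(f"row {rownum}: unknown sex token {sex!r}")
    age = row["age_class"].strip()
    if age not in AGE_CLASS_TOKENS:
        raise CohortSchemaError(f"row {rownum}: unknown age class token {age!r}")
    shaman_token = row["shaman"].strip().lower()
    if shaman_token not in ("true", "false"):
        raise CohortSchemaError(f"row {rownum}: shaman must be true/false")
    panel = {a: _parse_conc(row[a], a, rownum) for a in ANALYTES}
    try:
        return Individual(
            sample_id=sample_id,
            name=row["name"],
            dating=dating,
            sex=sex,
            age_class=age,
            pipe=row["pipe"].strip(),
            shaman=shaman_token == "true",
            anthracosis=row["anthracosis"].strip(),
            panel=panel,
        )
    except ValueError as exc:
        raise CohortSchemaError(f"row {rownum}: {exc}") from None


def _builtin_path():
    return importlib.resources.files("paleoxeno.data") / "builtin_cohort.csv"


def load_cohort(path: str | Path = "builtin") -> Cohort:
    """Load a cohort CSV; ``"builtin"`` returns the packaged 47-row table.

    The CSV must carry the exact declared header; ND cells hold the literal
    token ``ND``.  Schema violations raise :class:`CohortSchemaError` with
    the offending row number.
    """
    if path == "builtin":
        text = _builtin_path().read_text(encoding="utf-8")
        lines = text.splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    reader = csv.reader(lines)
    try:
        header = next(reader)
    except StopIteration:
        raise CohortSchemaError("empty file: missing header") from None
    if tuple(header) != CSV_COLUMNS:
        raise CohortSchemaError(
            f"bad header: expected {list(CSV_COLUMNS)}, got {header}"
        )
    individuals = []
    for rownum, values in enumerate(reader, start=2):
        if not values:
            continue
        if len(values) != len(CSV_COLUMNS):
            raise CohortSchemaError(
                f"row {rownum}: expected {len(CSV_COLUMNS)} fields, got {len(values)}"
            )
        individuals.append(_parse_row(dict(zip(CSV_COLUMNS, values)), rownum))
    return Cohort(individuals=tuple(individuals))


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the CSV schema, preserving ND as ``ND``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for ind in cohort:
            row: list[object] = [
                ind.sample_id,
                ind.name,
                ind.dating[0],
                ind.dating[1],
                ind.sex,
                ind.age_class,
                ind.pipe,
                "true" if ind.shaman else "false",
                ind.anthracosis,
            ]
            for analyte in ANALYTES:
                c = ind.conc(analyte)
                row.append(ND_TOKEN if c.is_nd else _fmt_number(c.value))
            writer.writerow(row)


def _fmt_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def era_of(ind: Individual) -> Era:
    """Binary periodization at 1800 AD.

    ``before_1800`` iff the dating interval ends at or before 1800;
    ``after_1800`` iff it starts at or after 1800.  Intervals straddling
    1800 are rejected rather than guessed (none occur in the builtin data).
    """
    start, end = ind.dating
    if end <= 1800:
        return "before_1800"
    if start >= 1800:
        return "after_1800"
    raise ValueError(
        f"#{ind.sample_id}: dating interval {start}-{end} straddles 1800"
    )


def detected(c: CensoredConc, limits: AnalyteLimits | None = None) -> bool:
    """True iff a quantified value is present.

    The source table stores only quantified values, so presence of a value
    is the detection criterion; ``limits`` is accepted for interface
    symmetry and future sub-LLOQ handling.
    """
    return not c.is_nd


def numeric_panel(ind: Individual, nd_policy: NdPolicy = "zero") -> np.ndarray:
    """Panel as a numeric vector under an explicit ND policy.

    ``zero``: ND becomes 0.0 (used by correlations, regressions, PCA).
    ``drop``: ND entries are omitted (used by detected-only summaries).
    """
    if nd_policy == "zero":
        return np.array(
            [0.0 if ind.conc(a).is_nd else ind.conc(a).value for a in ANALYTES]
        )
    if nd_policy == "drop":
        return np.array(
            [ind.conc(a).value for a in ANALYTES if not ind.conc(a).is_nd]
        )
    raise ValueError(f"unknown nd_policy {nd_policy!r}")
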