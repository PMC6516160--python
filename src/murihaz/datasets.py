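"""Reading, validation, filtering and joining of survival and bodyweight tables.

On-disk schemas
---------------
``cohort.csv``  — one row per animal:
    mouse_id, sex, site, cohort, age_days, status, cage_id
``weights.csv`` — one row per weight measurement:
    mouse_id, age_months, weight_g, measured_age_days

Ages are days since birth everywhere internally; months appear only as the
categorical label of the scheduled measurement ages (6, 12, 18, 24).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

SEXES = ("F", "M")
SITES = ("TJL", "UM", "UT")
STATUSES = ("died", "censored")
MEASUREMENT_AGES_MONTHS = (6, 12, 18, 24)

#: Nominal length of a month in days, used when a weight row carries no
#: explicit measurement age (the post-mortem check then uses months * 30.44).
DAYS_PER_MONTH = 30.44

DEFAULT_WEANING_AGE_DAYS = 21.0

COHORT_COLUMNS = ("mouse_id", "sex", "site", "cohort", "age_days", "status", "cage_id")
WEIGHT_COLUMNS = ("mouse_id", "age_months", "weight_g", "measured_age_days")


class SchemaError(ValueError):
    """A required column is missing or the file cannot be interpreted."""


class ValidationError(ValueError):
    """Row-level content violates a table invariant (e.g. duplicate ids)."""


@dataclass(frozen=True)
class MouseRecord:
    """One animal's survival outcome and grouping factors."""

    mouse_id: str
    sex: str
    site: str
    cohort: int
    age_days: float
    status: str
    cage_id: str | None = None
    weaning_age_days: float = DEFAULT_WEANING_AGE_DAYS

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.site not in SITES:
            raise ValidationError(f"site must be one of {SITES}, got {self.site!r}")
        if self.status not in STATUSES:
            raise ValidationError(f"status must be one of {STATUSES}, got {self.status!r}")
        if not self.age_days > 0:
            raise ValidationError(f"age_days must be positive, got {self.age_days}")


@dataclass
class CohortTable:
    """An ordered collection of animal survival records.

    Wraps a validated :class:`pandas.DataFrame` with the ``cohort.csv``
    columns. ``row_errors`` records rows that were rejected during parsing,
    as ``(line_number, message)`` pairs (line numbers count the header as
    line 1, matching what an editor shows).
    """

    table: pd.DataFrame
    provenance: str = ""
    weaning_age_days: float = DEFAULT_WEANING_AGE_DAYS
    row_errors: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.table) == 0 and not self.row_errors:
            raise ValidationError("cohort table is empty")
        dup = self.table["mouse_id"][self.table["mouse_id"].duplicated(keep=False)]
        if len(dup):
            ids = sorted(dup.unique().tolist())
            raise ValidationError(f"duplicate mouse_id values: {ids}")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sexes(self) -> list[str]:
        return sorted(self.table["sex"].unique().tolist())

    def subset(self, mask: pd.Series | np.ndarray, provenance: str | None = None) -> "CohortTable":
        sub = self.table.loc[mask].reset_index(drop=True)
        return CohortTable(sub, provenance or self.provenance, self.weaning_age_days)

    def require_both_sexes(self) -> None:
        missing = [s for s in SEXES if s not in set(self.table["sex"])]
        if missing:
            raise ValidationError(f"between-sex comparison requires both sexes; missing {missing}")


@dataclass
class ExclusionReport:
    """Counts of rows excluded from the bodyweight join, per rule and sex."""

    counts: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, rule: str, sex: str, n: int = 1) -> None:
        if n:
            self.counts[(rule, sex)] = self.counts.get((rule, sex), 0) + int(n)

    def total(self, rule: str | None = None) -> int:
        return sum(n for (r, _), n in self.counts.items() if rule is None or r == rule)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "sex": s, "count": n} for (r, s), n in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["rule", "sex", "count"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def read_cohort(path: str | Path, provenance: str | None = None,
                weaning_age_days: float = DEFAULT_WEANING_AGE_DAYS) -> CohortTable:
    """Read and validate a ``cohort.csv`` survival table.

    Rows failing a row-level check (unparseable or non-positive age, unknown
    category) are rejected and recorded in ``CohortTable.row_errors`` with
    their file line number. A missing required column raises
    :class:`SchemaError`; duplicated ``mouse_id`` raises
    :class:`ValidationError` listing the offending ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = [c for c in COHORT_COLUMNS if c != "cage_id"]
    for col in required:
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    if "cage_id" not in raw.columns:
        raw["cage_id"] = ""

    errors: list[tuple[int, str]] = []
    keep = np.ones(len(raw), dtype=bool)
    # header is line 1, first data row is line 2
    lines = raw.index.to_numpy() + 2

    age = pd.to_numeric(raw["age_days"], errors="coerce")
    cohort_year = pd.to_numeric(raw["cohort"], errors="coerce")
    for i in np.flatnonzero(age.isna().to_numpy()):
        errors.append((int(lines[i]), f"unparseable age_days {raw['age_days'].iat[i]!r}"))
        keep[i] = False
    bad_age = (~age.isna()) & (age <= 0)
    for i in np.flatnonzero(bad_age.to_numpy()):
        errors.append((int(lines[i]), f"age_days must be positive, got {age.iat[i]}"))
        keep[i] = False
    for i in np.flatnonzero(cohort_year.isna().to_numpy()):
        errors.append((int(lines[i]), f"unparseable cohort year {raw['cohort'].iat[i]!r}"))
        keep[i] = False
    for col, vocab in (("sex", SEXES), ("site", SITES), ("status", STATUSES)):
        bad = ~raw[col].isin(vocab)
        for i in np.flatnonzero(bad.to_numpy()):
            errors.append((int(lines[i]), f"{col} {raw[col].iat[i]!r} not in {vocab}"))
            keep[i] = False

    table = pd.DataFrame(
        {
            "mouse_id": raw.loc[keep, "mouse_id"].to_numpy(),
            "sex": pd.Categorical(raw.loc[keep, "sex"], categories=list(SEXES)),
            "site": pd.Categorical(raw.loc[keep, "site"], categories=list(SITES)),
            "cohort": cohort_year[keep].astype(int).to_numpy(),
            "age_days": age[keep].astype(float).to_numpy(),
            "status": pd.Categorical(raw.loc[keep, "status"], categories=list(STATUSES)),
            "cage_id": raw.loc[keep, "cage_id"].to_numpy(),
        }
    )
    return CohortTable(table, provenance or path.name, weaning_age_days, row_errors=errors)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort table back to ``cohort.csv`` form (round-trip safe)."""
    out = cohort.table.copy()
    # repr of float ages is round-trip exact; pandas default float_format is repr
    out.to_csv(path, index=False)


def read_weights(path: str | Path) -> pd.DataFrame:
    """Read a ``weights.csv`` bodyweight table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    for col in ("mouse_id", "age_months", "weight_g"):
        if col not in raw.columns:
            raise SchemaError(f"missing required column {col!r} in {path.name}")
    if "measured_age_days" not in raw.columns:
        raw["measured_age_days"] = np.nan
    bad_month = ~raw["age_months"].isin(MEASUREMENT_AGES_MONTHS)
    if bad_month.any():
        vals = sorted(raw.loc[bad_month, "age_months"].unique().tolist())
        raise ValidationError(
            f"age_months outside scheduled measurement ages {MEASUREMENT_AGES_MONTHS}: {vals}"
        )
    if (raw["weight_g"] <= 0).any():
        raise ValidationError("weight_g must be positive")
    raw["mouse_id"] = raw["mouse_id"].astype(str)
    return raw[list(WEIGHT_COLUMNS)]


def write_weights(weights: pd.DataFrame, path: str | Path) -> None:
    weights.to_csv(path, index=False)


def join_weights(
    cohort: CohortTable, weights: pd.DataFrame | Iterable[dict]
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Join bodyweights onto lifespans, applying the analysis exclusions.

    Three rules, mirroring how bodyweight analyses subset the data:

    1. weights of censored animals are dropped (their lifespan is unknown);
    2. a weight recorded after the animal's death ("post-mortem", i.e.
       measurement age exceeds the recorded age at death) is erroneous and
       dropped — when ``measured_age_days`` is absent the nominal age
       ``age_months * 30.44`` stands in;
    3. weights referencing an unknown ``mouse_id`` are orphans: excluded with
       a warning, not an error.

    Returns the joined analysis table (one row per retained weight, carrying
    ``lifespan_days``) and an :class:`ExclusionReport` with per-rule, per-sex
    counts.
    """
    if not isinstance(weights, pd.DataFrame):
        weights = pd.DataFrame(list(weights))
    report = ExclusionReport()

    merged = weights.merge(
        cohort.table[["mouse_id", "sex", "site", "cohort", "age_days", "status"]],
        on="mouse_id",
        how="left",
        validate="many_to_one",
    )
    orphan = merged["age_days"].isna()
    if orphan.any():
        warnings.warn(
            f"{int(orphan.sum())} weight rows reference unknown mouse_ids and were excluded",
            stacklevel=2,
        )
        report.add("orphan", "unknown", int(orphan.sum()))
        merged = merged.loc[~orphan]

    censored = merged["status"] == "censored"
    for sex, n in merged.loc[censored, "sex"].value_counts().items():
        report.add("censored_animal", str(sex), int(n))
    merged = merged.loc[~censored]

    measured = merged["measured_age_days"].to_numpy(dtype=float)
    nominal = merged["age_months"].to_numpy(dtype=float) * DAYS_PER_MONTH
    measured = np.where(np.isnan(measured), nominal, measured)
    post_mortem = measured > merged["age_days"].to_numpy(dtype=float)
    for sex, n in merged.loc[post_mortem, "sex"].value_counts().items():
        report.add("post_mortem", str(sex), int(n))
    merged = merged.loc[~post_mortem]

    out = merged.rename(columns={"age_days": "lifespan_days"}).reset_index(drop=True)
    return out, report


def heavy_animal_filter(
    joined: pd.DataFrame, threshold_g: float
) -> tuple[pd.DataFrame, int]:
    """Drop rows with ``weight_g`` above ``threshold_g`` (sensitivity filter).

    Idempotent; returns the filtered table and the number of rows removed.
    Emits a warning if the filter empties one sex's stratum entirely.
    """
    if not threshold_g > 0:
        raise ValueError(f"threshold_g must be positive, got {threshold_g}")
    heavy = joined["weight_g"] > threshold_g
    out = joined.loc[~heavy].reset_index(drop=True)
    if "sex" in joined.columns:
        before = set(joined["sex"].dropna().unique())
        after = set(out["sex"].dropna().unique())
        gone = before - after
        if gone:
            warnings.warn(
                f"heavy-animal threshold {threshold_g} g removed every row for sex {sorted(gone)}",
                stacklevel=2,
            )
    return out, int(heavy.sum())
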