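"""Individual-level records and their CSV round trip.

One record is one fly: its sex, diet, lifespan, and the reproduction count
from each 5-day assay it survived to.  Daily reproductive effort is the mean
count per assay; total reproductive effort is the lifetime sum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .diets import DietSpec
from .errors import ExcludedRecordError, ParseError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

ASSAY_INTERVAL_DAYS = 5

RECORD_COLUMNS = [
    "individual_id",
    "sex",
    "diet_id",
    "protein_pct",
    "carbohydrate_pct",
    "lifespan_days",
    "daily_re",
    "total_re",
]

SEXES = ("male", "female")


def derive_reproductive_measures(assay_counts: Sequence[int]) -> tuple[float, int]:
    """Return (daily, total) reproductive effort from per-assay counts.

    Total effort is the sum across assays; daily effort is the mean per
    assay (per mating opportunity).  An individual with no assays carries no
    reproductive information and signals its own exclusion.
    """
    if len(assay_counts) == 0:
        raise ExcludedRecordError("individual has no reproductive assays")
    if any(c < 0 for c in assay_counts):
        raise ValidationError("assay counts must be nonnegative")
    total = int(sum(assay_counts))
    return total / len(assay_counts), total


@dataclass(frozen=True)
class IndividualRecord:
    """One fly with its diet, lifespan and per-assay reproduction counts."""

    individual_id: str
    sex: str
    diet: DietSpec
    lifespan_days: float
    assay_counts: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.lifespan_days > 0:
            raise ValidationError("lifespan_days must be positive")

    @property
    def n_assays(self) -> int:
        return len(self.assay_counts)

    @property
    def total_re(self) -> int:
        return int(sum(self.assay_counts))

    @property
    def daily_re(self) -> float:
        daily, _ = derive_reproductive_measures(self.assay_counts)
        return daily

    def trait_value(self, trait: str) -> float:
        """Look up a named life-history trait of this record."""
        if trait == "lifespan":
            return float(self.lifespan_days)
        if trait == "daily_re":
            return self.daily_re
        if trait == "total_re":
            return float(self.total_re)
        raise ValidationError(f"unknown trait {trait!r}")


def scheduled_assay_days(lifespan_days: float) -> list[int]:
    """Assay days for a given lifespan: day 5, 10, ... while alive."""
    if lifespan_days <= 0:
        raise ValidationError("lifespan_days must be positive")
    last = int(lifespan_days // ASSAY_INTERVAL_DAYS)
    return [ASSAY_INTERVAL_DAYS * k for k in range(1, last + 1)]


def _parse_diet_id(diet_id: str) -> DietSpec:
    try:
        ratio, total = diet_id.split("@")
        p, c = ratio.split(":")
        return DietSpec.from_parts(float(p), float(c), float(total) / 100.0)
    except (ValueError, ValidationError) as exc:
        raise ParseError(f"malformed diet_id {diet_id!r}: {exc}") from exc


def write_records(
    records: Sequence[IndividualRecord],
    path: str | Path,
    assays_path: str | Path | None = None,
) -> None:
    """Write records to CSV, plus an optional long-format assay-count CSV."""
    rows = [
        {
            "individual_id": r.individual_id,
            "sex": r.sex,
            "diet_id": r.diet.diet_id,
            "protein_pct": r.diet.protein_pct,
            "carbohydrate_pct": r.diet.carbohydrate_pct,
            "lifespan_days": r.lifespan_days,
            "daily_re": r.daily_re,
            "total_re": r.total_re,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=RECORD_COLUMNS).to_csv(path, index=False)
    if assays_path is not None:
        assay_rows = [
            {"individual_id": r.individual_id, "assay_day": day, "count": count}
            for r in records
            for day, count in zip(scheduled_assay_days(r.lifespan_days), r.assay_counts)
        ]
        pd.DataFrame(
            assay_rows, columns=["individual_id", "assay_day", "count"]
        ).to_csv(assays_path, index=False)


def read_records(
    path: str | Path, assays_path: str | Path | None = None
) -> list[IndividualRecord]:
    """Read individual records from CSV (schema as written by :func:`write_records`).

    When ``assays_path`` is given, per-assay counts are re-attached from the
    long-format companion table and must be consistent with each record's
    lifespan-implied assay schedule.  Without it, counts are reconstructed
    from ``daily_re``/``total_re`` as evenly spread integers with the stated
    sum (sufficient for every downstream analysis, which uses only the two
    derived measures).  Rows with zero assays are excluded and logged.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")

    counts_by_id: dict[str, list[int]] = {}
    if assays_path is not None:
        adf = pd.read_csv(assays_path)
        for col in ("individual_id", "assay_day", "count"):
            if col not in adf.columns:
                raise SchemaError(f"assay table missing column {col!r}")
        adf = adf.sort_values(["individual_id", "assay_day"])
        for ind, sub in adf.groupby("individual_id", sort=False):
            counts_by_id[str(ind)] = [int(c) for c in sub["count"]]

    records: list[IndividualRecord] = []
    n_excluded = 0
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            lifespan = float(row.lifespan_days)
        except (TypeError, ValueError):
            raise ParseError(
                f"non-numeric lifespan_days {row.lifespan_days!r}", line=line
            ) from None
        diet = _parse_diet_id(str(row.diet_id))
        ind_id = str(row.individual_id)
        if ind_id in counts_by_id:
            counts = counts_by_id[ind_id]
        else:
            try:
                total = int(float(row.total_re))
                n_assays = len(scheduled_assay_days(lifespan))
            except (TypeError, ValueError):
                raise ParseError(f"non-numeric total_re {row.total_re!r}", line=line) from None
            counts = _spread_counts(total, n_assays)
        if len(counts) == 0:
            n_excluded += 1
            continue
        try:
            records.append(
                IndividualRecord(
                    individual_id=ind_id,
                    sex=str(row.sex),
                    diet=diet,
                    lifespan_days=lifespan,
                    assay_counts=tuple(counts),
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), line=line) from exc
    if n_excluded:
        logger.info("excluded %d record(s) with zero reproductive assays", n_excluded)
    return records


def _spread_counts(total: int, n_assays: int) -> list[int]:
    """Integers of length n_assays summing to total, as even as possible."""
    if n_assays == 0:
        return []
    base, extra = divmod(total, n_assays)
    return [base + (1 if k < extra else 0) for k in range(n_assays)]
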