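"""Fiber-monitoring records and their aggregation into annual mean concentrations.

Ambient asbestos surveillance programmes report phase-contrast-microscopy
fiber counts as concentrations in fibers per milliliter of air (f/mL),
sampled repeatedly per year across regions of a city.  The risk models in
this package consume one city-wide mean concentration per calendar year;
this module reads the raw per-region records from CSV, validates them, and
collapses them into that annual series.

Concentrations are carried as :class:`decimal.Decimal` so that a table read
from CSV and written back preserves the original decimal strings exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, InvalidOperation
from pathlib import Path
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import ConfigurationError, ValidationError

#: Calendar years outside this window are rejected as implausible.
YEAR_RANGE = (1990, 2100)

#: Concentrations are compared with this absolute tolerance internally.
CONCENTRATION_ATOL = 1e-12

Weighting = Literal["none", "by_n_samples"]


@dataclass(frozen=True)
class MonitoringRecord:
    """One year/region mean fiber-concentration observation.

    Parameters
    ----------
    year
        Calendar year of the observation.
    region
        Free-text label for the sampling region (may be empty).
    concentration
        PCM-equivalent fiber concentration in f/mL; must be non-negative.
    n_samples
        Optional number of samples behind this record (strictly positive).
    """

    year: int
    region: str
    concentration: Decimal
    n_samples: int | None = None

    def __post_init__(self) -> None:
        if not YEAR_RANGE[0] <= self.year <= YEAR_RANGE[1]:
            raise ValidationError(
                f"year {self.year} outside plausible range {YEAR_RANGE}"
            )
        if not isinstance(self.concentration, Decimal):
            object.__setattr__(self, "concentration", Decimal(str(self.concentration)))
        if self.concentration < 0:
            raise ValidationError(
                f"concentration must be >= 0 f/mL, got {self.concentration}"
            )
        if self.n_samples is not None and self.n_samples <= 0:
            raise ValidationError(f"n_samples must be positive, got {self.n_samples}")


@dataclass(frozen=True)
class AnnualSeries:
    """Mapping year -> annual mean concentration (f/mL) with record counts."""

    means: Mapping[int, float]
    counts: Mapping[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, mean in self.means.items():
            if mean < 0:
                raise ValidationError(f"annual mean for {year} is negative: {mean}")

    def years(self) -> list[int]:
        return sorted(self.means)

    def __getitem__(self, year: int) -> float:
        return self.means[year]

    def __len__(self) -> int:
        return len(self.means)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "year": self.years(),
                "mean_concentration": [self.means[y] for y in self.years()],
                "n_records": [self.counts.get(y, 0) for y in self.years()],
            }
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "annual_means_f_per_mL": {str(y): self.means[y] for y in self.years()},
                "record_counts": {str(y): self.counts.get(y, 0) for y in self.years()},
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "AnnualSeries":
        payload = json.loads(text)
        return cls(
            means={int(y): float(v) for y, v in payload["annual_means_f_per_mL"].items()},
            counts={int(y): int(v) for y, v in payload.get("record_counts", {}).items()},
        )


_REQUIRED_COLUMNS = ("year", "concentration")


def read_monitoring_table(
    path: str | Path, dialect: str = "excel"
) -> list[MonitoringRecord]:
    """Read monitoring records from a delimited file.

    The file must carry a header row with at least ``year`` and
    ``concentration`` columns; ``region`` and ``n_samples`` are optional.
    Every row is either parsed or reported: all offending rows are collected
    into a single :class:`ValidationError` naming their line numbers, so a
    bad file fails loudly instead of silently dropping or coercing values.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"monitoring table not found: {path}")

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, dialect=dialect)
        header = reader.fieldnames or []
        missing = [c for c in _REQUIRED_COLUMNS if c not in header]
        if missing:
            raise ConfigurationError(
                f"{path}: missing required column(s) {missing}; header was {header}"
            )
        records: list[MonitoringRecord] = []
        problems: list[str] = []
        for lineno, row in enumerate(reader, start=2):  # line 1 is the header
            try:
                records.append(_parse_row(row))
            except (ValidationError, ValueError, InvalidOperation) as exc:
                problems.append(f"line {lineno}: {exc}")
    if problems:
        raise ValidationError(
            f"{path}: {len(problems)} invalid row(s):\n" + "\n".join(problems)
        )
    return records


def _parse_row(row: Mapping[str, str | None]) -> MonitoringRecord:
    year = int(str(row["year"]).strip())
    concentration = Decimal(str(row["concentration"]).strip())
    region = (row.get("region") or "").strip()
    n_raw = (row.get("n_samples") or "").strip()
    n_samples = int(n_raw) if n_raw else None
    return MonitoringRecord(
        year=year, region=region, concentration=concentration, n_samples=n_samples
    )


def write_monitoring_table(
    records: Iterable[MonitoringRecord], path: str | Path
) -> None:
    """Write records back to CSV, preserving concentration decimal strings."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["year", "region", "concentration", "n_samples"])
        for rec in records:
            writer.writerow(
                [
                    rec.year,
                    rec.region,
                    str(rec.concentration),
                    "" if rec.n_samples is None else rec.n_samples,
                ]
            )


def annualize(
    records: Iterable[MonitoringRecord], weighting: Weighting = "none"
) -> AnnualSeries:
    """Collapse monitoring records into per-year mean concentrations.

    By default every record counts equally (the city-wide reports do not
    publish per-region sample sizes); with ``weighting="by_n_samples"``
    records are weighted by their sample count, records without one
    contributing weight 1.
    """
    records = list(records)
    if not records:
        raise ValidationError("cannot annualize an empty record list")
    if weighting not in ("none", "by_n_samples"):
        raise ConfigurationError(f"unknown weighting {weighting!r}")

    sums: dict[int, float] = {}
    weights: dict[int, float] = {}
    counts: dict[int, int] = {}
    for rec in records:
        w = 1.0
        if weighting == "by_n_samples" and rec.n_samples is not None:
            w = float(rec.n_samples)
        sums[rec.year] = sums.get(rec.year, 0.0) + w * float(rec.concentration)
        weights[rec.year] = weights.get(rec.year, 0.0) + w
        counts[rec.year] = counts.get(rec.year, 0) + 1
    means = {year: sums[year] / weights[year] for year in sums}
    return AnnualSeries(means=means, counts=counts)
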