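"""Synthetic monitoring scenarios and the published Tehran reference series.

Urban asbestos surveillance data are not publicly archived; only city-wide
annual means appear in published reports.  This module therefore provides
two things:

1. A scenario generator producing monitoring datasets with *known* ground
   truth: a geometrically decaying annual mean with optional episodic spike
   years (e.g. an import event), spread lognormally across regions.  Every
   pipeline stage can then be tested against the generator's own truth
   without any download.
2. The published Tehran 2011-2020 reference values (annual means and the
   derived risk-table columns) as frozen data, the replication surface for
   the deterministic pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal
from math import log
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .monitoring import AnnualSeries, MonitoringRecord

# --------------------------------------------------------------------------
# Scenario generator
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground-truth description of a synthetic monitoring campaign.

    The true city mean for year ``start_year + t`` is
    ``baseline_mean * (1 - annual_decay)**t * spike``, where ``spike`` is the
    multiplier from ``spike_years`` (1 if absent).  Each region contributes
    ``samples_per_region`` measurements drawn from a lognormal with that
    arithmetic mean and geometric standard deviation ``regional_gsd``
    (gsd 1 collapses to the exact mean).
    """

    start_year: int = 2011
    n_years: int = 10
    baseline_mean: float = 0.0065
    annual_decay: float = 0.12
    spike_years: Mapping[int, float] = field(default_factory=dict)
    n_regions: int = 10
    regional_gsd: float = 1.5
    samples_per_region: int = 12
    seed: int = 2011

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0:
            raise ValidationError("baseline_mean must be > 0")
        if not 0 <= self.annual_decay < 1:
            raise ValidationError("annual_decay must lie in [0, 1)")
        if self.regional_gsd < 1:
            raise ValidationError("regional_gsd must be >= 1")
        if self.n_years < 1 or self.n_regions < 1 or self.samples_per_region < 1:
            raise ValidationError("n_years, n_regions, samples_per_region must be >= 1")
        for year, mult in self.spike_years.items():
            if mult <= 0:
                raise ValidationError(f"spike multiplier for {year} must be > 0")

    def true_mean(self, year: int) -> float:
        t = year - self.start_year
        if not 0 <= t < self.n_years:
            raise ValidationError(f"year {year} outside scenario window")
        trend = self.baseline_mean * (1 - self.annual_decay) ** t
        return trend * self.spike_years.get(year, 1.0)


#: Named scenario mirroring the unexplained 2016 concentration increase
#: attributed to an asbestos-containing import event.
IMPORT_EVENT = ScenarioSpec(spike_years={2016: 1.8})


def generate_series(
    spec: ScenarioSpec,
) -> tuple[list[MonitoringRecord], dict[int, float]]:
    """Draw a monitoring dataset and return it with its ground-truth means.

    Returns ``(records, truth)`` where ``truth[year]`` is the exact mean the
    lognormal draws are centred on.  Deterministic under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    sigma = log(spec.regional_gsd)
    records: list[MonitoringRecord] = []
    truth: dict[int, float] = {}
    for t in range(spec.n_years):
        year = spec.start_year + t
        mean = spec.true_mean(year)
        truth[year] = mean
        for r in range(spec.n_regions):
            region = f"R{r + 1:02d}"
            if sigma == 0.0:
                values = np.full(spec.samples_per_region, mean)
            else:
                mu = log(mean) - sigma**2 / 2  # arithmetic-mean-preserving
                values = rng.lognormal(mu, sigma, spec.samples_per_region)
            for v in values:
                records.append(
                    MonitoringRecord(
                        year=year,
                        region=region,
                        concentration=Decimal(repr(float(v))),
                        n_samples=1,
                    )
                )
    return records, truth


def write_truth_sidecar(truth: Mapping[int, float], path: str | Path) -> None:
    """Write the generator's ground-truth means as a JSON sidecar."""
    Path(path).write_text(
        json.dumps({str(y): truth[y] for y in sorted(truth)}, indent=2),
        encoding="utf-8",
    )


# --------------------------------------------------------------------------
# Published Tehran reference values, 2011-2020
# --------------------------------------------------------------------------

#: City-wide annual mean airborne asbestos concentrations, f/mL (PCM).
TEHRAN_ANNUAL_MEANS: dict[int, float] = {
    2011: 0.0065,
    2012: 0.0033,
    2013: 0.0021,
    2014: 0.0017,
    2015: 0.0018,
    2016: 0.0026,
    2017: 0.0014,
    2018: 0.0018,
    2019: 0.0022,
    2020: 0.0019,
}

# Published lung-cancer risk table: cumulative exposure over 50 years,
# relative risk BE/UB, lifetime average concentration, lifetime mortality
# per 100,000 BE/UB, and the published Monte Carlo mean ELCR.
_LUNG_ROWS = [
    # year, x50,    rr_be, rr_ub, c_avg,  mort_be, mort_ub, elcr_mc_mean
    (2011, 0.3250, 1.009, 1.030, 0.0280, 8.4, 30.8, 2.41e-4),
    (2012, 0.1650, 1.005, 1.010, 0.0140, 4.2, 15.4, 1.26e-4),
    (2013, 0.1050, 1.003, 1.010, 0.0090, 2.7, 9.9, 7.76e-5),
    (2014, 0.0850, 1.002, 1.009, 0.0070, 2.1, 7.7, 6.18e-5),
    (2015, 0.0900, 1.003, 1.009, 0.0070, 2.1, 7.7, 6.55e-5),
    (2016, 0.1300, 1.004, 1.010, 0.0110, 3.3, 12.1, 9.55e-5),
    (2017, 0.0700, 1.002, 1.007, 0.0060, 1.8, 6.6, 5.08e-5),
    (2018, 0.0900, 1.003, 1.009, 0.0078, 2.3, 8.6, 6.62e-5),
    (2019, 0.1100, 1.003, 1.012, 0.0096, 2.9, 10.6, 8.09e-5),
    (2020, 0.0935, 1.003, 1.001, 0.0081, 2.4, 8.9, 6.88e-5),
]

# Published mesothelioma table: cumulative exposure, incident cases BE/UB,
# lifetime average concentration, lifetime mortality per 100,000 BE/UB.
_MESO_ROWS = [
    (2011, 0.3250, 6.80, 21.12, 0.0280, 8.96, 27.70),
    (2012, 0.1650, 3.46, 10.72, 0.0140, 4.48, 13.80),
    (2013, 0.1050, 2.20, 6.82, 0.0090, 2.88, 8.90),
    (2014, 0.0850, 1.80, 5.50, 0.0070, 2.24, 6.90),
    (2015, 0.0900, 1.90, 5.85, 0.0070, 2.24, 6.90),
    (2016, 0.1300, 2.70, 8.45, 0.0110, 3.52, 10.80),
    (2017, 0.0700, 1.50, 4.55, 0.0060, 1.92, 5.90),
    (2018, 0.0900, 1.89, 5.85, 0.0078, 2.50, 7.70),
    (2019, 0.1100, 2.31, 7.15, 0.0096, 3.07, 9.50),
    (2020, 0.0935, 1.96, 6.07, 0.0081, 2.60, 8.02),
]


def tehran_annual_means() -> AnnualSeries:
    """The ten published Tehran annual mean concentrations as a series."""
    return AnnualSeries(means=dict(TEHRAN_ANNUAL_MEANS))


def tehran_lung_table() -> pd.DataFrame:
    """Published per-year lung-cancer risk columns (replication reference)."""
    return pd.DataFrame(
        _LUNG_ROWS,
        columns=[
            "year",
            "cumulative_exposure",
            "rr_be",
            "rr_ub",
            "c_avg",
            "lung_mortality_be",
            "lung_mortality_ub",
            "elcr_mc_mean",
        ],
    ).set_index("year")


def tehran_mesothelioma_table() -> pd.DataFrame:
    """Published per-year mesothelioma risk columns (replication reference)."""
    return pd.DataFrame(
        _MESO_ROWS,
        columns=[
            "year",
            "cumulative_exposure",
            "meso_incidence_be",
            "meso_incidence_ub",
            "c_avg",
            "meso_mortality_be",
            "meso_mortality_ub",
        ],
    ).set_index("year")


def tehran_observed_c_avg() -> dict[int, float]:
    """The published lifetime average concentration column, year -> f/mL."""
    return {row[0]: row[4] for row in _LUNG_ROWS}
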