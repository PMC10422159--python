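"""Dose-response endpoint models: lung-cancer RR, lifetime mortality, mesothelioma.

Three scalar models link the exposure metrics to cancer endpoints, each with
best-estimate (BE) / upper-bound (UB) potency bookkeeping:

* lung-cancer relative risk       RR = 1 + KL * X
* lifetime mortality risk         R  = Cavg * UR * 100000   (per 100,000)
* mesothelioma incident cases     I  = X * KM * scale       (per 100,000)

KL and KM are linear potency slopes per unit cumulative exposure
(f/mL*year)^-1 fitted to occupational cohorts; UR is a lifetime unit risk
per f/mL of average lifetime concentration.  The Nicholson-style ratio
recalibration of a reference mesothelioma incidence to a different potency
is also provided (:func:`nicholson_ratio_incidence`).

``build_annual_summary`` assembles the full per-year risk table from an
annual concentration series.  Because published city-wide assessments
sometimes report the lifetime average concentration Cavg as its own
(independently rounded) data column rather than a fixed multiple of the
annual mean, the builder accepts an optional observed Cavg series that
overrides the ``lifetime_weight`` derivation year by year.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple

from .errors import ValidationError
from .exposure import (
    ExposureParameters,
    cumulative_exposure,
    exposure_concentration,
    lifetime_average_concentration,
)
from .monitoring import AnnualSeries
from .risk import elcr

PER_100K = 100_000

#: Empirical factor mapping KM (nominally x1e-8 per f/mL*year) onto the
#: per-100,000 incidence reporting scale of published tables.
DEFAULT_KM_REPORT_SCALE = 1000.0


class Bound(NamedTuple):
    """A best-estimate / upper-bound pair for an uncertain potency."""

    be: float
    ub: float


def _check_bound(name: str, b: Bound) -> None:
    if b.be <= 0 or b.ub <= 0:
        raise ValidationError(f"{name}: BE and UB must be strictly positive")
    if b.ub < b.be:
        raise ValidationError(f"{name}: upper bound {b.ub} below best estimate {b.be}")


@dataclass(frozen=True)
class PotencyFactors:
    """Potency slopes and unit risks, each as a BE/UB pair.

    Defaults are the amphibole-relevant literature values used for ambient
    urban assessments: KL 0.0030/0.011 (f/mL*yr)^-1, KM 0.021/0.065 on the
    table reporting scale, lung UR 0.0030/0.011 (f/mL)^-1, mesothelioma UR
    0.0032/0.0099 (f/mL)^-1, and IUR 0.23 (f/mL)^-1.
    """

    kl: Bound = Bound(0.0030, 0.011)
    km: Bound = Bound(0.021, 0.065)
    ur_lung: Bound = Bound(0.0030, 0.011)
    ur_meso: Bound = Bound(0.0032, 0.0099)
    iur: float = 0.23
    km_report_scale: float = DEFAULT_KM_REPORT_SCALE

    def __post_init__(self) -> None:
        for name in ("kl", "km", "ur_lung", "ur_meso"):
            value = getattr(self, name)
            if not isinstance(value, Bound):
                object.__setattr__(self, name, Bound(*value))
            _check_bound(name, getattr(self, name))
        if self.iur <= 0:
            raise ValidationError("iur must be strictly positive")
        if self.km_report_scale <= 0:
            raise ValidationError("km_report_scale must be strictly positive")


#: Potency set that replicates published RR tables computed with a lung
#: potency ten times the stated KL (see docs/methods.md).
TABLE_REPLICATION_KL = Bound(0.030, 0.11)


@dataclass(frozen=True)
class MesotheliomaCalibration:
    """Inputs of the Nicholson-style ratio recalibration."""

    im_ca: float
    km_sel: float
    km_nic: float

    def __post_init__(self) -> None:
        if self.im_ca < 0 or self.km_sel < 0:
            raise ValidationError("im_ca and km_sel must be non-negative")
        if self.km_nic <= 0:
            raise ValidationError("km_nic must be strictly positive")


def relative_risk(x: float, kl: float) -> float:
    """Lung-cancer relative risk RR = 1 + KL*X for cumulative exposure X."""
    if x < 0:
        raise ValidationError(f"cumulative exposure must be >= 0, got {x}")
    if kl < 0:
        raise ValidationError(f"potency factor must be >= 0, got {kl}")
    return 1.0 + kl * x


def lifetime_mortality_risk(c_avg: float, ur: float) -> float:
    """Lifetime mortality risk R = Cavg*UR, reported per 100,000 persons."""
    if c_avg < 0:
        raise ValidationError(f"average lifetime concentration must be >= 0, got {c_avg}")
    if ur <= 0:
        raise ValidationError(f"unit risk must be positive, got {ur}")
    return c_avg * ur * PER_100K


def mesothelioma_incidence(
    x: float, km: float, report_scale: float = DEFAULT_KM_REPORT_SCALE
) -> float:
    """Predicted mesothelioma incident cases per 100,000, I = X*KM*scale."""
    if x < 0:
        raise ValidationError(f"cumulative exposure must be >= 0, got {x}")
    if km < 0:
        raise ValidationError(f"potency factor must be >= 0, got {km}")
    if report_scale <= 0:
        raise ValidationError(f"report_scale must be positive, got {report_scale}")
    return x * km * report_scale


def nicholson_ratio_incidence(cal: MesotheliomaCalibration) -> float:
    """Recalibrate a reference incidence by a potency ratio: IM_Ca*KM_sel/KM_Nic."""
    return cal.im_ca * cal.km_sel / cal.km_nic


@dataclass(frozen=True)
class AnnualRiskSummary:
    """One year's complete computed risk row."""

    year: int
    mean_exposure: float
    cumulative_exposure: float
    rr_be: float
    rr_ub: float
    c_avg: float
    lung_mortality_be: float
    lung_mortality_ub: float
    meso_incidence_be: float
    meso_incidence_ub: float
    meso_mortality_be: float
    meso_mortality_ub: float
    elcr_mean: float

    def __post_init__(self) -> None:
        if self.rr_be < 1 or self.rr_ub < 1:
            raise ValidationError("relative risk cannot fall below baseline 1")
        for name in (
            "mean_exposure",
            "cumulative_exposure",
            "c_avg",
            "lung_mortality_be",
            "lung_mortality_ub",
            "meso_incidence_be",
            "meso_incidence_ub",
            "meso_mortality_be",
            "meso_mortality_ub",
            "elcr_mean",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        for be, ub in (
            (self.rr_be, self.rr_ub),
            (self.lung_mortality_be, self.lung_mortality_ub),
            (self.meso_incidence_be, self.meso_incidence_ub),
            (self.meso_mortality_be, self.meso_mortality_ub),
        ):
            if ub < be:
                raise ValidationError("upper-bound column fell below best estimate")


def build_annual_summary(
    series: AnnualSeries,
    params: ExposureParameters | None = None,
    potency: PotencyFactors | None = None,
    c_avg_observed: Mapping[int, float] | None = None,
) -> list[AnnualRiskSummary]:
    """Compute the full risk table, one row per year of the series.

    ``c_avg_observed`` optionally supplies measured/published lifetime
    average concentrations per year; years not listed fall back to
    ``mean * lifetime_weight``.
    """
    if len(series) == 0:
        raise ValidationError("annual series is empty")
    params = params or ExposureParameters()
    potency = potency or PotencyFactors()
    rows: list[AnnualRiskSummary] = []
    for year in series.years():
        c = series[year]
        x = cumulative_exposure(c, params.cumulative_horizon)
        if c_avg_observed is not None and year in c_avg_observed:
            c_avg = float(c_avg_observed[year])
        else:
            c_avg = lifetime_average_concentration(c, params.lifetime_weight)
        ec = exposure_concentration(c, params)
        rows.append(
            AnnualRiskSummary(
                year=year,
                mean_exposure=c,
                cumulative_exposure=x,
                rr_be=relative_risk(x, potency.kl.be),
                rr_ub=relative_risk(x, potency.kl.ub),
                c_avg=c_avg,
                lung_mortality_be=lifetime_mortality_risk(c_avg, potency.ur_lung.be),
                lung_mortality_ub=lifetime_mortality_risk(c_avg, potency.ur_lung.ub),
                meso_incidence_be=mesothelioma_incidence(
                    x, potency.km.be, potency.km_report_scale
                ),
                meso_incidence_ub=mesothelioma_incidence(
                    x, potency.km.ub, potency.km_report_scale
                ),
                meso_mortality_be=lifetime_mortality_risk(c_avg, potency.ur_meso.be),
                meso_mortality_ub=lifetime_mortality_risk(c_avg, potency.ur_meso.ub),
                elcr_mean=elcr(ec, potency.iur),
            )
        )
    return rows
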