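"""Exposure metrics: EC, cumulative exposure X, and lifetime average Cavg.

Three exposure quantities feed the downstream dose-response models, all
linear in the measured annual mean concentration C (f/mL):

* exposure concentration  EC = C * ET * EF * ED / AT   (f/mL),
  the time-activity-weighted concentration a receptor actually experiences,
* cumulative exposure     X  = C * horizon             (f/mL*year),
  the dose metric of the lung and mesothelioma potency models, accumulated
  over the 50-year horizon that covers the fiber's 20-50 year latency,
* lifetime average        Cavg = C * weight            (f/mL),
  a weighted average outdoor exposure concentration used with lifetime
  unit risks.

The default time-activity values describe a general urban population:
ET = 24 h/day outdoors-equivalent exposure, EF = 180 days/year,
ED = 24 years of exposure, averaged over a 74-year lifetime
(AT = 74*365*24 hours).  The Cavg weight defaults to 30/7 (~4.286), an
empirical calibration constant relating city-wide annual means to the
lifetime average concentration; see docs/methods.md for its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

#: Default averaging time: 74-year lifetime in hours, 365-day years.
DEFAULT_AVERAGING_TIME_H = 74 * 365 * 24

#: Default annual-mean -> lifetime-average concentration multiplier.
DEFAULT_LIFETIME_WEIGHT = 30 / 7


@dataclass(frozen=True)
class ExposureParameters:
    """Time-activity constants of the exposure model.

    Attributes
    ----------
    exposure_time
        ET, hours of exposure per day (0 < ET <= 24).
    exposure_frequency
        EF, days of exposure per year (0 < EF <= 366).
    exposure_duration
        ED, years of exposure.
    averaging_time
        AT, hours over which exposure is averaged (a lifetime).
    cumulative_horizon
        Years over which cumulative exposure X accrues (default 50).
    lifetime_weight
        Dimensionless multiplier mapping the annual mean to Cavg.
    """

    exposure_time: float = 24.0
    exposure_frequency: float = 180.0
    exposure_duration: float = 24.0
    averaging_time: float = DEFAULT_AVERAGING_TIME_H
    cumulative_horizon: float = 50.0
    lifetime_weight: float = DEFAULT_LIFETIME_WEIGHT

    def __post_init__(self) -> None:
        for name in (
            "exposure_time",
            "exposure_frequency",
            "exposure_duration",
            "averaging_time",
            "cumulative_horizon",
            "lifetime_weight",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")
        if self.exposure_time > 24:
            raise ValidationError("exposure_time cannot exceed 24 h/day")
        if self.exposure_frequency > 366:
            raise ValidationError("exposure_frequency cannot exceed 366 days/year")
        exposed_hours = (
            self.exposure_time * self.exposure_frequency * self.exposure_duration
        )
        if exposed_hours > self.averaging_time:
            raise ValidationError(
                "ET*EF*ED exceeds the averaging time: exposure cannot exceed lifetime"
            )

    @property
    def time_activity_factor(self) -> float:
        """EC / C, the dimensionless factor ET*EF*ED/AT (~0.15994 at defaults)."""
        return (
            self.exposure_time
            * self.exposure_frequency
            * self.exposure_duration
            / self.averaging_time
        )


@dataclass(frozen=True)
class ExposureResult:
    """The three exposure quantities computed from one annual mean."""

    ec: float
    cumulative_exposure: float
    c_avg: float

    def __post_init__(self) -> None:
        for name in ("ec", "cumulative_exposure", "c_avg"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


def exposure_concentration(c: float, params: ExposureParameters | None = None) -> float:
    """EC = C*ET*EF*ED/AT, f/mL."""
    if c < 0:
        raise ValidationError(f"concentration must be >= 0 f/mL, got {c}")
    params = params or ExposureParameters()
    return c * params.exposure_time * params.exposure_frequency \
        * params.exposure_duration / params.averaging_time


def cumulative_exposure(c: float, horizon: float = 50.0) -> float:
    """X = C * horizon, f/mL*year, over the latency-covering horizon."""
    if c < 0:
        raise ValidationError(f"concentration must be >= 0 f/mL, got {c}")
    if horizon <= 0:
        raise ValidationError(f"horizon must be positive, got {horizon}")
    return c * horizon


def lifetime_average_concentration(
    c: float, weight: float = DEFAULT_LIFETIME_WEIGHT
) -> float:
    """Cavg = C * weight, f/mL."""
    if c < 0:
        raise ValidationError(f"concentration must be >= 0 f/mL, got {c}")
    if weight <= 0:
        raise ValidationError(f"weight must be positive, got {weight}")
    return c * weight


def compute_exposure(c: float, params: ExposureParameters | None = None) -> ExposureResult:
    """All three exposure quantities for one annual mean concentration."""
    params = params or ExposureParameters()
    return ExposureResult(
        ec=exposure_concentration(c, params),
        cumulative_exposure=cumulative_exposure(c, params.cumulative_horizon),
        c_avg=lifetime_average_concentration(c, params.lifetime_weight),
    )
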