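"""Excess lifetime cancer risk, risk-band classification, and Monte Carlo engine.

ELCR = EC * IUR, where IUR is the inhalation unit risk applied per f/mL of
lifetime-averaged exposure concentration.  Computed risks are screened
against the regulatory bands: below 1e-6 the risk is *acceptable*, above
1e-4 it is *considerable*, and in between (including the boundaries, which
the screening guidance leaves open) it is *tolerable*.

The Monte Carlo engine propagates uncertainty in the exposure factors
(C, ET, EF, ED) through EC into ELCR.  Each factor carries an input
distribution; point distributions are allowed and collapse the engine
exactly onto the deterministic pipeline, which doubles as a correctness
check.  Lognormal concentration inputs are parametrised by (mean, gsd)
with the *arithmetic* mean preserved, the conventional description of
airborne fiber variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Iterable, Mapping

import numpy as np

from .errors import ConfigurationError, ValidationError
from .exposure import ExposureParameters

#: Factors of the EC equation that may carry an input distribution.
EC_FACTORS = ("C", "ET", "EF", "ED")

#: Library default seed; the CLI requires an explicit one.
DEFAULT_SEED = 2011

DEFAULT_N_ITERATIONS = 10_000


@dataclass(frozen=True)
class RiskBands:
    """Screening thresholds for lifetime cancer risk."""

    acceptable_below: float = 1e-6
    considerable_above: float = 1e-4

    def __post_init__(self) -> None:
        if not self.acceptable_below < self.considerable_above:
            raise ValidationError(
                "acceptable_below must be smaller than considerable_above"
            )


def elcr(ec: float, iur: float) -> float:
    """Excess lifetime cancer risk from exposure concentration and unit risk."""
    if ec < 0:
        raise ValidationError(f"exposure concentration must be >= 0, got {ec}")
    if iur <= 0:
        raise ValidationError(f"inhalation unit risk must be positive, got {iur}")
    return ec * iur


def classify_risk(r: float, bands: RiskBands | None = None) -> str:
    """Assign a risk to ``acceptable``, ``tolerable`` or ``considerable``.

    Boundary values fall in the middle band: the guidance phrases the outer
    bands strictly ("more than" / "lower than").
    """
    if r < 0:
        raise ValidationError(f"risk must be >= 0, got {r}")
    bands = bands or RiskBands()
    if r < bands.acceptable_below:
        return "acceptable"
    if r > bands.considerable_above:
        return "considerable"
    return "tolerable"


@dataclass(frozen=True)
class InputDistribution:
    """Distribution of one EC factor for the Monte Carlo engine.

    Supported families and their parameters:

    ``point``       value
    ``lognormal``   mean (arithmetic), gsd (geometric standard deviation >= 1)
    ``triangular``  left, mode, right
    ``uniform``     low, high

    All supports must be non-negative.
    """

    factor: str
    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.factor not in EC_FACTORS:
            raise ConfigurationError(
                f"unknown factor {self.factor!r}; expected one of {EC_FACTORS}"
            )
        getattr(self, f"_check_{self.family}", self._unknown_family)()

    def _unknown_family(self) -> None:
        raise ConfigurationError(f"unknown distribution family {self.family!r}")

    def _check_point(self) -> None:
        if self._p("value") < 0:
            raise ValidationError(f"{self.factor}: point value must be >= 0")

    def _check_lognormal(self) -> None:
        if self._p("mean") <= 0:
            raise ValidationError(f"{self.factor}: lognormal mean must be > 0")
        if self._p("gsd") < 1:
            raise ValidationError(f"{self.factor}: gsd must be >= 1")

    def _check_triangular(self) -> None:
        left, mode, right = self._p("left"), self._p("mode"), self._p("right")
        if not 0 <= left <= mode <= right:
            raise ValidationError(
                f"{self.factor}: need 0 <= left <= mode <= right, "
                f"got ({left}, {mode}, {right})"
            )
        if left == right:
            raise ValidationError(f"{self.factor}: degenerate triangular; use point")

    def _check_uniform(self) -> None:
        low, high = self._p("low"), self._p("high")
        if not 0 <= low < high:
            raise ValidationError(f"{self.factor}: need 0 <= low < high")

    def _p(self, key: str) -> float:
        try:
            return float(self.params[key])
        except KeyError:
            raise ConfigurationError(
                f"{self.factor}/{self.family}: missing parameter {key!r}"
            ) from None

    @classmethod
    def point(cls, factor: str, value: float) -> "InputDistribution":
        return cls(factor, "point", {"value": value})

    @classmethod
    def lognormal(cls, factor: str, mean: float, gsd: float) -> "InputDistribution":
        return cls(factor, "lognormal", {"mean": mean, "gsd": gsd})

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "point":
            return np.full(n, self._p("value"))
        if self.family == "lognormal":
            # mean-preserving: mu = ln(mean) - sigma^2/2, sigma = ln(gsd)
            sigma = log(self._p("gsd"))
            if sigma == 0.0:
                return np.full(n, self._p("mean"))
            mu = log(self._p("mean")) - sigma**2 / 2
            return rng.lognormal(mean=mu, sigma=sigma, size=n)
        if self.family == "triangular":
            return rng.triangular(self._p("left"), self._p("mode"), self._p("right"), n)
        return rng.uniform(self._p("low"), self._p("high"), n)


@dataclass(frozen=True)
class MonteCarloResult:
    """Summary of a sampled ELCR distribution."""

    n_iterations: int
    seed: int
    mean: float
    percentile_95: float
    percentile_5: float
    std: float

    def __post_init__(self) -> None:
        if self.n_iterations <= 0:
            raise ValidationError("n_iterations must be positive")
        if self.percentile_5 > self.percentile_95:
            raise ValidationError("percentile_5 cannot exceed percentile_95")


def monte_carlo_elcr(
    dists: Iterable[InputDistribution],
    params: ExposureParameters,
    iur: float,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = DEFAULT_SEED,
) -> MonteCarloResult:
    """Propagate factor uncertainty through EC = C*ET*EF*ED/AT into ELCR.

    ``dists`` must cover the concentration C; ET/EF/ED default to point
    distributions at their ``params`` values when not listed.  Sampling is
    joint-independent across factors.  Identical seed and inputs give
    bit-identical summaries.
    """
    if n_iterations < 1:
        raise ValidationError("n_iterations must be >= 1")
    if iur <= 0:
        raise ValidationError("inhalation unit risk must be positive")
    by_factor: dict[str, InputDistribution] = {}
    for dist in dists:
        if dist.factor in by_factor:
            raise ConfigurationError(f"duplicate distribution for factor {dist.factor}")
        by_factor[dist.factor] = dist
    if "C" not in by_factor:
        raise ConfigurationError("a distribution for the concentration C is required")
    defaults = {
        "ET": params.exposure_time,
        "EF": params.exposure_frequency,
        "ED": params.exposure_duration,
    }
    for factor, value in defaults.items():
        by_factor.setdefault(factor, InputDistribution.point(factor, value))

    rng = np.random.default_rng(seed)
    # Fixed sampling order keeps the draw stream reproducible.
    draws = {f: by_factor[f].sample(rng, n_iterations) for f in EC_FACTORS}
    ec = draws["C"] * draws["ET"] * draws["EF"] * draws["ED"] / params.averaging_time
    samples = ec * iur

    p5, p95 = np.percentile(samples, [5.0, 95.0])  # linear interpolation
    # A constant sample must collapse exactly onto the deterministic value
    # (and zero spread); pairwise summation inside mean()/std() can
    # otherwise drift by one ulp.
    if samples.min() == samples.max():
        mean, std = float(samples[0]), 0.0
    else:
        mean = float(samples.mean())
        std = float(samples.std(ddof=1)) if n_iterations > 1 else 0.0
    return MonteCarloResult(
        n_iterations=n_iterations,
        seed=seed,
        mean=mean,
        percentile_95=float(p95),
        percentile_5=float(p5),
        std=std,
    )
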