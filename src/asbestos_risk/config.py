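"""YAML/JSON run configuration for the assessment pipeline.

A configuration file has up to five blocks, all optional (defaults mirror
the published Tehran assessment):

.. code-block:: yaml

    input: monitoring.csv          # or `scenario:` - exactly one of the two
    scenario:
      start_year: 2011
      n_years: 10
      baseline_mean: 0.0065
      annual_decay: 0.12
      spike_years: {2016: 1.8}
    exposure:
      exposure_time: 24            # h/day
      exposure_frequency: 180      # days/year
      exposure_duration: 24        # years
      averaging_time: 648240       # hours (74 y x 365 d x 24 h)
      cumulative_horizon: 50       # years
      lifetime_weight: 4.2857142857142855
    potency:
      kl: {be: 0.0030, ub: 0.011}
      km: {be: 0.021, ub: 0.065}
      ur_lung: {be: 0.0030, ub: 0.011}
      ur_meso: {be: 0.0032, ub: 0.0099}
      iur: 0.23
      km_report_scale: 1000
    monte_carlo:
      n_iterations: 10000
      seed: 2011
      distributions:
        - {factor: C, family: lognormal, params: {gsd: 1.5}}
    risk_bands: {acceptable_below: 1.0e-6, considerable_above: 1.0e-4}

For the concentration factor ``C``, a lognormal spec may omit ``mean``:
the per-year annual mean is filled in at run time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .endpoints import Bound, PotencyFactors, TABLE_REPLICATION_KL
from .errors import ConfigurationError
from .exposure import ExposureParameters
from .risk import DEFAULT_N_ITERATIONS, DEFAULT_SEED, RiskBands
from .synthetic import ScenarioSpec


@dataclass(frozen=True)
class MonteCarloSettings:
    """Iteration count, seed, and per-factor distribution specs."""

    n_iterations: int = DEFAULT_N_ITERATIONS
    seed: int = DEFAULT_SEED
    #: raw distribution specs: [{"factor": ..., "family": ..., "params": {...}}]
    distributions: tuple[Mapping[str, Any], ...] = (
        {"factor": "C", "family": "lognormal", "params": {"gsd": 1.5}},
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything one assessment run needs."""

    input_path: Path | None = None
    scenario: ScenarioSpec | None = None
    exposure: ExposureParameters = field(default_factory=ExposureParameters)
    potency: PotencyFactors = field(default_factory=PotencyFactors)
    monte_carlo: MonteCarloSettings = field(default_factory=MonteCarloSettings)
    risk_bands: RiskBands = field(default_factory=RiskBands)

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigurationError(
                "exactly one of input path / synthetic scenario must be specified"
            )

    def digest(self) -> str:
        """Stable hash of the configuration, for the run log."""
        payload = {
            "input_path": str(self.input_path) if self.input_path else None,
            "scenario": asdict(self.scenario) if self.scenario else None,
            "exposure": asdict(self.exposure),
            "potency": {
                k: list(v) if isinstance(v, Bound) else v
                for k, v in asdict(self.potency).items()
            },
            "monte_carlo": asdict(self.monte_carlo),
            "risk_bands": asdict(self.risk_bands),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _bound(block: Mapping[str, Any], key: str, default: Bound) -> Bound:
    raw = block.get(key)
    if raw is None:
        return default
    try:
        return Bound(float(raw["be"]), float(raw["ub"]))
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"potency.{key}: expected {{be, ub}}") from exc


def potency_from_dict(block: Mapping[str, Any]) -> PotencyFactors:
    defaults = PotencyFactors()
    return PotencyFactors(
        kl=_bound(block, "kl", defaults.kl),
        km=_bound(block, "km", defaults.km),
        ur_lung=_bound(block, "ur_lung", defaults.ur_lung),
        ur_meso=_bound(block, "ur_meso", defaults.ur_meso),
        iur=float(block.get("iur", defaults.iur)),
        km_report_scale=float(block.get("km_report_scale", defaults.km_report_scale)),
    )


def table_replication_potency() -> PotencyFactors:
    """Potency set replicating the published RR(BE) column (KL x10)."""
    return PotencyFactors(kl=TABLE_REPLICATION_KL)


def load_config(path: str | Path) -> RunConfig:
    """Parse a YAML (or JSON) configuration file into a :class:`RunConfig`."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: top level must be a mapping")
    return config_from_dict(raw, base_dir=path.parent)


def config_from_dict(raw: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    base_dir = base_dir or Path.cwd()
    known = {"input", "scenario", "exposure", "potency", "monte_carlo", "risk_bands"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config block(s): {sorted(unknown)}")

    input_path = None
    if raw.get("input") is not None:
        input_path = (base_dir / str(raw["input"])).resolve()

    scenario = None
    if raw.get("scenario") is not None:
        block = dict(raw["scenario"])
        if "spike_years" in block:
            block["spike_years"] = {
                int(y): float(m) for y, m in block["spike_years"].items()
            }
        try:
            scenario = ScenarioSpec(**block)
        except TypeError as exc:
            raise ConfigurationError(f"scenario block: {exc}") from exc

    try:
        exposure = ExposureParameters(**(raw.get("exposure") or {}))
    except TypeError as exc:
        raise ConfigurationError(f"exposure block: {exc}") from exc

    mc_raw = dict(raw.get("monte_carlo") or {})
    if "distributions" in mc_raw:
        mc_raw["distributions"] = tuple(mc_raw["distributions"])
    try:
        monte_carlo = MonteCarloSettings(**mc_raw)
    except TypeError as exc:
        raise ConfigurationError(f"monte_carlo block: {exc}") from exc

    try:
        risk_bands = RiskBands(**(raw.get("risk_bands") or {}))
    except TypeError as exc:
        raise ConfigurationError(f"risk_bands block: {exc}") from exc

    return RunConfig(
        input_path=input_path,
        scenario=scenario,
        exposure=exposure,
        potency=potency_from_dict(raw.get("potency") or {}),
        monte_carlo=monte_carlo,
        risk_bands=risk_bands,
    )
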