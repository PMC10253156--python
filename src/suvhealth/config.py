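"""Run configuration: one YAML file describing a full reproducible run."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .co2 import CARBON_PRICES, GridIntensitySeries
from .nox import EuroLimitTable, LegacyComposition
from .scenarios import SCENARIOS

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (bad scenario name, missing file, ...)."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs.

    ``fleet_path`` / ``population_path`` point at delimited input files; when
    either is None the synthetic generator stands in (seeded by ``seed``).
    """

    seed: int = 0
    fleet_path: str | None = None
    population_path: str | None = None
    scenarios: list[str] = field(
        default_factory=lambda: list(SCENARIOS))
    horizons: list[int] = field(default_factory=lambda: [2035, 2050])
    nox_years_until: int = 2060
    health_end_year: int = 2126
    grid_anchors: dict[int, float] | None = None
    grid_path: str | None = None
    euro_limits_path: str | None = None
    carbon_prices: dict[int, dict[str, float]] = field(
        default_factory=lambda: {h: dict(p) for h, p in CARBON_PRICES.items()})
    volys: list[float] = field(default_factory=lambda: [20_000.0, 60_000.0])
    discount_rates: list[float] = field(default_factory=lambda: [0.015, 0.035])
    rr_coefficients: list[float] = field(default_factory=lambda: [1.008, 1.023, 1.037])
    legacy_diesel_share: float = 0.45
    output_dir: str = "results"

    def __post_init__(self) -> None:
        unknown = [s for s in self.scenarios if s not in SCENARIOS]
        if unknown:
            raise ConfigError(
                f"unknown scenario name(s) {unknown}; valid: {list(SCENARIOS)}")
        if "BAU" not in self.scenarios:
            self.scenarios = ["BAU"] + self.scenarios
        for path in (self.fleet_path, self.population_path, self.grid_path,
                     self.euro_limits_path):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if "grid_anchors" in raw and raw["grid_anchors"] is not None:
            raw["grid_anchors"] = {int(k): float(v)
                                   for k, v in raw["grid_anchors"].items()}
        if "carbon_prices" in raw:
            raw["carbon_prices"] = {
                int(h): {str(k): float(v) for k, v in d.items()}
                for h, d in raw["carbon_prices"].items()}
        return cls(**raw)

    def grid(self) -> GridIntensitySeries:
        if self.grid_path:
            return GridIntensitySeries.from_file(self.grid_path)
        return GridIntensitySeries.default(self.grid_anchors)

    def euro_limits(self) -> EuroLimitTable:
        if self.euro_limits_path:
            return EuroLimitTable.from_file(self.euro_limits_path)
        return EuroLimitTable()

    def legacy(self) -> LegacyComposition:
        return LegacyComposition(diesel_share=self.legacy_diesel_share)
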