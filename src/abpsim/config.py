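"""Scenario configuration: YAML loading, validation, presets, report writing.

A scenario config bundles everything one simulation run needs: the
disease epidemiology, the payer economics, the therapy price, the
candidate payment schemes, the durability of effect, and the horizon
truncation policy. Configs are human-editable YAML; unknown keys are
rejected by name and rates given in percent instead of fractions are
caught with a hint.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .conditions import EconomicSpec
from .epidemiology import EpidemiologySpec
from .streams import PaymentScheme, TruncationPolicy

__all__ = [
    "ConfigError",
    "ScenarioConfig",
    "load_config",
    "load_preset",
    "list_presets",
    "dump_config",
    "write_report",
]

log = logging.getLogger("abpsim")


class ConfigError(ValueError):
    """A scenario configuration failed validation."""


@dataclass(frozen=True)
class ScenarioConfig:
    name: str = "default"
    epidemiology: EpidemiologySpec = field(default_factory=EpidemiologySpec)
    economics: EconomicSpec = field(default_factory=lambda: EconomicSpec(budget_cap=250e6))
    price: float = 1_000_000.0
    durability_years: float = 75.0
    truncation: TruncationPolicy = TruncationPolicy.WINDOW_ONLY
    schemes: tuple[PaymentScheme, ...] = ()

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ConfigError("price must be > 0")
        if self.durability_years <= 0:
            raise ConfigError("durability_years must be > 0")
        object.__setattr__(self, "truncation", TruncationPolicy(self.truncation))
        object.__setattr__(self, "schemes", tuple(self.schemes))

    def with_schemes(self, schemes) -> "ScenarioConfig":
        return dataclasses.replace(self, schemes=tuple(schemes))


#: default (bond type, rate) x maturity grid used by the preset scenarios
DEFAULT_RATE_GRID = (("health_impact", 0.03), ("corporate", 0.10))
DEFAULT_MATURITIES = (5, 10, 15)


def default_scheme_grid(price: float) -> tuple[PaymentScheme, ...]:
    """The six annuity schemes: {3% health-impact, 10% corporate} x {5, 10, 15} y."""
    return tuple(
        PaymentScheme(
            price=price, modality="annuity", n_payments=n, bond_rate=rate, bond_type=kind
        )
        for kind, rate in DEFAULT_RATE_GRID
        for n in DEFAULT_MATURITIES
    )


_EPI_KEYS = {f.name for f in dataclasses.fields(EpidemiologySpec)}
_ECON_KEYS = {f.name for f in dataclasses.fields(EconomicSpec)}
_SCHEME_KEYS = {"bond_type", "bond_rate", "n_payments", "modality"}
_TOP_KEYS = {
    "name",
    "epidemiology",
    "economics",
    "price",
    "durability_years",
    "truncation",
    "schemes",
}
_RATE_KEYS = {
    "prevalence_rate",
    "incidence_rate",
    "growth_rate",
    "uptake_fraction",
    "social_discount_rate",
    "inflation_rate",
    "bond_rate",
}


def _check_keys(mapping: dict, allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(
            f"unknown key(s) in {where}: {sorted(unknown)}; allowed: {sorted(allowed)}"
        )


def _check_rates(mapping: dict, where: str) -> None:
    for key, value in mapping.items():
        if key in _RATE_KEYS and isinstance(value, (int, float)) and value > 1:
            raise ConfigError(
                f"{where}.{key} = {value} looks like a percentage; "
                "rates must be fractions (write 0.03, not 3)"
            )


def _build(data: dict) -> ScenarioConfig:
    _check_keys(data, _TOP_KEYS, "config")
    _check_rates(data, "config")
    epi_raw = data.get("epidemiology") or {}
    econ_raw = data.get("economics") or {}
    _check_keys(epi_raw, _EPI_KEYS, "epidemiology")
    _check_keys(econ_raw, _ECON_KEYS, "economics")
    _check_rates(epi_raw, "epidemiology")
    _check_rates(econ_raw, "economics")
    try:
        epi = EpidemiologySpec(**epi_raw)
        econ = EconomicSpec(**{"budget_cap": 250e6, **econ_raw})
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc

    price = float(data.get("price", 1_000_000.0))
    schemes_raw = data.get("schemes")
    if schemes_raw is None:
        schemes = default_scheme_grid(price)
    else:
        schemes = []
        for idx, entry in enumerate(schemes_raw):
            _check_keys(entry, _SCHEME_KEYS, f"schemes[{idx}]")
            _check_rates(entry, f"schemes[{idx}]")
            try:
                schemes.append(PaymentScheme(price=price, **entry))
            except ValueError as exc:
                raise ConfigError(f"schemes[{idx}]: {exc}") from exc
    try:
        return ScenarioConfig(
            name=str(data.get("name", "default")),
            epidemiology=epi,
            economics=econ,
            price=price,
            durability_years=float(data.get("durability_years", 75.0)),
            truncation=TruncationPolicy(data.get("truncation", "window_only")),
            schemes=tuple(schemes),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> ScenarioConfig:
    """Load and validate a scenario config from a YAML file.

    An empty file yields the default scenario (with a warning); every
    omitted field takes its documented default.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if data is None:
        log.warning("config file %s is empty; using all defaults", path)
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    return _build(data)


def list_presets() -> list[str]:
    files = resources.files("abpsim") / "presets"
    return sorted(p.stem for p in files.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> ScenarioConfig:
    """Load a packaged preset scenario (``lca`` or ``dlbcl``)."""
    files = resources.files("abpsim") / "presets"
    candidate = files / f"{name}.yaml"
    if not candidate.is_file():
        raise ConfigError(
            f"unknown preset {name!r}; available presets: {list_presets()}"
        )
    data = yaml.safe_load(candidate.read_text())
    return _build(data)


def _config_to_dict(config: ScenarioConfig) -> dict:
    return {
        "name": config.name,
        "price": config.price,
        "durability_years": config.durability_years,
        "truncation": config.truncation.value,
        "epidemiology": {
            "population_size": config.epidemiology.population_size,
            "births_per_year": config.epidemiology.births_per_year,
            "prevalence_rate": config.epidemiology.prevalence_rate,
            "incidence_rate": config.epidemiology.incidence_rate,
            "incidence_basis": config.epidemiology.incidence_basis.value,
            "growth_rate": config.epidemiology.growth_rate,
            "backlog_spread_years": config.epidemiology.backlog_spread_years,
            "disease_duration_years": config.epidemiology.disease_duration_years,
            "uptake_fraction": config.epidemiology.uptake_fraction,
        },
        "economics": {
            "budget_cap": config.economics.budget_cap,
            "social_discount_rate": config.economics.social_discount_rate,
            "inflation_rate": config.economics.inflation_rate,
            "horizon_years": config.economics.horizon_years,
        },
        "schemes": [
            {
                "modality": s.modality,
                "bond_type": s.bond_type,
                "bond_rate": s.bond_rate,
                "n_payments": s.n_payments,
            }
            for s in config.schemes
        ],
    }


def dump_config(config: ScenarioConfig, path: str | Path) -> Path:
    """Write a config back to YAML such that loading it reproduces it."""
    path = Path(path)
    path.write_text(yaml.safe_dump(_config_to_dict(config), sort_keys=False))
    return path


def write_report(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a report table as deterministic CSV.

    Ratio columns are fixed to two decimals (matching the conventional
    table style for these reports); column order is preserved; output
    ends with a newline and is byte-identical across reruns.
    """
    path = Path(path)
    out = table.copy()
    for col in out.columns:
        if "ratio" in col or col.endswith("_sum"):
            out[col] = out[col].map(lambda v: f"{v:.2f}")
    csv = out.to_csv(index=False, lineterminator="\n")
    if not csv.endswith("\n"):
        csv += "\n"
    path.write_text(csv)
    return path
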