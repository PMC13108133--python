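"""Preset scenarios, parameter sweeps and the feasibility space.

The feasibility space is the range of epidemiological and financial
characteristics over which annuity-based payment satisfies all four
conditions. This module evaluates the packaged disease presets against
a scheme grid, sweeps model parameters over Cartesian grids, and
locates the largest bond rate at which the annuity scheme is still no
more costly to the payer than upfront payment.

Everything here is deterministic: identical configurations produce
identical tables.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .conditions import RATIO_TOL, condition2a, evaluate_all
from .config import ScenarioConfig, load_preset
from .epidemiology import classify_dominance, patient_flow
from .streams import PaymentScheme, build_abp_stream, build_upfront_stream
from .finance import discount_stream

__all__ = [
    "SweepSpec",
    "run_scenario",
    "run_preset",
    "sweep",
    "rate_threshold",
    "stream_table",
]

#: report columns, in deterministic output order
REPORT_COLUMNS = [
    "scenario",
    "dominance",
    "bond_type",
    "bond_rate",
    "maturity_years",
    "c1_upfront_exceeds_cap",
    "c1_abp_within_cap",
    "c1_pass",
    "c2a_ratio",
    "c2a_pass",
    "c2b_ratio",
    "c2b_pass",
    "c3_ratio",
    "c3_nominal_sum",
    "c3_pass",
    "c4_n_max",
    "c4_pass",
    "overall_feasible",
]

#: parameters a sweep may vary, mapped to how they modify a config
_SWEEP_PARAMS = (
    "bond_rate",
    "n_payments",
    "backlog_spread_years",
    "growth_rate",
    "price",
    "prevalence_rate",
    "incidence_rate",
)


@dataclass(frozen=True)
class SweepSpec:
    """Axes of a Cartesian parameter sweep.

    ``axes`` is an ordered sequence of ``(parameter, grid)`` pairs; each
    grid must be non-empty and strictly increasing.
    """

    axes: tuple[tuple[str, tuple[float, ...]], ...]

    def __init__(self, axes: Sequence[tuple[str, Sequence[float]]]):
        normalized = []
        for name, grid in axes:
            if name not in _SWEEP_PARAMS:
                raise ValueError(
                    f"unknown sweep parameter {name!r}; known: {_SWEEP_PARAMS}"
                )
            grid = tuple(grid)
            if not grid:
                raise ValueError(f"sweep grid for {name!r} is empty")
            if any(b <= a for a, b in zip(grid, grid[1:])):
                raise ValueError(f"sweep grid for {name!r} must be strictly increasing")
            normalized.append((name, grid))
        object.__setattr__(self, "axes", tuple(normalized))


def _apply_override(config: ScenarioConfig, name: str, value) -> ScenarioConfig:
    if name in ("bond_rate", "n_payments"):
        schemes = tuple(
            dataclasses.replace(
                s, **{name: int(value) if name == "n_payments" else float(value)}
            )
            for s in config.schemes
        )
        return config.with_schemes(schemes)
    if name == "price":
        schemes = tuple(dataclasses.replace(s, price=float(value)) for s in config.schemes)
        return dataclasses.replace(config, price=float(value), schemes=schemes)
    # epidemiology fields
    cast = int if name == "backlog_spread_years" else float
    epi = dataclasses.replace(config.epidemiology, **{name: cast(value)})
    return dataclasses.replace(config, epidemiology=epi)


def run_scenario(config: ScenarioConfig) -> pd.DataFrame:
    """Evaluate every scheme in a config; one report row per scheme."""
    flow = patient_flow(config.epidemiology, config.economics.horizon_years)
    dominance = classify_dominance(config.epidemiology).value
    rows = []
    for scheme in config.schemes:
        report = evaluate_all(
            flow,
            scheme,
            config.economics,
            config.durability_years,
            config.truncation,
        )
        rows.append(
            {
                "scenario": config.name,
                "dominance": dominance,
                "bond_type": scheme.bond_type,
                "bond_rate": scheme.bond_rate,
                "maturity_years": scheme.n_payments,
                **dataclasses.asdict(report),
            }
        )
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_preset(
    name: str, scheme_grid: Sequence[PaymentScheme] | None = None
) -> pd.DataFrame:
    """Evaluate a packaged preset against a scheme grid.

    With the default grid this yields six rows: bond rates {3%, 10%}
    crossed with maturities {5, 10, 15} years.
    """
    config = load_preset(name)
    if scheme_grid is not None:
        config = config.with_schemes(scheme_grid)
    return run_scenario(config)


def sweep(base: ScenarioConfig, spec: SweepSpec) -> pd.DataFrame:
    """Evaluate ``base`` at every point of the Cartesian grid in ``spec``.

    Returns long-format records: one row per (grid point, scheme), the
    axis values as leading columns, rows ordered by axis order.
    """
    names = [name for name, _ in spec.axes]
    grids = [grid for _, grid in spec.axes]
    frames = []
    for point in itertools.product(*grids):
        config = base
        for name, value in zip(names, point):
            config = _apply_override(config, name, value)
        frame = run_scenario(config)
        for name, value in reversed(list(zip(names, point))):
            # scheme-level axes (bond_rate) already appear as report
            # columns and carry the overridden value
            if name not in frame.columns:
                frame.insert(0, name, value)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def rate_threshold(
    base: ScenarioConfig,
    social_discount_rate: float,
    rate_grid: Sequence[float],
) -> float | None:
    """Largest bond rate in the grid at which NPV cost-equivalence holds.

    Evaluates the condition-2a ratio at each grid rate under the base
    config's truncation policy and returns the largest rate whose ratio
    is no greater than 1, or ``None`` if no rate passes. Under
    full-ledger accounting the threshold equals the social discount
    rate whenever the grid contains it.
    """
    grid = tuple(rate_grid)
    if not grid:
        raise ValueError("rate_grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("rate_grid must be strictly increasing")
    flow = patient_flow(base.epidemiology, base.economics.horizon_years)
    upfront = build_upfront_stream(flow, base.price)
    n = base.schemes[0].n_payments if base.schemes else 10
    passing = []
    for rate in grid:
        scheme = PaymentScheme(
            price=base.price, modality="annuity", n_payments=n, bond_rate=rate
        )
        abp = build_abp_stream(flow, scheme, base.truncation)
        if condition2a(upfront, abp, social_discount_rate) <= 1.0 + RATIO_TOL:
            passing.append(rate)
    return max(passing) if passing else None


def stream_table(config: ScenarioConfig) -> pd.DataFrame:
    """Tidy per-year budget-impact table for the upfront and all ABP schemes.

    Columns: year, scheme_label, basis, value — nominal and discounted
    rows for each stream, ready for CSV export or plotting.
    """
    flow = patient_flow(config.epidemiology, config.economics.horizon_years)
    r = config.economics.social_discount_rate
    streams = [build_upfront_stream(flow, config.price)]
    streams += [build_abp_stream(flow, s, config.truncation) for s in config.schemes]
    rows = []
    for stream in streams:
        for version in (stream, discount_stream(stream, r)):
            for year, value in enumerate(np.asarray(version.values)):
                rows.append(
                    {
                        "year": year,
                        "scheme_label": version.scheme_label,
                        "basis": version.basis,
                        "value": float(value),
                    }
                )
    return pd.DataFrame(rows, columns=["year", "scheme_label", "basis", "value"])
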