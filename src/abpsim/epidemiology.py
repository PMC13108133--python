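"""Patient-flow projection from disease and population parameters.

The treated population over a horizon of ``T`` years has two parts: a
prevalent *backlog* of existing patients waiting when the therapy
launches, spread equally over the first ``m`` years, and an *incident*
flow of new cases each year, growing at a demographic factor ``g``.
A disease is prevalence-dominant when the backlog exceeds the first-year
incident count (prev/inc > 1), incidence-dominant otherwise.

Counts are expected values and may be fractional; the model is
deterministic.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EpidemiologySpec",
    "TreatedFlow",
    "Dominance",
    "patient_flow",
    "classify_dominance",
]

# Belgium-like reference population; the condition ratios that drive the
# feasibility verdicts are invariant to this scale (only absolute euro
# figures against the budget cap depend on it).
DEFAULT_POPULATION = 11_500_000
DEFAULT_BIRTHS_PER_YEAR = 120_000


class IncidenceBasis(str, enum.Enum):
    """Denominator population for the incidence rate."""

    POPULATION = "population"
    BIRTHS = "births"


class Dominance(str, enum.Enum):
    PREVALENCE_DOMINANT = "prevalence_dominant"
    INCIDENCE_DOMINANT = "incidence_dominant"


@dataclass(frozen=True)
class EpidemiologySpec:
    """Disease/population parameters generating the treated-patient flow.

    Defaults describe a rare inherited retinal dystrophy treated by a
    one-time gene therapy: prevalence 1/10,700 of the population,
    incidence 1/750,000 newborns, disease duration ~70 years.
    """

    population_size: float = DEFAULT_POPULATION
    births_per_year: float = DEFAULT_BIRTHS_PER_YEAR
    prevalence_rate: float = 1 / 10_700
    incidence_rate: float = 1 / 750_000
    incidence_basis: IncidenceBasis = IncidenceBasis.BIRTHS
    growth_rate: float = 0.0
    backlog_spread_years: int = 1
    disease_duration_years: float | None = 70.0
    uptake_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.population_size <= 0 or self.births_per_year < 0:
            raise ValueError("population_size must be > 0 and births_per_year >= 0")
        for name in ("prevalence_rate", "incidence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not -0.05 <= self.growth_rate <= 0.05:
            raise ValueError(f"growth_rate must be in [-0.05, 0.05], got {self.growth_rate}")
        if self.backlog_spread_years < 1:
            raise ValueError("backlog_spread_years must be >= 1")
        if not 0.0 < self.uptake_fraction <= 1.0:
            raise ValueError("uptake_fraction must be in (0, 1]")
        object.__setattr__(self, "incidence_basis", IncidenceBasis(self.incidence_basis))
        self._check_consistency()

    def _check_consistency(self) -> None:
        # prevalence ~ incidence x disease duration; a mismatch is suspicious
        # but legitimate (e.g. uptake folded into one rate), so warn only.
        if self.disease_duration_years is None or self.incidence_rate == 0:
            return
        implied = self.incidence_rate * self.disease_duration_years
        if implied == 0 and self.prevalence_rate == 0:
            return
        ref = max(self.prevalence_rate, implied)
        if abs(self.prevalence_rate - implied) > 0.10 * ref:
            warnings.warn(
                "prevalence_rate "
                f"({self.prevalence_rate:.3g}) differs from incidence_rate x "
                f"disease_duration ({implied:.3g}) by more than 10%",
                stacklevel=3,
            )

    @property
    def prevalent_count(self) -> float:
        """Backlog patient count at launch (after uptake)."""
        return self.prevalence_rate * self.population_size * self.uptake_fraction

    @property
    def incident_count0(self) -> float:
        """New treated cases in year 0 (after uptake)."""
        basis = (
            self.births_per_year
            if self.incidence_basis is IncidenceBasis.BIRTHS
            else self.population_size
        )
        return self.incidence_rate * basis * self.uptake_fraction


@dataclass(frozen=True)
class TreatedFlow:
    """Yearly counts of patients initiating therapy over the horizon."""

    backlog_component: np.ndarray
    incident_component: np.ndarray
    initiated: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        backlog = np.asarray(self.backlog_component, dtype=float)
        incident = np.asarray(self.incident_component, dtype=float)
        if backlog.shape != incident.shape:
            raise ValueError("component vectors must have equal length")
        if (backlog < 0).any() or (incident < 0).any():
            raise ValueError("patient counts must be non-negative")
        object.__setattr__(self, "backlog_component", backlog)
        object.__setattr__(self, "incident_component", incident)
        object.__setattr__(self, "initiated", backlog + incident)

    @property
    def horizon_years(self) -> int:
        return int(self.initiated.size)

    @property
    def total_patients(self) -> float:
        return float(self.initiated.sum())


def patient_flow(spec: EpidemiologySpec, horizon: int) -> TreatedFlow:
    """Project the yearly flow of newly treated patients over ``horizon`` years.

    The prevalent backlog is split equally over years ``0..m-1``; the
    incident flow in year ``t`` is ``inc0 * (1+g)**t``.
    """
    horizon = int(horizon)
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    m = spec.backlog_spread_years
    if m > horizon:
        raise ValueError(
            f"backlog_spread_years ({m}) exceeds horizon ({horizon})"
        )
    backlog = np.zeros(horizon)
    backlog[:m] = spec.prevalent_count / m
    t = np.arange(horizon)
    incident = spec.incident_count0 * (1.0 + spec.growth_rate) ** t
    return TreatedFlow(backlog_component=backlog, incident_component=incident)


def classify_dominance(spec: EpidemiologySpec) -> Dominance:
    """Classify a disease as prevalence- or incidence-dominant.

    Prevalence-dominant iff backlog count / first-year incident count > 1;
    a ratio of exactly 1 is incidence-dominant.
    """
    inc0 = spec.incident_count0
    prev = spec.prevalent_count
    if inc0 == 0:
        if prev == 0:
            raise ValueError("cannot classify: both prevalence and incidence are zero")
        return Dominance.PREVALENCE_DOMINANT
    ratio = prev / inc0
    if math.isnan(ratio):
        raise ValueError("dominance ratio is undefined")
    return (
        Dominance.PREVALENCE_DOMINANT if ratio > 1 else Dominance.INCIDENCE_DOMINANT
    )
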