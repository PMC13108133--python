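"""Yearly payer budget-impact streams under upfront and annuity funding.

Under upfront payment every patient costs the full price in the year of
treatment. Under an annuity-based payment (ABP) scheme of duration ``n``
priced at bond rate ``i``, every patient treated in year ``s`` owes the
annuity ``A`` in years ``s .. s+n-1`` (per-patient ledger semantics), so
the payer's budget impact in year ``t`` is ``A`` times the number of
patients treated in the window ``t-(n-1) .. t``.

Payments owed past the budget horizon are handled by a truncation
policy: ``window_only`` keeps the payer's 25-year budget window and
drops later payments from the stream; ``full_ledger`` extends the
stream until the last cohort has paid in full.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from .finance import annuity_due

__all__ = [
    "CashflowStream",
    "PaymentScheme",
    "TruncationPolicy",
    "build_upfront_stream",
    "build_abp_stream",
    "apply_inflation",
]


class TruncationPolicy(str, enum.Enum):
    """How annuity payments owed beyond the horizon are treated."""

    WINDOW_ONLY = "window_only"
    FULL_LEDGER = "full_ledger"


@dataclass(frozen=True)
class PaymentScheme:
    """A funding arrangement for the therapy price.

    ``modality`` is ``"upfront"`` (single lump sum) or ``"annuity"``
    (n yearly annuity-due payments at ``bond_rate``). ``bond_type`` is a
    free label, conventionally ``"health_impact"`` (government-issued,
    low rate) or ``"corporate"`` (manufacturer-issued, high rate).
    """

    price: float
    modality: str = "annuity"
    n_payments: int = 1
    bond_rate: float = 0.0
    bond_type: str = "health_impact"

    def __post_init__(self) -> None:
        if self.price <= 0:
            raise ValueError(f"price must be > 0, got {self.price}")
        if self.modality not in ("upfront", "annuity"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.n_payments < 1:
            raise ValueError("n_payments must be >= 1")
        if self.bond_rate < 0:
            raise ValueError("bond_rate must be >= 0")

    @property
    def label(self) -> str:
        if self.modality == "upfront":
            return "upfront"
        return f"{self.bond_type}_{self.bond_rate:.0%}_{self.n_payments}y"


@dataclass(frozen=True)
class CashflowStream:
    """A yearly payer budget-impact series, time-indexed from year 0."""

    values: np.ndarray
    basis: str = "nominal"
    scheme_label: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("values must be a 1-D yearly vector")
        if (values < 0).any():
            raise ValueError("budget-impact values must be non-negative")
        if self.basis not in ("nominal", "discounted"):
            raise ValueError(f"unknown basis {self.basis!r}")
        object.__setattr__(self, "values", values)

    @property
    def horizon_years(self) -> int:
        return int(self.values.size)

    @property
    def max_yearly(self) -> float:
        return float(self.values.max()) if self.values.size else 0.0


def build_upfront_stream(flow, price: float) -> CashflowStream:
    """Budget impact when every patient is paid for in the treatment year."""
    if price <= 0:
        raise ValueError(f"price must be > 0, got {price}")
    return CashflowStream(
        values=price * flow.initiated, basis="nominal", scheme_label="upfront"
    )


def build_abp_stream(
    flow,
    scheme: PaymentScheme,
    policy: TruncationPolicy = TruncationPolicy.WINDOW_ONLY,
) -> CashflowStream:
    """Budget impact under an annuity-based payment scheme.

    Every patient treated in year ``s`` owes ``scheme``'s annuity in
    years ``s .. s+n-1``; yearly totals follow by superposition over
    cohorts. Under ``window_only`` the stream keeps the flow's horizon
    and payments falling beyond it are dropped (they remain owed in the
    manufacturer's contract view); under ``full_ledger`` the stream is
    extended by ``n-1`` years so every payment appears.
    """
    if scheme.modality != "annuity":
        raise ValueError("build_abp_stream requires an annuity-modality scheme")
    policy = TruncationPolicy(policy)
    n = scheme.n_payments
    horizon = flow.horizon_years
    if policy is TruncationPolicy.WINDOW_ONLY and n > horizon:
        warnings.warn(
            f"annuity duration ({n}) exceeds the budget horizon ({horizon}); "
            "later payments are dropped from the payer stream",
            stacklevel=2,
        )
    schedule = annuity_due(scheme.price, scheme.bond_rate, n)
    # rolling window sum over the last n cohorts, including year t itself
    totals = np.convolve(flow.initiated, np.ones(n))  # length horizon + n - 1
    if policy is TruncationPolicy.WINDOW_ONLY:
        totals = totals[:horizon]
    return CashflowStream(
        values=schedule.annuity_amount * totals,
        basis="nominal",
        scheme_label=scheme.label,
    )


def apply_inflation(stream: CashflowStream, inflation_rate: float) -> CashflowStream:
    """Inflate a nominal stream by a constant yearly rate (year 0 unchanged)."""
    if stream.basis != "nominal":
        raise ValueError("inflation applies to nominal streams only")
    if inflation_rate == 0:
        return stream
    t = np.arange(stream.values.size)
    return CashflowStream(
        values=stream.values * (1.0 + inflation_rate) ** t,
        basis="nominal",
        scheme_label=stream.scheme_label,
    )
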