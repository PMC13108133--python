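"""The four feasibility conditions for annuity-based payment schemes.

A scheme is acceptable to both payer and manufacturer when:

1. the discounted upfront budget impact exceeds the payer's yearly cap
   ``BI_max`` in some year while the annuity stream stays within it
   (otherwise either spreading is unnecessary or it does not help);
2a. the net present value of the annuity stream at the social discount
   rate ``r`` is no greater than that of the upfront stream;
2b. the maximum discounted yearly budget impact under annuities is no
   greater than under upfront payment;
3. the annuity schedule compensates the manufacturer: its NPV at the
   bond rate matches the principal (the defining identity of the
   annuity due), with the undiscounted premium ``n*A/P`` reported as a
   secondary audit metric;
4. the number of annuities does not exceed the measured durability of
   the therapy's effect, in whole years.

Ratios exactly equal to 1 count as passing ("no greater than").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .finance import annuity_due, discount_stream, npv
from .streams import (
    CashflowStream,
    PaymentScheme,
    TruncationPolicy,
    apply_inflation,
    build_abp_stream,
    build_upfront_stream,
)

__all__ = [
    "EconomicSpec",
    "ConditionReport",
    "condition1",
    "condition2a",
    "condition2b",
    "condition3",
    "condition4",
    "evaluate_all",
]

#: tolerance for "no greater than 1" ratio comparisons
RATIO_TOL = 1e-9


@dataclass(frozen=True)
class EconomicSpec:
    """Payer-side economic parameters.

    ``budget_cap`` is the maximum tolerable net yearly budget impact
    ``BI_max`` for the indication, in currency per year; it is compared
    against discounted streams as a fixed yearly amount.
    """

    budget_cap: float
    social_discount_rate: float = 0.03
    inflation_rate: float = 0.0
    horizon_years: int = 25

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ValueError("horizon_years must be >= 1")
        if self.budget_cap <= 0:
            raise ValueError("budget_cap must be > 0")
        if not 0.0 <= self.social_discount_rate <= 0.15:
            raise ValueError(
                f"social_discount_rate must be in [0, 0.15], got {self.social_discount_rate}"
            )


@dataclass(frozen=True)
class ConditionReport:
    """Pass/fail flags and ratio metrics for the four conditions."""

    c1_upfront_exceeds_cap: bool
    c1_abp_within_cap: bool
    c1_pass: bool
    c2a_ratio: float
    c2a_pass: bool
    c2b_ratio: float
    c2b_pass: bool
    c3_ratio: float
    c3_metric: str
    c3_nominal_sum: float
    c3_pass: bool
    c4_n_max: int
    c4_pass: bool
    overall_feasible: bool

    def __post_init__(self) -> None:
        for name in ("c2a_ratio", "c2b_ratio", "c3_ratio", "c3_nominal_sum"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        expected = self.c1_pass and self.c2a_pass and self.c2b_pass and self.c3_pass and self.c4_pass
        if self.overall_feasible != expected:
            raise ValueError("overall_feasible must be the conjunction of the pass flags")


def _require_basis(stream: CashflowStream, basis: str, what: str) -> None:
    if stream.basis != basis:
        raise ValueError(f"{what} requires {basis} streams, got {stream.basis!r}")


def condition1(
    upfront: CashflowStream, abp: CashflowStream, econ: EconomicSpec
) -> tuple[bool, bool]:
    """Budget-cap screen on discounted streams.

    Returns ``(upfront exceeds BI_max in some year, annuity stream stays
    within BI_max every year)``; the condition passes when both hold.
    """
    _require_basis(upfront, "discounted", "condition1")
    _require_basis(abp, "discounted", "condition1")
    cap = econ.budget_cap
    return upfront.max_yearly > cap, abp.max_yearly <= cap


def condition2a(
    upfront: CashflowStream, abp: CashflowStream, social_discount_rate: float
) -> float:
    """NPV cost-equivalence ratio ``NPV(ABP, r) / NPV(upfront, r)``.

    Takes nominal streams and discounts internally; passes when <= 1.
    """
    _require_basis(upfront, "nominal", "condition2a")
    _require_basis(abp, "nominal", "condition2a")
    denom = npv(upfront, social_discount_rate)
    if denom == 0:
        raise ValueError("upfront stream has zero NPV; ratio undefined")
    return npv(abp, social_discount_rate) / denom


def condition2b(upfront: CashflowStream, abp: CashflowStream) -> float:
    """Ratio of maximum discounted yearly budget impacts, BI_A,Max / BI_U,Max."""
    _require_basis(upfront, "discounted", "condition2b")
    _require_basis(abp, "discounted", "condition2b")
    denom = upfront.max_yearly
    if denom == 0:
        raise ValueError("upfront stream has zero maximum; ratio undefined")
    return abp.max_yearly / denom


def condition3(scheme: PaymentScheme, metric: str = "npv_at_bond_rate") -> float:
    """Manufacturer-compensation ratio for an annuity scheme.

    ``npv_at_bond_rate``: NPV of the schedule at the bond rate over the
    principal — equal to 1 by construction of the annuity due, computed
    and reported for audit. ``nominal_sum``: the undiscounted premium
    ``n*A/P`` the payer concedes. Passes when the ratio is >= 1.
    """
    if scheme.modality != "annuity":
        raise ValueError("condition3 requires an annuity-modality scheme")
    schedule = annuity_due(scheme.price, scheme.bond_rate, scheme.n_payments)
    if metric == "npv_at_bond_rate":
        return npv(schedule.payments, scheme.bond_rate) / scheme.price
    if metric == "nominal_sum":
        return schedule.nominal_total / scheme.price
    raise ValueError(f"unknown condition-3 metric {metric!r}")


def condition4(scheme: PaymentScheme, durability_years: float) -> bool:
    """Annuity count must not exceed the durability of effect in whole years."""
    if durability_years <= 0:
        raise ValueError("durability_years must be > 0")
    return scheme.n_payments <= math.floor(durability_years)


def evaluate_all(
    flow,
    scheme: PaymentScheme,
    econ: EconomicSpec,
    durability_years: float,
    policy: TruncationPolicy = TruncationPolicy.WINDOW_ONLY,
    c3_metric: str = "npv_at_bond_rate",
) -> ConditionReport:
    """Build both streams for a flow/scheme pair and evaluate all conditions.

    Streams are built nominal, inflation-adjusted at the economic spec's
    rate, then discounted at the social rate for conditions 1 and 2b;
    condition 2a discounts the (inflated) nominal streams itself.
    """
    if flow.horizon_years != econ.horizon_years:
        raise ValueError(
            f"flow horizon ({flow.horizon_years}) does not match economic "
            f"horizon ({econ.horizon_years})"
        )
    r = econ.social_discount_rate
    upfront_nom = apply_inflation(
        build_upfront_stream(flow, scheme.price), econ.inflation_rate
    )
    abp_nom = apply_inflation(build_abp_stream(flow, scheme, policy), econ.inflation_rate)
    upfront_disc = discount_stream(upfront_nom, r)
    abp_disc = discount_stream(abp_nom, r)

    c1_up, c1_abp = condition1(upfront_disc, abp_disc, econ)
    c1_pass = c1_up and c1_abp
    c2a = condition2a(upfront_nom, abp_nom, r)
    c2a_pass = c2a <= 1.0 + RATIO_TOL
    c2b = condition2b(upfront_disc, abp_disc)
    c2b_pass = c2b <= 1.0 + RATIO_TOL
    c3 = condition3(scheme, c3_metric)
    c3_nominal = condition3(scheme, "nominal_sum")
    c3_pass = c3 >= 1.0 - RATIO_TOL
    c4_n_max = math.floor(durability_years)
    c4_pass = condition4(scheme, durability_years)
    return ConditionReport(
        c1_upfront_exceeds_cap=c1_up,
        c1_abp_within_cap=c1_abp,
        c1_pass=c1_pass,
        c2a_ratio=c2a,
        c2a_pass=c2a_pass,
        c2b_ratio=c2b,
        c2b_pass=c2b_pass,
        c3_ratio=c3,
        c3_metric=c3_metric,
        c3_nominal_sum=c3_nominal,
        c3_pass=c3_pass,
        c4_n_max=c4_n_max,
        c4_pass=c4_pass,
        overall_feasible=c1_pass and c2a_pass and c2b_pass and c3_pass and c4_pass,
    )
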