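"""Annuity-due pricing and net-present-value arithmetic.

This module holds the financial core of the simulator: pricing a
one-time therapy of negotiated principal ``P`` as an annuity due (equal
payments at the *beginning* of each of ``n`` yearly periods, priced at a
bond rate ``i``), and discounting yearly cashflow streams at a social
rate of time preference ``r``.

The annuity due ``A`` is the unique constant payment whose net present
value at the bond rate equals the principal::

    A = i * P / (1 - (1 + i)**-n) * 1 / (1 + i)        (i > 0)
    A = P / n                                           (i = 0 limit)

Two exact algebraic identities anchor the implementation and its tests:
``A == P`` when ``n == 1`` for any rate, and ``NPV(schedule, i) == P``
for every valid schedule.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["AnnuitySchedule", "annuity_due", "npv", "discount_stream"]


@dataclass(frozen=True)
class AnnuitySchedule:
    """An annuity-due repayment schedule for a single treated patient.

    Attributes
    ----------
    principal
        Negotiated upfront price ``P`` (currency units, > 0).
    bond_rate
        Yearly financing rate ``i`` as a fraction (>= 0).
    n_payments
        Number of yearly payments ``n`` (>= 1).
    annuity_amount
        The constant payment ``A`` due at the beginning of each year.
    """

    principal: float
    bond_rate: float
    n_payments: int
    annuity_amount: float

    def __post_init__(self) -> None:
        if self.principal <= 0:
            raise ValueError(f"principal must be > 0, got {self.principal}")
        if self.n_payments < 1:
            raise ValueError(f"n_payments must be >= 1, got {self.n_payments}")
        if self.bond_rate < 0:
            raise ValueError(f"bond_rate must be >= 0, got {self.bond_rate}")
        if self.annuity_amount <= 0:
            raise ValueError("annuity_amount must be > 0")

    @property
    def payment_offsets(self) -> np.ndarray:
        """Years from the treatment year at which payments fall: 0..n-1."""
        return np.arange(self.n_payments)

    @property
    def payments(self) -> np.ndarray:
        """The payment vector, time-indexed from the treatment year."""
        return np.full(self.n_payments, self.annuity_amount)

    @property
    def nominal_total(self) -> float:
        """Undiscounted sum of all payments, ``n * A`` (>= P, = P iff i = 0)."""
        return self.n_payments * self.annuity_amount


def annuity_due(principal: float, bond_rate: float, n_payments: int) -> AnnuitySchedule:
    """Price a principal as an annuity due over ``n_payments`` years.

    Parameters
    ----------
    principal
        Upfront price ``P`` of the therapy, > 0.
    bond_rate
        Yearly bond rate ``i`` as a fraction (e.g. ``0.03``), >= 0.
    n_payments
        Number of yearly payments, >= 1.

    Returns
    -------
    AnnuitySchedule
        Schedule whose NPV at ``bond_rate`` equals ``principal``.

    Examples
    --------
    >>> round(annuity_due(1_000_000, 0.03, 5).annuity_amount)
    211995
    >>> round(annuity_due(1_000_000, 0.10, 5).annuity_amount)
    239816
    """
    if principal <= 0:
        raise ValueError(f"principal must be > 0, got {principal}")
    if n_payments < 1:
        raise ValueError(f"n_payments must be >= 1, got {n_payments}")
    if bond_rate < 0:
        raise ValueError(f"bond_rate must be >= 0, got {bond_rate}")
    n_payments = int(n_payments)

    if n_payments == 1:
        # a single payment due immediately is the principal itself, exactly
        amount = float(principal)
    elif bond_rate == 0 or (1.0 + bond_rate) ** -n_payments == 1.0:
        # analytic i -> 0 limit; the second clause catches rates so small
        # that the discount factor underflows to 1 in floating point
        amount = principal / n_payments
    else:
        i = bond_rate
        # 1 - (1+i)^-n via expm1/log1p: stable for rates near zero
        denom = -math.expm1(-n_payments * math.log1p(i))
        amount = i * principal / denom / (1.0 + i)
    return AnnuitySchedule(
        principal=float(principal),
        bond_rate=float(bond_rate),
        n_payments=n_payments,
        annuity_amount=float(amount),
    )


def _values_of(stream) -> np.ndarray:
    """Accept a CashflowStream, an AnnuitySchedule, or a plain vector."""
    if hasattr(stream, "values"):
        return np.asarray(stream.values, dtype=float)
    if isinstance(stream, AnnuitySchedule):
        return stream.payments
    return np.asarray(stream, dtype=float)


def npv(stream, rate: float) -> float:
    """Net present value of a yearly stream, time-indexed from year 0.

    The first element is the current year (not discounted); element ``t``
    is weighted by ``(1 + rate)**-t``. An empty stream has NPV zero.
    """
    if rate <= -1:
        raise ValueError(f"rate must be > -1, got {rate}")
    values = _values_of(stream)
    if values.size == 0:
        return 0.0
    t = np.arange(values.size)
    return float(np.sum(values * (1.0 + rate) ** -t))


def discount_stream(stream, rate: float):
    """Discount a nominal yearly stream elementwise at ``rate``.

    Returns a stream of the same type with ``values[t] / (1+rate)**t`` and
    basis ``"discounted"``. Discounting an already-discounted stream raises,
    which guards against silent double discounting.
    """
    if rate <= -1:
        raise ValueError(f"rate must be > -1, got {rate}")
    if getattr(stream, "basis", "nominal") == "discounted":
        raise ValueError("stream is already discounted; refusing to discount twice")
    values = _values_of(stream)
    t = np.arange(values.size)
    discounted = values * (1.0 + rate) ** -t
    if dataclasses.is_dataclass(stream):
        return dataclasses.replace(stream, values=discounted, basis="discounted")
    return discounted
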