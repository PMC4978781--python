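"""Numerical demonstrations of the 3PL model's lack of identifiability.

Two families of observationally equivalent reparameterizations are provided.

First, in the Maris form of the model with ``a = 1`` the success probability
is ``(vartheta + delta) / (vartheta + beta)``; adding a constant to every
person's ``vartheta`` while subtracting it from every item's ``beta`` and
``delta`` changes all parameters but no response probability.

Second, when every person shares the same ability ``theta``, scaling the
complement of the lower asymptote, ``gamma = 1 - c``, by a factor
``kappa <= 1`` can be exactly compensated by adjusting the item's difficulty,
its discrimination, or the common ability — the trade-off curves behind the
classic demonstration that the guessing parameter is not identifiable in this
case. Writing ``E = exp(a * (theta - b))``, the compensating values are::

    b*     = theta - ln(kappa * (1 + E) - 1) / a
    a*     = ln(kappa * (1 + E) - 1) / (theta - b)
    theta* = b + ln(kappa * (1 + E) - 1) / a

each valid only for ``kappa`` above a lower bound: ``1 - Psi`` (with
``Psi = logistic(a * (theta - b))``) for the ``b`` and ``theta`` trade-offs,
and ``2 * (1 - Psi)`` for the ``a`` trade-off, whose compensated slope must
additionally stay positive (requiring ``theta > b``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import Item3PL, logistic

__all__ = [
    "MarisParams",
    "TradeoffSpec",
    "InfeasibleTradeoffError",
    "maris_shift",
    "kappa_admissible_range",
    "compensating_tradeoff",
    "tradeoff_curves",
    "eta_3pl",
]

_TARGETS = ("b", "a", "theta")


class InfeasibleTradeoffError(ValueError):
    """Raised when a requested trade-off lies outside its admissible range."""


@dataclass(frozen=True)
class MarisParams:
    """Maris-form parameters: ``vartheta = exp(theta)``, ``beta_m = exp(b)``,
    ``delta = c * exp(b)``; success probability
    ``(vartheta + delta) / (vartheta + beta_m)``."""

    vartheta: float
    beta_m: float
    delta: float

    def __post_init__(self) -> None:
        if self.vartheta <= 0:
            raise ValueError(f"vartheta must be > 0, got {self.vartheta}")
        if self.beta_m <= 0:
            raise ValueError(f"beta_m must be > 0, got {self.beta_m}")
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if not self.delta < self.beta_m:
            raise ValueError(
                f"delta must be < beta_m (c < 1), got delta={self.delta}, "
                f"beta_m={self.beta_m}"
            )

    def probability(self) -> float:
        return (self.vartheta + self.delta) / (self.vartheta + self.beta_m)


@dataclass(frozen=True)
class TradeoffSpec:
    """An item, a common ability shared by all persons, and the factor
    ``kappa`` scaling ``gamma = 1 - c``."""

    item: Item3PL
    theta: float
    kappa: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        if not (0.0 < self.kappa <= 1.0):
            raise ValueError(f"kappa must lie in (0, 1], got {self.kappa}")


def maris_shift(params: MarisParams, constant: float) -> MarisParams:
    """Shift Maris-form parameters by a constant without changing the
    success probability: ``vartheta + s``, ``beta_m - s``, ``delta - s``.

    Raises a domain error naming the first violated bound if the shifted
    values leave the admissible region.
    """
    if not isinstance(params, MarisParams):
        params = MarisParams(*params)
    s = float(constant)
    if params.vartheta + s <= 0:
        raise ValueError(
            f"shift {s} drives vartheta to {params.vartheta + s} <= 0"
        )
    if params.delta - s <= 0:
        raise ValueError(f"shift {s} drives delta to {params.delta - s} <= 0")
    if params.beta_m - s <= 0:
        raise ValueError(f"shift {s} drives beta_m to {params.beta_m - s} <= 0")
    return MarisParams(params.vartheta + s, params.beta_m - s, params.delta - s)


def eta_3pl(gamma: float, a: float, b: float, theta: float) -> float:
    """Failure probability ``eta = 1 - pi = gamma / (1 + exp(a*(theta - b)))``."""
    return gamma / (1.0 + np.exp(a * (theta - b)))


def kappa_admissible_range(item: Item3PL, theta: float, target: str):
    """Admissible interval ``(lower, 1]`` of the gamma-scaling factor kappa.

    For ``target`` ``'b'`` or ``'theta'`` the lower bound is ``1 - Psi``;
    for ``'a'`` (where the compensated slope must stay positive) it is
    ``2 * (1 - Psi)`` and ``theta > b`` is required.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}, got {target!r}")
    if not isinstance(item, Item3PL):
        item = Item3PL(*item)
    psi = logistic(item.a * (theta - item.b))
    if target == "a":
        if theta <= item.b:
            raise InfeasibleTradeoffError(
                "the discrimination trade-off requires theta > b "
                f"(got theta={theta}, b={item.b})"
            )
        return (2.0 * (1.0 - psi), 1.0)
    return (1.0 - psi, 1.0)


def _log_argument(item: Item3PL, theta: float, kappa: float) -> float:
    """``kappa * (1 + exp(a*(theta-b))) - 1``, the argument of the trade-off log."""
    return kappa * (1.0 + np.exp(item.a * (theta - item.b))) - 1.0


def compensating_tradeoff(
    spec: TradeoffSpec, target: str, allow_negative_a: bool = False
) -> float:
    """Adjusted parameter value compensating the scaling of ``gamma`` by kappa.

    Returns the value of ``b*``, ``a*`` or ``theta*`` such that, paired with
    ``gamma* = kappa * gamma``, the failure probability ``eta`` of every
    response is unchanged. ``kappa = 1`` returns the original value.

    ``allow_negative_a`` lifts the positivity requirement on the compensated
    slope (used only to draw the negative branch of the trade-off curve) so
    that only ``kappa > 1 - Psi`` is required for ``target='a'``.
    """
    if target not in _TARGETS:
        raise ValueError(f"target must be one of {_TARGETS}, got {target!r}")
    item, theta, kappa = spec.item, spec.theta, spec.kappa
    arg = _log_argument(item, theta, kappa)
    if arg <= 0:
        psi = logistic(item.a * (theta - item.b))
        raise InfeasibleTradeoffError(
            f"kappa={kappa} is at or below the admissibility bound "
            f"1 - Psi = {1.0 - psi:.6g}; the trade-off log argument is non-positive"
        )
    if target == "b":
        return float(theta - np.log(arg) / item.a)
    if target == "theta":
        return float(item.b + np.log(arg) / item.a)
    # target == "a"
    if theta == item.b:
        raise InfeasibleTradeoffError(
            "the discrimination trade-off is undefined at theta == b"
        )
    a_star = float(np.log(arg) / (theta - item.b))
    if a_star <= 0 and not allow_negative_a:
        lower, _ = kappa_admissible_range(item, theta, "a")
        raise InfeasibleTradeoffError(
            f"kappa={kappa} yields a non-positive compensated slope "
            f"{a_star:.6g}; require kappa > {lower:.6g} (or allow_negative_a)"
        )
    return a_star


def tradeoff_curves(
    item: Item3PL, theta: float, kappa_grid, include_negative_a: bool = False
) -> pd.DataFrame:
    """Table of compensated parameter values over a grid of kappa.

    Returns columns ``kappa, b_star, a_star, theta_star``. Grid points outside
    a target's admissible range yield missing values for that column rather
    than errors, so full-grid curves can be produced. By default ``a_star`` is
    reported only where positive (defined above ``2 * (1 - Psi)``);
    ``include_negative_a=True`` additionally emits the negative branch down to
    the common ``1 - Psi`` asymptote (drawn dashed in trade-off plots).
    """
    if not isinstance(item, Item3PL):
        item = Item3PL(*item)
    kappa_grid = np.asarray(kappa_grid, dtype=float)
    if kappa_grid.size == 0:
        raise ValueError("kappa grid must be nonempty")
    rows = []
    for kappa in kappa_grid:
        row = {"kappa": kappa, "b_star": np.nan, "a_star": np.nan, "theta_star": np.nan}
        if 0.0 < kappa <= 1.0 and _log_argument(item, theta, kappa) > 0:
            spec = TradeoffSpec(item, theta, kappa)
            row["b_star"] = compensating_tradeoff(spec, "b")
            row["theta_star"] = compensating_tradeoff(spec, "theta")
            if theta != item.b:
                a_star = compensating_tradeoff(spec, "a", allow_negative_a=True)
                if a_star > 0 or include_negative_a:
                    row["a_star"] = a_star
        rows.append(row)
    return pd.DataFrame(rows)
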