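"""The 3PL response model, alternate parameterizations, and the Bernoulli likelihood.

The three-parameter logistic (3PL) model gives the probability of a correct
response by a person with ability ``theta`` on an item with discrimination
``a``, difficulty ``b`` and lower asymptote ``c``::

    p(theta; a, b, c) = c + (1 - c) * logistic(a * (theta - b))

Two alternate parameterizations with a bijective relation to the standard one
are provided: the slope-intercept form ``alpha * theta + beta`` (with
``alpha = a``, ``beta = -a * b``) and, for the Rasch submodel (``a = 1``,
``c = 0``), the multiplicative form ``vartheta / (vartheta + beta_m)`` with
``theta = ln(vartheta)``, ``b = ln(beta_m)``.

Ability values are plain reals; which calibration's identifiability
restrictions define their scale is metadata carried by the surrounding tables,
not by the type system.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Item3PL",
    "ItemSlopeIntercept",
    "RaschMultiplicativeParams",
    "ResponseMatrix",
    "logistic",
    "evaluate_3pl",
    "prob_3pl",
    "to_slope_intercept",
    "from_slope_intercept",
    "rasch_log_transform",
    "log_likelihood",
    "items_to_frame",
    "items_from_frame",
]

#: Default floor applied to response probabilities inside log-likelihoods so
#: that log(0) never occurs. Probabilities are clamped to
#: [floor, 1 - floor] with a warning.
DEFAULT_PROB_FLOOR = 1e-12


@dataclass(frozen=True)
class Item3PL:
    """One item's parameters on a given calibration's scale.

    Parameters
    ----------
    a : float
        Discrimination, dimensionless, strictly positive.
    b : float
        Difficulty, in ability-scale units.
    c : float
        Lower asymptote (guessing probability), in ``[0, 1)``. ``c = 0``
        gives the 2PL submodel.
    """

    a: float
    b: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.a) or self.a <= 0:
            raise ValueError(f"discrimination a must be finite and > 0, got {self.a}")
        if not np.isfinite(self.b):
            raise ValueError(f"difficulty b must be finite, got {self.b}")
        if not np.isfinite(self.c) or not (0.0 <= self.c < 1.0):
            raise ValueError(f"lower asymptote c must lie in [0, 1), got {self.c}")


@dataclass(frozen=True)
class ItemSlopeIntercept:
    """Slope-intercept parameterization ``alpha * theta + beta`` of a 3PL item."""

    alpha: float
    beta: float
    c: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha) or self.alpha <= 0:
            raise ValueError(f"slope alpha must be finite and > 0, got {self.alpha}")
        if not np.isfinite(self.beta):
            raise ValueError(f"intercept beta must be finite, got {self.beta}")
        if not np.isfinite(self.c) or not (0.0 <= self.c < 1.0):
            raise ValueError(f"lower asymptote c must lie in [0, 1), got {self.c}")


@dataclass(frozen=True)
class RaschMultiplicativeParams:
    """Multiplicative Rasch parameters: ability ``vartheta`` and difficulty
    ``beta_m``, both strictly positive; success probability is
    ``vartheta / (vartheta + beta_m)``."""

    vartheta: float
    beta_m: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.vartheta) or self.vartheta <= 0:
            raise ValueError(f"vartheta must be finite and > 0, got {self.vartheta}")
        if not np.isfinite(self.beta_m) or self.beta_m <= 0:
            raise ValueError(f"beta_m must be finite and > 0, got {self.beta_m}")

    def probability(self) -> float:
        return self.vartheta / (self.vartheta + self.beta_m)


class ResponseMatrix:
    """Persons x items matrix of dichotomous (0/1) responses.

    Entries of ``-1`` code missing responses and are excluded from
    likelihood computations. Rows that are entirely missing are rejected.
    """

    def __init__(self, values, person_ids=None, item_ids=None):
        values = np.asarray(values)
        if values.ndim != 2:
            raise ValueError("response matrix must be two-dimensional")
        if not np.isin(values, (0, 1, -1)).all():
            raise ValueError("responses must be 0, 1 or -1 (missing)")
        self.values = values.astype(np.int8)
        n_p, n_i = self.values.shape
        if (self.values == -1).all(axis=1).any():
            raise ValueError("response matrix contains an all-missing person row")
        self.person_ids = (
            list(person_ids) if person_ids is not None else list(range(1, n_p + 1))
        )
        self.item_ids = (
            list(item_ids) if item_ids is not None else list(range(1, n_i + 1))
        )
        if len(self.person_ids) != n_p:
            raise ValueError("person_ids length does not match matrix")
        if len(self.item_ids) != n_i:
            raise ValueError("item_ids length does not match matrix")

    @property
    def shape(self):
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of observed (non-missing) entries."""
        return self.values >= 0

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, person_col: str = "person_id"):
        if person_col not in frame.columns:
            raise ValueError(f"responses table must have a '{person_col}' column")
        items = [c for c in frame.columns if c != person_col]
        vals = frame[items].to_numpy()
        vals = np.where(np.isnan(vals.astype(float)), -1, vals).astype(int)
        return cls(vals, person_ids=list(frame[person_col]), item_ids=items)

    def to_frame(self, person_col: str = "person_id") -> pd.DataFrame:
        out = pd.DataFrame(self.values, columns=self.item_ids)
        out.insert(0, person_col, self.person_ids)
        return out


def logistic(x):
    """Standard logistic function ``exp(x) / (1 + exp(x))``.

    Accepts scalars or arrays; raises on non-finite input.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("logistic requires finite input")
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out if out.ndim else float(out)


def prob_3pl(theta, a, b, c):
    """Vectorized 3PL response probability; broadcasts over all arguments."""
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    theta = np.asarray(theta, dtype=float)
    return c + (1.0 - c) * logistic(a * (theta - np.asarray(b, dtype=float)))


def evaluate_3pl(theta, item: Item3PL):
    """3PL response probability for ``item`` at ability ``theta``.

    ``theta`` may be a scalar or an array; the return value lies strictly
    between ``item.c`` and 1 and is strictly increasing in ``theta``.
    """
    if not isinstance(item, Item3PL):
        item = Item3PL(*item)
    theta = np.asarray(theta, dtype=float)
    if not np.isfinite(theta).all():
        raise ValueError("theta must be finite")
    out = prob_3pl(theta, item.a, item.b, item.c)
    return out if np.ndim(out) else float(out)


def to_slope_intercept(item: Item3PL) -> ItemSlopeIntercept:
    """Convert a standard-parameterization item to slope-intercept form
    (``alpha = a``, ``beta = -a * b``)."""
    if not isinstance(item, Item3PL):
        item = Item3PL(*item)
    return ItemSlopeIntercept(alpha=item.a, beta=-item.a * item.b, c=item.c)


def from_slope_intercept(item: ItemSlopeIntercept) -> Item3PL:
    """Convert a slope-intercept item back to the standard parameterization
    (``a = alpha``, ``b = -beta / alpha``)."""
    if not isinstance(item, ItemSlopeIntercept):
        item = ItemSlopeIntercept(*item)
    return Item3PL(a=item.alpha, b=-item.beta / item.alpha, c=item.c)


def rasch_log_transform(params: RaschMultiplicativeParams):
    """Map multiplicative Rasch parameters to additive ones:
    ``theta = ln(vartheta)``, ``b = ln(beta_m)``.

    The multiplicative success probability ``vartheta / (vartheta + beta_m)``
    equals the 3PL probability at the transformed parameters with ``a = 1``,
    ``c = 0``. Scaling both inputs by a common positive factor leaves the
    probability unchanged — the scale indeterminacy of this form.
    """
    if not isinstance(params, RaschMultiplicativeParams):
        params = RaschMultiplicativeParams(*params)
    return float(np.log(params.vartheta)), float(np.log(params.beta_m))


def log_likelihood(responses, thetas, items, floor: float = DEFAULT_PROB_FLOOR):
    """Bernoulli log-likelihood of a response matrix given abilities and items.

    Parameters
    ----------
    responses : ResponseMatrix or array-like of shape (P, I)
        0/1 entries; ``-1`` marks missing responses, which are excluded.
    thetas : array-like of shape (P,)
    items : sequence of Item3PL (or (a, b, c) triples), length I
    floor : float
        Probabilities are clamped to ``[floor, 1 - floor]``; a warning is
        emitted if clamping occurs.
    """
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(responses)
    u = responses.values
    thetas = np.asarray(thetas, dtype=float)
    items = [it if isinstance(it, Item3PL) else Item3PL(*it) for it in items]
    if thetas.shape[0] != u.shape[0]:
        raise ValueError("number of abilities does not match number of persons")
    if len(items) != u.shape[1]:
        raise ValueError("number of items does not match response matrix")
    a = np.array([it.a for it in items])
    b = np.array([it.b for it in items])
    c = np.array([it.c for it in items])
    pi = prob_3pl(thetas[:, None], a[None, :], b[None, :], c[None, :])
    if (pi < floor).any() or (pi > 1.0 - floor).any():
        warnings.warn(
            f"response probabilities clamped to [{floor}, 1 - {floor}]",
            RuntimeWarning,
            stacklevel=2,
        )
        pi = np.clip(pi, floor, 1.0 - floor)
    obs = responses.mask
    uu = np.where(obs, u, 0)
    ll = uu * np.log(pi) + np.where(obs, 1 - uu, 0) * np.log1p(-pi)
    return float(ll[obs].sum())


def items_to_frame(items, item_ids=None) -> pd.DataFrame:
    """Build an item table (columns ``item_id, a, b, c``) from Item3PL values."""
    items = [it if isinstance(it, Item3PL) else Item3PL(*it) for it in items]
    ids = list(item_ids) if item_ids is not None else list(range(1, len(items) + 1))
    return pd.DataFrame(
        {
            "item_id": ids,
            "a": [it.a for it in items],
            "b": [it.b for it in items],
            "c": [it.c for it in items],
        }
    )


def items_from_frame(frame: pd.DataFrame) -> list[Item3PL]:
    """Read Item3PL values from an item table with columns ``a, b, c``."""
    missing = {"a", "b", "c"} - set(frame.columns)
    if missing:
        raise ValueError(f"item table is missing columns: {sorted(missing)}")
    return [Item3PL(r.a, r.b, r.c) for r in frame.itertuples()]
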