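"""Linking transforms between two calibrations of the 3PL model.

When the same items and persons are calibrated twice under different
identifiability restrictions, the parameter values on the two scales are
connected by a componentwise monotone map which, for the 3PL model in its
standard parameterization, is affine::

    theta* = u * theta + v      a* = a / u      b* = u * b + v      c* = c

with slope ``u > 0`` and intercept ``v``. Response probabilities are
invariant: ``p(theta; a, b, c) = p(u*theta + v; a/u, u*b + v, c)``.

Direction convention
--------------------
Throughout this package a :class:`LinearLink` maps SOURCE-calibration values
onto the TARGET-calibration scale, with source = calibration 1 and target =
calibration 2 in the worked example. In particular
``u = a_source / a_target`` for a common item — note the source estimate in
the numerator.

Under the slope-intercept parameterization ``alpha * theta + beta`` the link
takes a different, three-parameter form (``u``, ``v``, ``w``)::

    alpha* = (alpha - u) / v     beta* = beta + u
    c*     = c                   vartheta* = (vartheta - u) / w

which is identifiable only from designs containing BOTH a common item and a
common person.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Item3PL, ItemSlopeIntercept

__all__ = [
    "LinearLink",
    "SlopeInterceptLink",
    "IdentifiabilityError",
    "DegenerateDesignError",
    "apply_link",
    "apply_link_theta",
    "apply_link_frame",
    "invert_link",
    "compose_links",
    "link_from_one_item",
    "link_from_two_items_b",
    "link_from_two_persons",
    "si_apply_link",
    "si_link_from_design",
]


class IdentifiabilityError(ValueError):
    """Raised when a linking design cannot identify the linking parameters."""


class DegenerateDesignError(ValueError):
    """Raised when a design is formally sufficient but numerically degenerate
    (e.g. equal source difficulties in a two-item design)."""


@dataclass(frozen=True)
class LinearLink:
    """Affine link ``theta* = u * theta + v`` from a source calibration's
    scale onto a target calibration's scale."""

    u: float
    v: float
    direction: str = field(default="source_to_target", compare=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.u) or self.u <= 0:
            raise ValueError(f"link slope u must be finite and > 0, got {self.u}")
        if not np.isfinite(self.v):
            raise ValueError(f"link intercept v must be finite, got {self.v}")

    def invert(self) -> "LinearLink":
        return invert_link(self)

    def to_dict(self) -> dict:
        return {"u": self.u, "v": self.v, "direction": self.direction}


@dataclass(frozen=True)
class SlopeInterceptLink:
    """Three-parameter link for the slope-intercept parameterization:
    ``alpha* = (alpha - u)/v``, ``beta* = beta + u``,
    ``vartheta* = (vartheta - u)/w``."""

    u: float
    v: float
    w: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.u):
            raise ValueError(f"u must be finite, got {self.u}")
        if not np.isfinite(self.v) or self.v <= 0:
            raise ValueError(f"v must be finite and > 0, got {self.v}")
        if not np.isfinite(self.w) or self.w == 0:
            raise ValueError(f"w must be finite and nonzero, got {self.w}")


def apply_link(item: Item3PL, link: LinearLink) -> Item3PL:
    """Map an item's parameters onto the target scale:
    ``(a/u, u*b + v, c)``."""
    if not isinstance(item, Item3PL):
        item = Item3PL(*item)
    return Item3PL(a=item.a / link.u, b=link.u * item.b + link.v, c=item.c)


def apply_link_theta(theta, link: LinearLink):
    """Map abilities onto the target scale: ``u * theta + v``."""
    theta = np.asarray(theta, dtype=float)
    out = link.u * theta + link.v
    return out if out.ndim else float(out)


def apply_link_frame(items: pd.DataFrame, link: LinearLink) -> pd.DataFrame:
    """Apply a link to an item table (columns ``a, b, c``), returning a copy."""
    out = items.copy()
    out["a"] = items["a"] / link.u
    out["b"] = link.u * items["b"] + link.v
    return out


def invert_link(link: LinearLink) -> LinearLink:
    """Inverse link ``(1/u, -v/u)``, mapping target scale back to source."""
    return LinearLink(1.0 / link.u, -link.v / link.u, direction="target_to_source")


def compose_links(first: LinearLink, second: LinearLink) -> LinearLink:
    """Composition applying ``first`` then ``second``:
    ``theta -> second.u * (first.u * theta + first.v) + second.v``."""
    return LinearLink(second.u * first.u, second.u * first.v + second.v)


def link_from_one_item(source: Item3PL, target: Item3PL) -> LinearLink:
    """Identify (u, v) from one common item's parameters in two calibrations.

    ``u = a_source / a_target`` and ``v = b_target - u * b_source``; a single
    common item suffices for the standard parameterization.
    """
    if not isinstance(source, Item3PL):
        source = Item3PL(*source)
    if not isinstance(target, Item3PL):
        target = Item3PL(*target)
    if target.a <= 0:
        raise ValueError(f"target discrimination must be > 0, got {target.a}")
    u = source.a / target.a
    v = target.b - u * source.b
    return LinearLink(u, v)


def link_from_two_items_b(
    b_source_pair, b_target_pair, consistency_tol: float | None = None
) -> LinearLink:
    """Identify (u, v) from the difficulties of two common items.

    ``u`` is the ratio of target to source difficulty differences and ``v``
    follows from either item. On noise-free inputs the two candidate values
    of ``v`` coincide; if ``consistency_tol`` is given, their disagreement
    beyond it raises :class:`DegenerateDesignError`. With estimates the mean
    of the two is returned.
    """
    b1s, b2s = (float(x) for x in b_source_pair)
    b1t, b2t = (float(x) for x in b_target_pair)
    if b1s == b2s:
        raise DegenerateDesignError(
            "two-item identification requires distinct source difficulties"
        )
    u = (b1t - b2t) / (b1s - b2s)
    if u <= 0:
        raise DegenerateDesignError(
            f"difficulty differences imply a non-positive slope u={u}"
        )
    v1 = b1t - u * b1s
    v2 = b2t - u * b2s
    if consistency_tol is not None and abs(v1 - v2) > consistency_tol:
        raise DegenerateDesignError(
            f"inconsistent intercepts from the two items: {v1} vs {v2}"
        )
    return LinearLink(u, 0.5 * (v1 + v2))


def link_from_two_persons(theta_source_pair, theta_target_pair) -> LinearLink:
    """Identify (u, v) from the abilities of two common persons.

    A single common person cannot identify the link; passing scalars (or
    length-1 sequences) raises :class:`IdentifiabilityError`, as do equal
    source abilities.
    """
    src = np.atleast_1d(np.asarray(theta_source_pair, dtype=float))
    tgt = np.atleast_1d(np.asarray(theta_target_pair, dtype=float))
    if src.size < 2 or tgt.size < 2:
        raise IdentifiabilityError(
            "linking parameters are not identifiable from a single common person; "
            "at least two are required"
        )
    t1s, t2s = src[:2]
    t1t, t2t = tgt[:2]
    if t1s == t2s:
        raise IdentifiabilityError(
            "two-person identification requires distinct source abilities"
        )
    u = (t1t - t2t) / (t1s - t2s)
    if u <= 0:
        raise DegenerateDesignError(
            f"ability differences imply a non-positive slope u={u}"
        )
    v = t1t - u * t1s
    return LinearLink(u, v)


def si_apply_link(
    item: ItemSlopeIntercept, theta: float, link: SlopeInterceptLink
):
    """Apply a slope-intercept link to an item and an ability.

    Returns ``(item_star, vartheta_star, residual)`` where ``residual`` is
    ``alpha* * vartheta* + beta* - (alpha * vartheta + beta)``, the deviation
    from the logit-invariance the link is supposed to preserve. The link
    family is over-parameterized, so the residual vanishes only when
    ``(u, v, w)`` satisfy the consistency relation tying them together (as
    those returned by :func:`si_link_from_design` do); the caller receives
    the residual rather than having an arbitrary reduction imposed.
    """
    if not isinstance(item, ItemSlopeIntercept):
        item = ItemSlopeIntercept(*item)
    alpha_star = (item.alpha - link.u) / link.v
    beta_star = item.beta + link.u
    theta_star = (float(theta) - link.u) / link.w
    if alpha_star <= 0:
        raise ValueError(
            f"link drives the slope to {alpha_star} <= 0; not a valid item"
        )
    item_star = ItemSlopeIntercept(alpha=alpha_star, beta=beta_star, c=item.c)
    residual = (
        alpha_star * theta_star + beta_star - (item.alpha * float(theta) + item.beta)
    )
    return item_star, theta_star, residual


def si_link_from_design(
    common_item_source: ItemSlopeIntercept | None,
    common_item_target: ItemSlopeIntercept | None,
    common_person_source: float | None,
    common_person_target: float | None,
) -> SlopeInterceptLink:
    """Identify (u, v, w) from one common item AND one common person.

    ``u = beta_target - beta_source``; ``v = (alpha_source - u) / alpha_target``;
    ``w = (vartheta_source - u) / vartheta_target``. Designs with only common
    items or only common persons cannot identify this link and raise
    :class:`IdentifiabilityError`.
    """
    has_item = common_item_source is not None and common_item_target is not None
    has_person = (
        common_person_source is not None and common_person_target is not None
    )
    if not (has_item and has_person):
        missing = "common person" if has_item else (
            "common item" if has_person else "common item and common person"
        )
        raise IdentifiabilityError(
            "the slope-intercept link is identifiable only from designs with "
            f"both common items and common persons; missing: {missing}"
        )
    src = common_item_source
    tgt = common_item_target
    if not isinstance(src, ItemSlopeIntercept):
        src = ItemSlopeIntercept(*src)
    if not isinstance(tgt, ItemSlopeIntercept):
        tgt = ItemSlopeIntercept(*tgt)
    th_s = float(common_person_source)
    th_t = float(common_person_target)
    if tgt.alpha == 0:
        raise ValueError("target slope must be nonzero")
    if th_t == 0:
        raise ValueError("target common-person vartheta must be nonzero")
    u = tgt.beta - src.beta
    v = (src.alpha - u) / tgt.alpha
    w = (th_s - u) / th_t
    return SlopeInterceptLink(u=u, v=v, w=w)
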