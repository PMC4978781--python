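"""Estimating the linking parameters (u, v) from common-item estimates.

Given item-parameter estimates for the common items of two calibrations
(source and target tables with columns ``item_id, a, b, c``), the slope and
intercept of the affine link can be estimated several ways:

* per item: ``u_i = a_i(source) / a_i(target)``,
  ``v_i = b_i(target) - u_i * b_i(source)``, with first-order delta-method
  standard errors from the per-item covariance matrices of the estimates,
  pooled by inverse squared SE (the precision-weighted estimator);
* mean/mean: ``u = mean(a_source) / mean(a_target)`` (or the geometric-mean
  variant), ``v = mean(b_target) - u * mean(b_source)``;
* mean/sigma: ``u = sd(b_target) / sd(b_source)``;
* response-function (Stocking-Lord / Haebara) criteria minimized
  numerically over a theta grid.

All estimators are exposed both as scikit-learn style classes with
``fit(source, target)`` and fitted attributes ``u_, v_, se_u_, se_v_``, and
as thin module-level functions returning :class:`PooledLink`.

Covariance tables follow the schema
``item_id, var_a, var_b, var_c, cov_ab, cov_ac, cov_bc`` (one row per item
within one calibration). Estimates from different calibrations are treated
as independent; only within-calibration, within-item covariances enter the
delta method — the same convention under which the worked example's printed
standard errors reproduce.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from .linking import LinearLink, apply_link_frame
from .model import prob_3pl

__all__ = [
    "ItemCovariance",
    "PerItemLink",
    "PooledLink",
    "MomentSummary",
    "per_item_links",
    "delta_se_per_item",
    "pool_precision_weighted",
    "mean_mean",
    "log_mean_mean",
    "mean_sigma",
    "stocking_lord",
    "sequential_se_curve",
    "PrecisionWeightedLink",
    "MeanMeanLink",
    "MeanSigmaLink",
    "StockingLordLink",
]

COV_COLUMNS = ["var_a", "var_b", "var_c", "cov_ab", "cov_ac", "cov_bc"]


@dataclass(frozen=True)
class ItemCovariance:
    """Symmetric 3x3 covariance of one item's (a, b, c) estimates within one
    calibration."""

    item_id: object
    calibration: object
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("covariance matrix must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")
        if (np.diag(m) < 0).any():
            raise ValueError("covariance diagonal must be nonnegative")
        eigmin = float(np.linalg.eigvalsh(m).min())
        if eigmin < -1e-10:
            warnings.warn(
                f"covariance for item {self.item_id} is not positive "
                f"semidefinite (min eigenvalue {eigmin:.3g}); proceeding",
                RuntimeWarning,
                stacklevel=2,
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_row(cls, row, calibration=None) -> "ItemCovariance":
        m = np.array(
            [
                [row["var_a"], row["cov_ab"], row["cov_ac"]],
                [row["cov_ab"], row["var_b"], row["cov_bc"]],
                [row["cov_ac"], row["cov_bc"], row["var_c"]],
            ],
            dtype=float,
        )
        return cls(item_id=row["item_id"], calibration=calibration, matrix=m)


@dataclass(frozen=True)
class PerItemLink:
    """Per-common-item link estimate with optional delta-method SEs."""

    item_id: object
    u: float
    v: float
    se_u: float | None = None
    se_v: float | None = None


@dataclass(frozen=True)
class PooledLink:
    """A combined (u, v) estimate with standard errors and per-item detail."""

    method: str
    u: float
    v: float
    se_u: float | None = None
    se_v: float | None = None
    per_item: pd.DataFrame | None = field(default=None, compare=False)

    @property
    def link(self) -> LinearLink:
        return LinearLink(self.u, self.v)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "u": self.u,
            "se_u": self.se_u,
            "v": self.v,
            "se_v": self.se_v,
        }


@dataclass(frozen=True)
class MomentSummary:
    """Means and standard deviations entering the moment methods
    (population SDs, divide-by-n)."""

    mu_a: float
    mu_b: float
    sigma_b: float
    n: int

    @classmethod
    def from_items(cls, items: pd.DataFrame) -> "MomentSummary":
        a = items["a"].to_numpy(float)
        b = items["b"].to_numpy(float)
        return cls(float(a.mean()), float(b.mean()), float(b.std()), len(items))


def _check_aligned(source: pd.DataFrame, target: pd.DataFrame):
    """Align two item tables on item_id; raise listing unmatched ids."""
    for name, df in (("source", source), ("target", target)):
        missing = {"item_id", "a", "b"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table is missing columns: {sorted(missing)}")
    s = source.set_index("item_id")
    t = target.set_index("item_id")
    only_s = sorted(set(s.index) - set(t.index))
    only_t = sorted(set(t.index) - set(s.index))
    if only_s or only_t:
        raise ValueError(
            "item tables do not match: "
            f"only in source {only_s}, only in target {only_t}"
        )
    t = t.loc[s.index]
    return s, t


def _cov_lookup(cov: pd.DataFrame, item_ids) -> pd.DataFrame:
    missing = {"item_id", *COV_COLUMNS} - set(cov.columns)
    if missing:
        raise ValueError(f"covariance table is missing columns: {sorted(missing)}")
    c = cov.set_index("item_id")
    absent = sorted(set(item_ids) - set(c.index))
    if absent:
        raise ValueError(f"covariance rows missing for items: {absent}")
    out = c.loc[list(item_ids)]
    if (out[["var_a", "var_b", "var_c"]].to_numpy(float) < 0).any():
        raise ValueError("covariance table has negative variances")
    not_psd = []
    for iid, row in out.iterrows():
        m = np.array(
            [
                [row["var_a"], row["cov_ab"], row["cov_ac"]],
                [row["cov_ab"], row["var_b"], row["cov_bc"]],
                [row["cov_ac"], row["cov_bc"], row["var_c"]],
            ],
            dtype=float,
        )
        if np.linalg.eigvalsh(m).min() < -1e-10:
            not_psd.append(iid)
    if not_psd:
        # rounded published covariances are routinely slightly indefinite
        warnings.warn(
            f"covariance matrices not positive semidefinite for items "
            f"{not_psd}; proceeding (common with rounded inputs)",
            RuntimeWarning,
            stacklevel=3,
        )
    return out


def per_item_links(source: pd.DataFrame, target: pd.DataFrame) -> pd.DataFrame:
    """One (u_i, v_i) per common item from the one-item identification
    formulas applied itemwise. Returns columns ``item_id, u, v``."""
    s, t = _check_aligned(source, target)
    if (t["a"] <= 0).any():
        bad = list(t.index[t["a"] <= 0])
        raise ValueError(f"non-positive target discriminations for items: {bad}")
    u = s["a"].to_numpy(float) / t["a"].to_numpy(float)
    v = t["b"].to_numpy(float) - u * s["b"].to_numpy(float)
    return pd.DataFrame({"item_id": s.index.to_numpy(), "u": u, "v": v})


def delta_se_per_item(
    per_item: pd.DataFrame,
    source: pd.DataFrame,
    target: pd.DataFrame,
    cov_source: pd.DataFrame,
    cov_target: pd.DataFrame,
) -> pd.DataFrame:
    """First-order delta-method SEs for the per-item link estimates.

    ``Var(u_i) = var_a1 / a2^2 + a1^2 var_a2 / a2^4`` (independent
    calibrations); ``Var(v_i)`` propagates the 4-vector (a1, b1, a2, b2)
    gradient ``(-b1/a2, -u, u*b1/a2, 1)`` including the within-calibration
    a-b covariances. Entries involving c are unused (its link is the
    identity). Returns ``per_item`` with ``se_u, se_v`` columns added.
    """
    s, t = _check_aligned(source, target)
    ids = per_item["item_id"].to_numpy()
    s = s.loc[ids]
    t = t.loc[ids]
    cs = _cov_lookup(cov_source, ids)
    ct = _cov_lookup(cov_target, ids)
    a1 = s["a"].to_numpy(float)
    b1 = s["b"].to_numpy(float)
    a2 = t["a"].to_numpy(float)
    va1 = cs["var_a"].to_numpy(float)
    vb1 = cs["var_b"].to_numpy(float)
    cab1 = cs["cov_ab"].to_numpy(float)
    va2 = ct["var_a"].to_numpy(float)
    vb2 = ct["var_b"].to_numpy(float)
    cab2 = ct["cov_ab"].to_numpy(float)
    u = per_item["u"].to_numpy(float)
    var_u = va1 / a2**2 + a1**2 * va2 / a2**4
    g_a1 = -b1 / a2
    g_b1 = -u
    g_a2 = u * b1 / a2
    var_v = (
        g_a1**2 * va1
        + g_b1**2 * vb1
        + 2.0 * g_a1 * g_b1 * cab1
        + g_a2**2 * va2
        + vb2
        + 2.0 * g_a2 * cab2
    )
    out = per_item.copy()
    out["se_u"] = np.sqrt(var_u)
    out["se_v"] = np.sqrt(var_v)
    return out


def pool_precision_weighted(per_item: pd.DataFrame) -> PooledLink:
    """Inverse-variance (1/SE^2) weighted combination of per-item estimates.

    The pooled SE is ``(sum SE^-2)^(-1/2)``, never larger than the smallest
    per-item SE. Requires strictly positive SEs.
    """
    for col in ("se_u", "se_v"):
        if col not in per_item.columns:
            raise ValueError("per-item table must carry se_u and se_v; "
                             "run delta_se_per_item first")
        se = per_item[col].to_numpy(float)
        if (se <= 0).any() or not np.isfinite(se).all():
            raise ValueError(f"{col} must be finite and > 0 for every item")
    wu = per_item["se_u"].to_numpy(float) ** -2.0
    wv = per_item["se_v"].to_numpy(float) ** -2.0
    u = float(np.sum(wu * per_item["u"].to_numpy(float)) / np.sum(wu))
    v = float(np.sum(wv * per_item["v"].to_numpy(float)) / np.sum(wv))
    return PooledLink(
        method="precision_weighted",
        u=u,
        v=v,
        se_u=float(np.sum(wu) ** -0.5),
        se_v=float(np.sum(wv) ** -0.5),
        per_item=per_item.copy(),
    )


def _moment_gradients_v(mu_b1, u, mu_a2, n):
    """Per-item gradients of v = mu(b2) - u * mu(b1) for the mean/mean method
    with u = mu(a1)/mu(a2); constant across items."""
    g_a1 = -mu_b1 / (n * mu_a2)
    g_b1 = -u / n
    g_a2 = u * mu_b1 / (n * mu_a2)
    g_b2 = 1.0 / n
    return g_a1, g_b1, g_a2, g_b2


def _quad_form(g_a, g_b, va, vb, cab):
    return g_a**2 * va + g_b**2 * vb + 2.0 * g_a * g_b * cab


def mean_mean(
    source: pd.DataFrame,
    target: pd.DataFrame,
    cov_source: pd.DataFrame | None = None,
    cov_target: pd.DataFrame | None = None,
    geometric: bool = False,
) -> PooledLink:
    """Mean/mean linking: ``u = mean(a_source) / mean(a_target)``,
    ``v = mean(b_target) - u * mean(b_source)``.

    With ``geometric=True`` the geometric means of the ``a`` estimates are
    used for ``u`` (the log-mean/mean variant); ``v`` is unchanged in form.
    Delta-method SEs (when covariances are supplied) treat items as
    independent with within-calibration (a, b) covariance per item.
    """
    s, t = _check_aligned(source, target)
    n = len(s)
    a1 = s["a"].to_numpy(float)
    b1 = s["b"].to_numpy(float)
    a2 = t["a"].to_numpy(float)
    b2 = t["b"].to_numpy(float)
    if geometric:
        if (a1 <= 0).any() or (a2 <= 0).any():
            raise ValueError("geometric means require strictly positive a")
        u = float(np.exp(np.log(a1).mean() - np.log(a2).mean()))
    else:
        if t["a"].mean() == 0:
            raise ValueError("target mean discrimination is zero")
        u = float(a1.mean() / a2.mean())
    v = float(b2.mean() - u * b1.mean())
    se_u = se_v = None
    if cov_source is not None and cov_target is not None:
        cs = _cov_lookup(cov_source, s.index)
        ct = _cov_lookup(cov_target, s.index)
        va1 = cs["var_a"].to_numpy(float)
        vb1 = cs["var_b"].to_numpy(float)
        cab1 = cs["cov_ab"].to_numpy(float)
        va2 = ct["var_a"].to_numpy(float)
        vb2 = ct["var_b"].to_numpy(float)
        cab2 = ct["cov_ab"].to_numpy(float)
        if geometric:
            # u = exp(mean(log a1) - mean(log a2)): d u/d a1i = u/(n a1i)
            gu_a1 = u / (n * a1)
            gu_a2 = -u / (n * a2)
        else:
            gu_a1 = np.full(n, 1.0 / (n * a2.mean()))
            gu_a2 = np.full(n, -a1.mean() / (n * a2.mean() ** 2))
        var_u = float(np.sum(gu_a1**2 * va1 + gu_a2**2 * va2))
        # v = mean(b2) - u * mean(b1); propagate u's dependence on the a's
        gv_a1 = -b1.mean() * gu_a1
        gv_b1 = np.full(n, -u / n)
        gv_a2 = -b1.mean() * gu_a2
        gv_b2 = np.full(n, 1.0 / n)
        var_v = float(
            np.sum(
                _quad_form(gv_a1, gv_b1, va1, vb1, cab1)
                + _quad_form(gv_a2, gv_b2, va2, vb2, cab2)
            )
        )
        se_u = float(np.sqrt(var_u))
        se_v = float(np.sqrt(var_v))
    return PooledLink(
        method="log_mean_mean" if geometric else "mean_mean",
        u=u, v=v, se_u=se_u, se_v=se_v,
    )


def log_mean_mean(
    source: pd.DataFrame,
    target: pd.DataFrame,
    cov_source: pd.DataFrame | None = None,
    cov_target: pd.DataFrame | None = None,
) -> PooledLink:
    """Mean/mean linking with geometric means of the ``a`` estimates."""
    return mean_mean(source, target, cov_source, cov_target, geometric=True)


def mean_sigma(
    source: pd.DataFrame,
    target: pd.DataFrame,
    cov_source: pd.DataFrame | None = None,
    cov_target: pd.DataFrame | None = None,
    mode: str = "items",
) -> PooledLink:
    """Mean/sigma linking: ``u = sd(b_target) / sd(b_source)``,
    ``v = mean(b_target) - u * mean(b_source)``.

    ``mode='persons'`` applies the same formulas to ability columns named
    ``theta`` instead of difficulties (common-person designs). Population
    (divide-by-n) standard deviations are used; the ratio ``u`` is invariant
    to the n versus n-1 choice. Delta-method SEs use
    ``d sd(b)/d b_i = (b_i - mean(b)) / (n * sd(b))``.
    """
    if mode not in ("items", "persons"):
        raise ValueError(f"mode must be 'items' or 'persons', got {mode!r}")
    col = "b" if mode == "items" else "theta"
    if mode == "persons":
        for name, df in (("source", source), ("target", target)):
            if col not in df.columns:
                raise ValueError(f"{name} table needs a '{col}' column in persons mode")
        b1 = source[col].to_numpy(float)
        b2 = target[col].to_numpy(float)
        if len(b1) != len(b2):
            raise ValueError("common-person tables must have equal length")
        vb1 = vb2 = None
    else:
        s, t = _check_aligned(source, target)
        b1 = s["b"].to_numpy(float)
        b2 = t["b"].to_numpy(float)
        vb1 = vb2 = None
        if cov_source is not None and cov_target is not None:
            vb1 = _cov_lookup(cov_source, s.index)["var_b"].to_numpy(float)
            vb2 = _cov_lookup(cov_target, s.index)["var_b"].to_numpy(float)
    n = len(b1)
    s1 = float(b1.std())
    s2 = float(b2.std())
    if s1 == 0:
        raise ValueError("source dispersion is zero; mean/sigma undefined")
    u = s2 / s1
    v = float(b2.mean() - u * b1.mean())
    se_u = se_v = None
    if vb1 is not None:
        du_db1 = -u * (b1 - b1.mean()) / (n * s1**2)
        du_db2 = (b2 - b2.mean()) / (n * s1 * s2)
        var_u = float(np.sum(du_db1**2 * vb1 + du_db2**2 * vb2))
        dv_db1 = -u / n - b1.mean() * du_db1
        dv_db2 = 1.0 / n - b1.mean() * du_db2
        var_v = float(np.sum(dv_db1**2 * vb1 + dv_db2**2 * vb2))
        se_u = float(np.sqrt(var_u))
        se_v = float(np.sqrt(var_v))
    return PooledLink(method="mean_sigma", u=u, v=v, se_u=se_u, se_v=se_v)


DEFAULT_THETA_GRID = np.linspace(-4.0, 4.0, 41)


def stocking_lord(
    source: pd.DataFrame,
    target: pd.DataFrame,
    theta_grid=None,
    criterion: str = "stocking_lord",
    bounds=((0.1, 10.0), (-5.0, 5.0)),
    start=(1.0, 0.0),
) -> PooledLink:
    """Response-function linking by bounded numerical minimization.

    The Stocking-Lord criterion is the squared difference, summed over a
    theta grid, between the target test characteristic curve of the common
    items and the source curve transformed by the candidate link; the
    Haebara variant sums squared per-item differences instead of
    differencing the sums. Both admit estimation error in the c estimates
    into the linking, unlike the per-item and moment methods.
    """
    if criterion not in ("stocking_lord", "haebara"):
        raise ValueError(f"unknown criterion {criterion!r}")
    s, t = _check_aligned(source, target)
    grid = np.asarray(
        DEFAULT_THETA_GRID if theta_grid is None else theta_grid, dtype=float
    )
    if grid.size == 0:
        raise ValueError("theta grid must be nonempty")
    if start[0] <= 0:
        raise ValueError("u must be initialized > 0")
    a1 = s["a"].to_numpy(float)
    b1 = s["b"].to_numpy(float)
    c1 = s["c"].to_numpy(float) if "c" in s.columns else np.zeros_like(a1)
    a2 = t["a"].to_numpy(float)
    b2 = t["b"].to_numpy(float)
    c2 = t["c"].to_numpy(float) if "c" in t.columns else np.zeros_like(a2)
    p_target = prob_3pl(grid[:, None], a2[None, :], b2[None, :], c2[None, :])

    def objective(x):
        u, v = x
        p_src = prob_3pl(grid[:, None], (a1 / u)[None, :],
                         (u * b1 + v)[None, :], c1[None, :])
        if criterion == "stocking_lord":
            return float(np.sum((p_target.sum(axis=1) - p_src.sum(axis=1)) ** 2))
        return float(np.sum((p_target - p_src) ** 2))

    res = optimize.minimize(
        objective, np.asarray(start, float), method="Powell",
        bounds=bounds, options={"xtol": 1e-10, "ftol": 1e-12, "maxiter": 10000},
    )
    if not res.success:
        raise RuntimeError(
            f"{criterion} optimization did not converge: {res.message}; "
            f"x={res.x}, fun={res.fun}, nit={res.nit}"
        )
    return PooledLink(method=criterion, u=float(res.x[0]), v=float(res.x[1]))


def sequential_se_curve(
    source: pd.DataFrame,
    target: pd.DataFrame,
    cov_source: pd.DataFrame,
    cov_target: pd.DataFrame,
    order=None,
    methods=("precision_weighted", "mean_mean", "mean_sigma"),
) -> pd.DataFrame:
    """Linking estimates and SEs as common items accrue one at a time.

    ``order`` is a permutation of the source table's item ids (default:
    table order). Row k uses the first k items. Mean/sigma needs at least
    two items and is reported from k=2. Returns a tidy table with columns
    ``n_items, method, u, se_u, v, se_v``. The precision-weighted SE columns
    are monotone nonincreasing in k by construction, and the k = n endpoint
    does not depend on the order.
    """
    s, _ = _check_aligned(source, target)
    ids = list(s.index)
    if order is None:
        order = ids
    order = list(order)
    if sorted(order) != sorted(ids) or len(set(order)) != len(order):
        raise ValueError("order must be a permutation of the item ids")
    per = per_item_links(source, target)
    per = delta_se_per_item(per, source, target, cov_source, cov_target)
    per = per.set_index("item_id")
    rows = []
    for k in range(1, len(order) + 1):
        chosen = order[:k]
        sub_s = source[source["item_id"].isin(chosen)]
        sub_t = target[target["item_id"].isin(chosen)]
        for method in methods:
            if method == "precision_weighted":
                pooled = pool_precision_weighted(
                    per.loc[chosen].reset_index()
                )
            elif method == "mean_mean":
                pooled = mean_mean(sub_s, sub_t, cov_source, cov_target)
            elif method == "log_mean_mean":
                pooled = log_mean_mean(sub_s, sub_t, cov_source, cov_target)
            elif method == "mean_sigma":
                if k < 2:
                    continue
                pooled = mean_sigma(sub_s, sub_t, cov_source, cov_target)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append(
                {"n_items": k, "method": method, "u": pooled.u,
                 "se_u": pooled.se_u, "v": pooled.v, "se_v": pooled.se_v}
            )
    return pd.DataFrame(rows)


class _FittedLinkMixin:
    """Shared fitted-state behaviour for the link estimators."""

    def _set_result(self, pooled: PooledLink):
        self.result_ = pooled
        self.u_ = pooled.u
        self.v_ = pooled.v
        self.se_u_ = pooled.se_u
        self.se_v_ = pooled.se_v
        self.link_ = LinearLink(pooled.u, pooled.v)
        return self

    def _check_fitted(self):
        if not hasattr(self, "link_"):
            raise AttributeError(
                f"{type(self).__name__} is not fitted yet; call fit first"
            )

    def transform(self, items: pd.DataFrame) -> pd.DataFrame:
        """Map a source-scale item table onto the target scale."""
        self._check_fitted()
        return apply_link_frame(items, self.link_)

    def transform_theta(self, theta):
        """Map source-scale abilities onto the target scale."""
        self._check_fitted()
        return self.link_.u * np.asarray(theta, dtype=float) + self.link_.v


class PrecisionWeightedLink(BaseEstimator, _FittedLinkMixin):
    """Precision-weighted common-item linking estimator.

    Fits per-item (u_i, v_i) with delta-method SEs and pools them with
    inverse-squared-SE weights. Requires per-item covariance tables for both
    calibrations.

    Attributes (after fit): ``u_``, ``v_``, ``se_u_``, ``se_v_``,
    ``per_item_`` (per-item table with SEs), ``link_``, ``result_``.
    """

    def fit(self, source, target, cov_source=None, cov_target=None):
        if cov_source is None or cov_target is None:
            raise ValueError(
                "precision weighting needs cov_source and cov_target tables"
            )
        per = per_item_links(source, target)
        per = delta_se_per_item(per, source, target, cov_source, cov_target)
        pooled = pool_precision_weighted(per)
        self.per_item_ = per
        return self._set_result(pooled)


class MeanMeanLink(BaseEstimator, _FittedLinkMixin):
    """Mean/mean (or geometric-mean) common-item linking estimator."""

    def __init__(self, geometric: bool = False):
        self.geometric = geometric

    def fit(self, source, target, cov_source=None, cov_target=None):
        return self._set_result(
            mean_mean(source, target, cov_source, cov_target,
                      geometric=self.geometric)
        )


class MeanSigmaLink(BaseEstimator, _FittedLinkMixin):
    """Mean/sigma linking estimator (items or persons mode)."""

    def __init__(self, mode: str = "items"):
        self.mode = mode

    def fit(self, source, target, cov_source=None, cov_target=None):
        return self._set_result(
            mean_sigma(source, target, cov_source, cov_target, mode=self.mode)
        )


class StockingLordLink(BaseEstimator, _FittedLinkMixin):
    """Stocking-Lord (or Haebara) response-function linking estimator."""

    def __init__(self, theta_grid=None, criterion: str = "stocking_lord",
                 bounds=((0.1, 10.0), (-5.0, 5.0)), start=(1.0, 0.0)):
        self.theta_grid = theta_grid
        self.criterion = criterion
        self.bounds = bounds
        self.start = start

    def fit(self, source, target, cov_source=None, cov_target=None):
        return self._set_result(
            stocking_lord(source, target, theta_grid=self.theta_grid,
                          criterion=self.criterion, bounds=self.bounds,
                          start=self.start)
        )
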