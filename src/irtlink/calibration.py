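"""Two-stage 3PL calibration: MML-EM item estimation, then ability estimation.

Stage one treats abilities as a random sample from a standard normal
population, marginalizes the Bernoulli likelihood over a fixed quadrature
grid (Bock-Aitkin EM), and maximizes the marginal likelihood in the item
parameters. Adopting theta ~ N(0, 1) is the de facto identifiability
restriction: the estimates converge to the generating parameters re-expressed
on the scale on which the calibration sample's abilities have mean 0 and
standard deviation 1 (a -> a*s, b -> (b - m)/s for a sample with mean m and
SD s) — the mechanism that makes separate calibrations of the same items
disagree and parameter linking necessary.

Stage two estimates each person's ability given the calibrated items, by
default the posterior mean (EAP) under the same N(0, 1) prior.

Per-item covariance matrices of the estimates come from the inverse of the
per-item cross-product (outer-product) matrix of the per-person marginal
score vectors, evaluated at the solution with the final posterior weights
(block-diagonal across items).

The unpenalized 3PL likelihood is notoriously flat in c; when c is estimated
a weak logit-normal prior centred at 0.25 and soft bounds stabilize the
M-steps (on by default for the 3PL, off for the 2PL, and always recorded in
the result). Fixing c at a known value (``c_fixed``) sidesteps the issue
entirely and is the configuration the built-in linking study uses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .model import Item3PL, ResponseMatrix, items_to_frame, logistic

__all__ = [
    "QuadratureGrid",
    "CalibrationResult",
    "ThreePLCalibrator",
    "mml_em_3pl",
    "eap_abilities",
    "simulate_responses",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed quadrature nodes and probability masses for the ability prior."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.shape != weights.shape or nodes.ndim != 1:
            raise ValueError("nodes and weights must be 1-d arrays of equal length")
        if (weights < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    @classmethod
    def normal(cls, n: int = 61, lo: float = -5.0, hi: float = 5.0,
               mean: float = 0.0, sd: float = 1.0) -> "QuadratureGrid":
        """Equispaced nodes with normalized normal masses."""
        nodes = np.linspace(lo, hi, n)
        w = stats.norm.pdf(nodes, mean, sd)
        return cls(nodes=nodes, weights=w / w.sum())


@dataclass
class CalibrationResult:
    """Output of one MML-EM calibration."""

    items: pd.DataFrame
    covariances: pd.DataFrame
    abilities: np.ndarray
    ability_method: str
    log_likelihood: float
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    settings: dict = field(default_factory=dict)


def simulate_responses(items, thetas, seed=None) -> ResponseMatrix:
    """Independent Bernoulli response draws under the 3PL model.

    ``items`` is an item table (columns ``a, b, c``; optional ``item_id``) or
    a sequence of Item3PL; ``seed`` may be an int or a numpy Generator.
    Reproducible bit-for-bit under a fixed integer seed.
    """
    if isinstance(items, pd.DataFrame):
        a = items["a"].to_numpy(float)
        b = items["b"].to_numpy(float)
        c = items["c"].to_numpy(float)
        ids = list(items["item_id"]) if "item_id" in items.columns else None
    else:
        items = [it if isinstance(it, Item3PL) else Item3PL(*it) for it in items]
        a = np.array([it.a for it in items])
        b = np.array([it.b for it in items])
        c = np.array([it.c for it in items])
        ids = None
    thetas = np.asarray(thetas, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pi = c + (1.0 - c) * logistic(a[None, :] * (thetas[:, None] - b[None, :]))
    vals = (rng.random(pi.shape) < pi).astype(np.int8)
    return ResponseMatrix(vals, item_ids=ids)


def _node_probs(a, b, c, nodes):
    """Item response probabilities at the quadrature nodes, shape (I, K)."""
    return c[:, None] + (1.0 - c[:, None]) * logistic(
        a[:, None] * (nodes[None, :] - b[:, None])
    )


def _posterior_weights(values, mask, logpi, log1mpi, logA):
    """Per-person posterior masses over nodes and the marginal log-likelihood."""
    u = np.where(mask, values, 0).astype(float)
    m = mask.astype(float)
    # (P, K) log-likelihood of each person's pattern at each node
    ll = u @ logpi + (m - u) @ log1mpi
    ll = ll + logA[None, :]
    mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    norm = w.sum(axis=1, keepdims=True)
    marginal = float((mx[:, 0] + np.log(norm[:, 0])).sum())
    return w / norm, marginal


class ThreePLCalibrator(BaseEstimator):
    """MML-EM calibrator for the 3PL model with a fixed N(0, 1) ability prior.

    Parameters
    ----------
    model : {'3pl', '2pl'}
        '2pl' fixes every c at 0 and disables the c prior.
    c_fixed : float, optional
        Fix every lower asymptote at this known value instead of
        estimating it.
    n_quadrature, quad_range :
        Bock-Aitkin grid: equispaced nodes with normalized N(0, 1) masses.
    tol : float
        EM stops when the largest absolute parameter change falls below it.
    max_iter : int
        EM cycle cap; exceeding it flags the result as non-converged.
    c_prior_sd : float or None
        SD of the weak logit-normal prior on estimated c (centred at
        logit(0.25)); None disables it. The default 'auto' enables it
        exactly when c is freely estimated.
    a_bounds, c_bounds :
        Soft box bounds for the M-steps.

    Attributes (after fit)
    ----------------------
    items_ : DataFrame (item_id, a, b, c)
    covariances_ : DataFrame (item_id, var_a, var_b, var_c, cov_ab, cov_ac,
        cov_bc) from the per-item cross-product of marginal scores
    abilities_ : EAP ability estimates, one per person
    loglik_trace_ : marginal log-likelihood per EM cycle (nondecreasing)
    n_iter_, converged_
    """

    def __init__(self, model: str = "3pl", c_fixed: float | None = None,
                 n_quadrature: int = 61, quad_range=(-5.0, 5.0),
                 tol: float = 1e-4, max_iter: int = 500,
                 c_prior_sd="auto", a_bounds=(0.05, 5.0),
                 c_bounds=(0.001, 0.5)):
        self.model = model
        self.c_fixed = c_fixed
        self.n_quadrature = n_quadrature
        self.quad_range = quad_range
        self.tol = tol
        self.max_iter = max_iter
        self.c_prior_sd = c_prior_sd
        self.a_bounds = a_bounds
        self.c_bounds = c_bounds

    # -- configuration ---------------------------------------------------
    def _resolve(self):
        if self.model not in ("3pl", "2pl"):
            raise ValueError(f"model must be '3pl' or '2pl', got {self.model!r}")
        if self.model == "2pl":
            c_value, estimate_c = 0.0, False
        elif self.c_fixed is not None:
            if not (0.0 <= self.c_fixed < 1.0):
                raise ValueError("c_fixed must lie in [0, 1)")
            c_value, estimate_c = float(self.c_fixed), False
        else:
            c_value, estimate_c = 0.25, True
        prior_sd = self.c_prior_sd
        if prior_sd == "auto":
            prior_sd = 1.0 if estimate_c else None
        return c_value, estimate_c, prior_sd

    # -- M-step objectives ----------------------------------------------
    @staticmethod
    def _item_Q(params, nodes, r_k, n_k, c_value, estimate_c, prior_sd):
        """Negative expected complete-data log-likelihood for one item."""
        if estimate_c:
            a, b, c = params
        else:
            a, b = params
            c = c_value
        psi = logistic(a * (nodes - b))
        pi = np.clip(c + (1.0 - c) * psi, 1e-10, 1.0 - 1e-10)
        q = float(np.sum(r_k * np.log(pi) + (n_k - r_k) * np.log1p(-pi)))
        grad_pi = r_k / pi - (n_k - r_k) / (1.0 - pi)
        dpsi = psi * (1.0 - psi)
        da = float(np.sum(grad_pi * (1.0 - c) * dpsi * (nodes - b)))
        db = float(np.sum(grad_pi * (1.0 - c) * dpsi * (-a)))
        if estimate_c:
            dc = float(np.sum(grad_pi * (1.0 - psi)))
            if prior_sd is not None:
                z = np.log(c / (1.0 - c)) - np.log(0.25 / 0.75)
                q += -0.5 * (z / prior_sd) ** 2
                dc += -(z / prior_sd**2) / (c * (1.0 - c))
            return -q, -np.array([da, db, dc])
        return -q, -np.array([da, db])

    # -- fitting ---------------------------------------------------------
    def fit(self, X, y=None):
        if not isinstance(X, ResponseMatrix):
            X = ResponseMatrix(X) if not isinstance(X, pd.DataFrame) \
                else ResponseMatrix.from_frame(X)
        values, mask = X.values, X.mask
        n_persons, n_items = values.shape
        if n_items < 2 or n_persons < 2:
            raise ValueError("calibration needs at least 2 items and 2 persons")
        observed = np.where(mask, values, 0)
        p_correct = observed.sum(axis=0) / np.maximum(mask.sum(axis=0), 1)
        if (p_correct == 0).any() or (p_correct == 1).any():
            bad = [X.item_ids[j] for j in
                   np.where((p_correct == 0) | (p_correct == 1))[0]]
            raise ValueError(f"constant-response items cannot be calibrated: {bad}")

        c_value, estimate_c, prior_sd = self._resolve()
        grid = QuadratureGrid.normal(self.n_quadrature, *self.quad_range)
        nodes, logA = grid.nodes, np.log(grid.weights)

        a = np.ones(n_items)
        adj = (p_correct - c_value) / np.maximum(1.0 - c_value, 1e-6)
        adj = np.clip(adj, 0.05, 0.95)
        b = -np.log(adj / (1.0 - adj))
        c = np.full(n_items, c_value)

        a_lo, a_hi = self.a_bounds
        bounds = [(a_lo, a_hi), (-8.0, 8.0)]
        if estimate_c:
            bounds.append(tuple(self.c_bounds))

        trace = []
        converged = False
        W = r_ik = n_k = None
        for iteration in range(1, self.max_iter + 1):
            pi_nodes = _node_probs(a, b, c, nodes)
            pi_nodes = np.clip(pi_nodes, 1e-10, 1.0 - 1e-10)
            logpi = np.log(pi_nodes)
            log1mpi = np.log1p(-pi_nodes)
            W, marginal = _posterior_weights(values, mask, logpi, log1mpi, logA)
            trace.append(marginal)
            # per-item expected trial and success counts at each node
            # (missing entries excluded via the mask)
            n_k = mask.astype(float).T @ W  # (I, K)
            r_ik = np.where(mask, values, 0).astype(float).T @ W

            max_change = 0.0
            for j in range(n_items):
                x0 = np.array([a[j], b[j], c[j]] if estimate_c else [a[j], b[j]])
                res = optimize.minimize(
                    self._item_Q, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                    args=(nodes, r_ik[j], n_k[j], c_value, estimate_c, prior_sd),
                    options={"maxiter": 50, "ftol": 1e-12, "gtol": 1e-9},
                )
                new = res.x
                max_change = max(max_change, float(np.max(np.abs(new - x0))))
                a[j], b[j] = new[0], new[1]
                if estimate_c:
                    c[j] = new[2]
            if max_change < self.tol:
                converged = True
                break

        if not converged:
            warnings.warn(
                f"EM did not converge in {self.max_iter} cycles "
                f"(last max parameter change {max_change:.3g})",
                RuntimeWarning,
                stacklevel=2,
            )
        if estimate_c:
            at_bound = (c <= self.c_bounds[0] + 1e-9) | (c >= self.c_bounds[1] - 1e-9)
            if at_bound.any():
                warnings.warn(
                    f"{int(at_bound.sum())} c estimate(s) at the box bound",
                    RuntimeWarning,
                    stacklevel=2,
                )

        # final E-step quantities for information matrices and EAP
        pi_nodes = np.clip(_node_probs(a, b, c, nodes), 1e-10, 1.0 - 1e-10)
        W, marginal = _posterior_weights(
            values, mask, np.log(pi_nodes), np.log1p(-pi_nodes), logA
        )
        trace.append(marginal)

        self.items_ = items_to_frame(
            [Item3PL(a[j], b[j], c[j]) for j in range(n_items)],
            item_ids=X.item_ids,
        )
        self.covariances_ = self._information_covariances(
            a, b, c, nodes, W, values, mask, estimate_c, X.item_ids
        )
        self.abilities_ = (W @ nodes)
        self.loglik_trace_ = np.asarray(trace)
        self.log_likelihood_ = marginal
        self.n_iter_ = iteration
        self.converged_ = converged
        self.grid_ = grid
        self.settings_ = {
            "model": self.model,
            "c_fixed": self.c_fixed,
            "estimate_c": estimate_c,
            "c_prior_sd": prior_sd,
            "n_quadrature": self.n_quadrature,
            "tol": self.tol,
            "max_iter": self.max_iter,
        }
        return self

    @staticmethod
    def _information_covariances(a, b, c, nodes, W, values, mask,
                                 estimate_c, item_ids):
        """Per-item covariance from the inverse of the cross-product matrix
        of per-person marginal score vectors (posterior-weighted scores, so
        the latency of the abilities is accounted for); c rows/columns are
        zero when c is not estimated."""
        rows = []
        for j in range(len(a)):
            psi = logistic(a[j] * (nodes - b[j]))
            pi = np.clip(c[j] + (1.0 - c[j]) * psi, 1e-10, 1.0 - 1e-10)
            dpsi = psi * (1.0 - psi)
            g = [
                (1.0 - c[j]) * dpsi * (nodes - b[j]),
                (1.0 - c[j]) * dpsi * (-a[j]),
            ]
            if estimate_c:
                g.append(1.0 - psi)
            G = np.vstack(g)  # (d, K)
            M = G / (pi * (1.0 - pi))[None, :]
            # per-person marginal score: s_p = E_post[ (u_pj - pi) * M ]
            u_j = np.where(mask[:, j], values[:, j], 0).astype(float)
            s = u_j[:, None] * (W @ M.T) - W @ (M * pi[None, :]).T  # (P, d)
            s = s * mask[:, j][:, None]
            info = s.T @ s
            try:
                cov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(info)
                warnings.warn(
                    f"singular information for item {item_ids[j]}; "
                    "pseudo-inverse used",
                    RuntimeWarning,
                    stacklevel=3,
                )
            full = np.zeros((3, 3))
            d = cov.shape[0]
            full[:d, :d] = cov
            rows.append(
                {
                    "item_id": item_ids[j],
                    "var_a": full[0, 0],
                    "var_b": full[1, 1],
                    "var_c": full[2, 2],
                    "cov_ab": full[0, 1],
                    "cov_ac": full[0, 2],
                    "cov_bc": full[1, 2],
                }
            )
        return pd.DataFrame(rows)

    def eap(self, X) -> np.ndarray:
        """EAP abilities for new response patterns under the fitted items."""
        if not hasattr(self, "items_"):
            raise AttributeError("calibrator is not fitted yet")
        if not isinstance(X, ResponseMatrix):
            X = ResponseMatrix(X) if not isinstance(X, pd.DataFrame) \
                else ResponseMatrix.from_frame(X)
        from .model import items_from_frame

        return eap_abilities(X, items_from_frame(self.items_), self.grid_)

    def result(self) -> CalibrationResult:
        """Package the fitted state as a :class:`CalibrationResult`."""
        if not hasattr(self, "items_"):
            raise AttributeError("calibrator is not fitted yet")
        return CalibrationResult(
            items=self.items_,
            covariances=self.covariances_,
            abilities=self.abilities_,
            ability_method="EAP",
            log_likelihood=self.log_likelihood_,
            loglik_trace=self.loglik_trace_,
            n_iter=self.n_iter_,
            converged=self.converged_,
            settings=self.settings_,
        )


def mml_em_3pl(responses, **config) -> CalibrationResult:
    """Calibrate a response matrix by MML-EM; see :class:`ThreePLCalibrator`."""
    return ThreePLCalibrator(**config).fit(responses).result()


def eap_abilities(responses, items, grid: QuadratureGrid | None = None) -> np.ndarray:
    """Posterior-mean (EAP) abilities under an N(0, 1) prior on the grid."""
    if not isinstance(responses, ResponseMatrix):
        responses = ResponseMatrix(responses)
    if grid is None:
        grid = QuadratureGrid.normal()
    items = [it if isinstance(it, Item3PL) else Item3PL(*it) for it in items]
    a = np.array([it.a for it in items])
    b = np.array([it.b for it in items])
    c = np.array([it.c for it in items])
    pi = np.clip(_node_probs(a, b, c, grid.nodes), 1e-12, 1.0 - 1e-12)
    W, _ = _posterior_weights(
        responses.values, responses.mask, np.log(pi), np.log1p(-pi),
        np.log(grid.weights),
    )
    return W @ grid.nodes
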