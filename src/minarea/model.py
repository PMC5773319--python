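"""Cumulative-logit (proportional-odds) model for three ordered occupancy states.

The latent model is

    logit P(Y <= j) = theta_j - eta,        eta = beta . x,

with ordered cutpoints theta_1 < theta_2 and a slope shared across the
two category transitions (the proportional-odds assumption).  Under this
sign convention — the one used by R's ``clm``/``polr`` family — a
positive area slope moves probability mass toward richer states on
larger islands.  Category probabilities follow as differences of
adjacent cumulative logistic curves:

    P0  = sigma(theta_1 - eta)
    P1  = sigma(theta_2 - eta) - sigma(theta_1 - eta)
    P2+ = 1 - sigma(theta_2 - eta)

Five candidate model forms are expressible: area, isolation,
area + isolation (additive), area * isolation (interaction, always with
both main effects), and random occurrence (cutpoints only).

Fitting is by maximum likelihood: quasi-Newton (BFGS) on the smooth
negative log-likelihood with an analytic gradient.  The cutpoint order
constraint is enforced by optimizing (theta_1, log(theta_2 - theta_1));
results are reported on the natural scale.  Starting values come from
the closed-form null MLE (empirical cumulative logits) with zero slopes,
so the fit is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .io import OrdinalDataset

MODEL_NAMES = ("area", "isolation", "additive", "interaction", "random")

#: Probability floor applied before logging, to keep the objective finite.
PROB_FLOOR = 1e-300

#: |beta| beyond this (on the log10 scale) is treated as parameter
#: divergence, the signature of complete separation.
SEPARATION_BOUND = 50.0

_TERMS_BY_NAME = {
    "random": (),
    "area": ("area",),
    "isolation": ("isolation",),
    "additive": ("area", "isolation"),
    "interaction": ("area", "isolation", "area:isolation"),
}


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One of the five candidate incidence models.

    ``terms`` is a subset of {"area", "isolation", "area:isolation"};
    the interaction always implies both main effects, so exactly the
    five a priori candidate forms are expressible.
    """

    terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.terms not in _TERMS_BY_NAME.values():
            raise ModelError(
                f"terms {self.terms!r} is not one of the five candidate "
                f"model forms {list(_TERMS_BY_NAME.values())}"
            )

    @classmethod
    def from_name(cls, name: str) -> "ModelSpec":
        if name not in _TERMS_BY_NAME:
            raise ModelError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
        return cls(terms=_TERMS_BY_NAME[name])

    @property
    def name(self) -> str:
        return next(k for k, v in _TERMS_BY_NAME.items() if v == self.terms)

    @property
    def K(self) -> int:
        """Parameter count: 2 cutpoints + one slope per term."""
        return 2 + len(self.terms)

    def design_matrix(self, data: OrdinalDataset) -> np.ndarray:
        cols = {
            "area": data.x_area,
            "isolation": data.x_isolation,
            "area:isolation": data.x_area * data.x_isolation,
        }
        if not self.terms:
            return np.empty((data.n, 0))
        return np.column_stack([cols[t] for t in self.terms])


@dataclass(frozen=True)
class OrdinalFit:
    """A fitted cumulative-logit model."""

    theta: tuple[float, float]
    beta: np.ndarray
    loglik: float
    spec: ModelSpec
    n: int
    converged: bool
    group: str = ""
    message: str = ""
    n_floored: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))

    @property
    def K(self) -> int:
        return self.spec.K

    def beta_for(self, term: str) -> float:
        return float(self.beta[self.spec.terms.index(term)])


def category_probs(
    theta: Sequence[float], beta: Sequence[float], x: np.ndarray
) -> np.ndarray:
    """Probabilities (P0, P1, P2+) at predictor rows ``x``.

    ``x`` is an (n, p) design matrix (or a length-p vector for one
    island) matching ``beta``; returns an (n, 3) array (or length-3
    vector) of category probabilities summing to 1.
    """
    theta1, theta2 = float(theta[0]), float(theta[1])
    if not theta1 < theta2:
        raise ModelError(f"ill-ordered cutpoints: theta1={theta1} >= theta2={theta2}")
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    x = np.asarray(x, dtype=float)
    p = beta.size
    if p == 0:
        eta, single = np.zeros(1), True
    elif x.ndim == 0:
        if p != 1:
            raise ModelError(f"scalar x but {p} slopes")
        eta, single = np.array([beta[0] * float(x)]), True
    elif x.ndim == 1 and x.size == p:
        eta, single = np.array([float(x @ beta)]), True
    elif x.ndim == 1 and p == 1:
        # vector of predictor values for a single-slope model
        eta, single = beta[0] * x, False
    elif x.ndim == 2 and x.shape[1] == p:
        eta, single = x @ beta, False
    else:
        raise ModelError(f"x shape {x.shape} incompatible with {p} slopes")
    cum1 = expit(theta1 - eta)
    cum2 = expit(theta2 - eta)
    probs = np.column_stack([cum1, cum2 - cum1, 1.0 - cum2])
    return probs[0] if single else probs


def neg_loglik(
    theta: Sequence[float],
    beta: Sequence[float],
    data: OrdinalDataset,
    spec: ModelSpec,
) -> float:
    """Negative log-likelihood -sum_i log P(Y = y_i | x_i)."""
    X = spec.design_matrix(data)
    value, _, _ = _nll_and_grad(
        float(theta[0]), float(theta[1]), np.asarray(beta, float), X, data.y
    )
    return value


def _nll_and_grad(theta1, theta2, beta, X, y):
    """Objective, gradient wrt (theta1, theta2, beta), and floor count."""
    eta = X @ beta if beta.size else np.zeros(len(y))
    z1 = theta1 - eta
    z2 = theta2 - eta
    F1 = expit(z1)
    F2 = expit(z2)
    f1 = F1 * (1.0 - F1)
    f2 = F2 * (1.0 - F2)

    p = np.where(y == 0, F1, np.where(y == 1, F2 - F1, 1.0 - F2))
    # dp/dtheta1, dp/dtheta2, dp/deta per island
    dp1 = np.where(y == 0, f1, np.where(y == 1, -f1, 0.0))
    dp2 = np.where(y == 0, 0.0, np.where(y == 1, f2, -f2))
    dpe = -dp1 - dp2

    floored = int(np.count_nonzero(p < PROB_FLOOR))
    p = np.maximum(p, PROB_FLOOR)
    value = -float(np.sum(np.log(p)))

    w = -1.0 / p
    g1 = float(np.sum(w * dp1))
    g2 = float(np.sum(w * dp2))
    gb = X.T @ (w * dpe) if beta.size else np.zeros(0)
    return value, np.concatenate([[g1, g2], gb]), floored


def _null_cutpoints(y: np.ndarray) -> tuple[float, float]:
    """Closed-form null MLE: logits of empirical cumulative proportions.

    Proportions are lightly clipped away from 0/1 so the starting values
    stay finite when a category is empty.
    """
    n = len(y)
    eps = 0.5 / n
    c1 = np.clip(np.mean(y <= 0), eps, 1.0 - 2 * eps)
    c2 = np.clip(np.mean(y <= 1), c1 + eps, 1.0 - eps)
    return float(logit(c1)), float(logit(c2))


def fit_mle(
    data: OrdinalDataset,
    spec: ModelSpec,
    gtol: float = 1e-8,
    maxiter: int = 500,
    start: tuple[float, float, np.ndarray] | None = None,
) -> OrdinalFit:
    """Fit a candidate model by maximum likelihood.

    Deterministic given the data (no random initialization): starts at
    the closed-form null cutpoints with zero slopes unless an explicit
    warm ``start = (theta1, theta2, beta)`` is given.  Non-convergence
    and suspected complete separation are flagged, never raised.
    """
    if len(np.unique(data.y)) < 2:
        raise ModelError(
            "fewer than 2 observed states: cutpoints are unidentifiable"
        )
    if data.n < spec.K + 1:
        raise ModelError(f"need at least K+1={spec.K + 1} islands, have {data.n}")
    X = spec.design_matrix(data)
    y = data.y
    p = X.shape[1]

    if start is None:
        t1, t2 = _null_cutpoints(y)
        beta0 = np.zeros(p)
    else:
        t1, t2, beta0 = float(start[0]), float(start[1]), np.asarray(start[2], float)
    # optimize (theta1, delta, beta) with theta2 = theta1 + exp(delta)
    x0 = np.concatenate([[t1, np.log(t2 - t1)], beta0])

    floor_count = 0

    def objective(params):
        nonlocal floor_count
        theta1 = params[0]
        edelta = np.exp(min(params[1], 50.0))  # barrier against overflow
        beta = params[2:]
        value, grad, floored = _nll_and_grad(theta1, theta1 + edelta, beta, X, y)
        floor_count += floored
        # chain rule onto (theta1, delta)
        g = np.empty_like(params)
        g[0] = grad[0] + grad[1]
        g[1] = grad[1] * edelta
        g[2:] = grad[2:]
        return value, g

    res = minimize(
        objective,
        x0,
        jac=True,
        method="BFGS",
        options={"gtol": gtol, "maxiter": maxiter},
    )
    theta1 = float(res.x[0])
    theta2 = theta1 + float(np.exp(res.x[1]))
    beta = np.asarray(res.x[2:], dtype=float)

    converged = bool(res.success) or float(np.max(np.abs(res.jac))) < 1e-5
    message = res.message
    if np.any(np.abs(beta) > SEPARATION_BOUND):
        converged = False
        message = (
            "parameter divergence (|beta| > "
            f"{SEPARATION_BOUND}); suspected complete separation"
        )
    return OrdinalFit(
        theta=(theta1, theta2),
        beta=beta,
        loglik=-float(res.fun),
        spec=spec,
        n=data.n,
        converged=converged,
        group=data.group,
        message=message,
        n_floored=floor_count,
    )


def aic(fit: OrdinalFit, force: bool = False) -> float:
    """Akaike information criterion, AIC = 2K - 2 logL."""
    if not fit.converged and not force:
        raise ModelError(
            f"refusing AIC of an unconverged fit ({fit.message}); "
            "pass force=True to override"
        )
    return 2.0 * fit.K - 2.0 * fit.loglik
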