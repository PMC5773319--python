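"""Minimum area thresholds as crossings of adjacent category probability curves.

The central statistic: along the log10-area axis of an area-only fit,
the minimum area for supporting one species is the point where
P(1 species) first exceeds P(0 species), and the minimum area for
supporting two or more species is where P(2+) first exceeds P(1).
Each is located as the sign change of the difference between the two
probability curves — coarse grid scan, then bisection.

For the cumulative-logit model both crossings exist iff the cutpoint
gap d = theta2 - theta1 exceeds ln 2, in which case they are unique:
writing c = ln(1 - 2 exp(-d)),

    x*_0->1  = (theta1 - c) / beta,
    x*_1->2+ = (theta2 + c) / beta.

The search-based estimator is the implementation (it generalizes and
mirrors how the statistic is defined); the closed form above is exposed
for generative truths and cross-checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .io import OrdinalDataset
from .model import ModelSpec, OrdinalFit, category_probs, fit_mle

TRANSITIONS = ("zero_to_one", "one_to_two_plus")

#: Coarse grid resolution for the sign-change scan.
GRID_POINTS = 4096

#: Bisection refinement tolerance on the log10-area axis.
X_TOL = 1e-6

#: Search extends this many log10 decades beyond the observed areas.
SEARCH_PAD = 2.0


class ThresholdError(ValueError):
    pass


@dataclass(frozen=True)
class ThresholdEstimate:
    """Crossing of adjacent category probability curves.

    ``x_star`` is on the log10 km² scale; ``area_km2 = 10**x_star``.
    ``exists`` is False when the curves never cross in the search
    interval (flat incidence or cutpoint gap below ln 2).
    """

    transition: str
    x_star: float
    area_km2: float
    exists: bool
    group: str = ""
    reason: str = ""

    @property
    def area_km2_rounded(self) -> float:
        """Area to one decimal, the usual reporting precision."""
        return round(self.area_km2, 1)


def _curve_difference(fit: OrdinalFit, transition: str, x: np.ndarray) -> np.ndarray:
    """P_lower(x) - P_upper(x) for the adjacent pair of the transition."""
    probs = np.atleast_2d(category_probs(fit.theta, fit.beta, np.asarray(x, float)))
    lower, upper = (0, 1) if transition == "zero_to_one" else (1, 2)
    return probs[:, lower] - probs[:, upper]


def find_crossing(
    fit: OrdinalFit,
    transition: str,
    search: tuple[float, float],
) -> ThresholdEstimate:
    """Locate one threshold for an area-only fit by grid scan + bisection.

    Scans ``search`` (log10 km²) on a coarse grid for a sign change of
    P_lower - P_upper, then refines by bisection to |Δx| < 1e-6.
    Multiple sign changes violate the model structure and raise; no sign
    change yields ``exists=False``.
    """
    if transition not in TRANSITIONS:
        raise ThresholdError(f"transition must be one of {TRANSITIONS}")
    if fit.spec.name != "area":
        raise ThresholdError("thresholds are defined on the area-only model")
    if not fit.converged:
        raise ThresholdError(f"refusing thresholds from an unconverged fit: {fit.message}")
    beta = fit.beta_for("area")
    if beta == 0:
        return ThresholdEstimate(
            transition, math.nan, math.nan, False, fit.group, "flat incidence"
        )

    grid = np.linspace(float(search[0]), float(search[1]), GRID_POINTS)
    diff = _curve_difference(fit, transition, grid)
    return _locate(fit, transition, grid, diff)


#: |P_lower - P_upper| below this is rounding noise: in the far tails both
#: probabilities underflow and their difference carries no sign information.
DIFF_NOISE_FLOOR = 1e-12


def _locate(
    fit: OrdinalFit, transition: str, grid: np.ndarray, diff: np.ndarray
) -> ThresholdEstimate:
    """Bracket the sign change of a pre-evaluated curve difference, then refine."""
    sign = np.sign(np.where(np.abs(diff) < DIFF_NOISE_FLOOR, 0.0, diff))
    # count strict sign flips, skipping near-zero grid values
    idx = np.flatnonzero(sign != 0)
    nonzero = sign[idx]
    flips = int(np.count_nonzero(nonzero[1:] != nonzero[:-1]))
    if flips > 1:
        raise ThresholdError(
            f"multiple crossings for {transition}: model structure violated"
        )
    if flips == 0:
        return ThresholdEstimate(
            transition, math.nan, math.nan, False, fit.group,
            "no sign change in search interval",
        )
    k = int(np.flatnonzero(nonzero[1:] != nonzero[:-1])[0])
    a, b = grid[idx[k]], grid[idx[k + 1]]
    x_star = float(
        brentq(lambda x: _curve_difference(fit, transition, x)[0], a, b, xtol=X_TOL)
    )
    return ThresholdEstimate(transition, x_star, 10.0**x_star, True, fit.group)


def default_search_interval(data: OrdinalDataset) -> tuple[float, float]:
    """Observed log10-area range padded by ±2 decades."""
    return (
        float(data.x_area.min() - SEARCH_PAD),
        float(data.x_area.max() + SEARCH_PAD),
    )


def thresholds_from_fit(
    fit: OrdinalFit, search: tuple[float, float]
) -> tuple[ThresholdEstimate, ThresholdEstimate]:
    """Both transitions' crossings, sharing one grid evaluation."""
    if fit.spec.name != "area":
        raise ThresholdError("thresholds are defined on the area-only model")
    if not fit.converged:
        raise ThresholdError(
            f"refusing thresholds from an unconverged fit: {fit.message}"
        )
    if fit.beta_for("area") == 0:
        return tuple(
            ThresholdEstimate(t, math.nan, math.nan, False, fit.group, "flat incidence")
            for t in TRANSITIONS
        )
    grid = np.linspace(float(search[0]), float(search[1]), GRID_POINTS)
    probs = category_probs(fit.theta, fit.beta, grid)
    return (
        _locate(fit, "zero_to_one", grid, probs[:, 0] - probs[:, 1]),
        _locate(fit, "one_to_two_plus", grid, probs[:, 1] - probs[:, 2]),
    )


def thresholds_report(
    data: OrdinalDataset,
) -> tuple[ThresholdEstimate, ThresholdEstimate]:
    """Fit the area-only model and return both transitions' thresholds.

    The area-only model is used even when richer models carry weight:
    the threshold statistic is defined on the incidence-versus-area
    curves of the model selected by AIC.
    """
    fit = fit_mle(data, ModelSpec.from_name("area"))
    if not fit.converged:
        raise ThresholdError(f"area-only fit did not converge: {fit.message}")
    return thresholds_from_fit(fit, default_search_interval(data))


def analytic_crossings(
    theta: tuple[float, float], beta_area: float
) -> tuple[float, float]:
    """Closed-form crossing points (log10 km²) of a cumulative-logit model.

    Returns (x*_0->1, x*_1->2+); NaN when the cutpoint gap is ≤ ln 2 or
    the slope is zero (no crossing exists).  Used for generative truths
    in simulations and as an independent check on the search.
    """
    theta1, theta2 = float(theta[0]), float(theta[1])
    d = theta2 - theta1
    if beta_area == 0 or d <= math.log(2.0):
        return (math.nan, math.nan)
    c = math.log(1.0 - 2.0 * math.exp(-d))
    return ((theta1 - c) / beta_area, (theta2 + c) / beta_area)
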