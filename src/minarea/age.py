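"""Island-age confounding check via modal-state residuals.

The threshold analysis assumes occupancy is driven by island area, not
confounded by island age.  The check: fit the area-only model on ALL
islands, compute for each island with a reliable age the residual
(observed state minus the modal predicted state), and regress that
residual on log10 age by ordinary least squares.  A slope near zero and
negligible R² indicate age does not structure the occupancy pattern
beyond what area explains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import OrdinalDataset
from .model import ModelSpec, OrdinalFit, category_probs, fit_mle


@dataclass(frozen=True)
class ResidualAgeResult:
    """OLS line of modal-state residuals on log10 island age."""

    names: tuple[str, ...]
    residuals: np.ndarray
    log10_age: np.ndarray
    slope: float
    intercept: float
    r2: float
    n: int


def modal_state(fit: OrdinalFit, x) -> int:
    """State (0, 1 or 2) with the highest probability at predictor x.

    Ties break toward the LOWER state (deterministic, conservative).
    """
    probs = category_probs(fit.theta, fit.beta, x)
    # np.argmax already returns the first (= lowest) index on ties
    return int(np.argmax(probs))


def age_check(data: OrdinalDataset, log10_ages: np.ndarray) -> ResidualAgeResult:
    """Regress modal-state residuals on log10 age for the aged subset.

    ``log10_ages`` is per-island, NaN where age is unknown; the model
    is fitted on all islands, residuals only on the aged subset.
    """
    log10_ages = np.asarray(log10_ages, dtype=float)
    if len(log10_ages) != data.n:
        raise ValueError("log10_ages must align with the dataset rows")
    fit = fit_mle(data, ModelSpec.from_name("area"))
    aged = np.flatnonzero(np.isfinite(log10_ages))
    if aged.size < 3:
        raise ValueError(f"need at least 3 islands with age, have {aged.size}")
    t = log10_ages[aged]
    if np.ptp(t) == 0:
        raise ValueError("zero variance in log10 age: slope undefined")

    predicted = np.array([modal_state(fit, data.x_area[i]) for i in aged])
    resid = data.y[aged] - predicted

    slope, intercept = np.polyfit(t, resid, 1)
    fitted = slope * t + intercept
    ss_tot = float(np.sum((resid - resid.mean()) ** 2))
    ss_res = float(np.sum((resid - fitted) ** 2))
    r2 = 0.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    names = tuple(np.asarray(data.names)[aged]) if data.names else ()
    return ResidualAgeResult(
        names=names,
        residuals=resid,
        log10_age=t,
        slope=float(slope),
        intercept=float(intercept),
        r2=r2,
        n=int(aged.size),
    )
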