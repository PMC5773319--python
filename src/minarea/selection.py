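"""AIC model selection over the five candidate incidence models.

Produces, per taxonomic group, the selection table: K, AIC, ΔAIC,
Akaike weights over the full five-model set and over the main-effects
set {area, isolation, random}, and McFadden's pseudo-R² against the
random-occurrence (cutpoints-only) null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import OrdinalDataset
from .model import ModelSpec, OrdinalFit, aic, fit_mle

#: Table row order: area, isolation, additive, interaction, random.
TABLE_ORDER = ("area", "isolation", "additive", "interaction", "random")

#: The reduced main-effects candidate set over which weights are also reported.
MAIN_EFFECTS_SET = ("area", "isolation", "random")


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights w_i = exp(-Δ_i/2) / Σ_j exp(-Δ_j/2).

    The minimum AIC is subtracted before exponentiating so the weights
    are numerically stable however large the AICs are.
    """
    aics = np.asarray(aics, dtype=float)
    if aics.size == 0:
        raise ValueError("need at least one AIC value")
    if not np.isfinite(aics).all():
        raise ValueError("AIC values must be finite")
    rel = np.exp(-0.5 * (aics - aics.min()))
    return rel / rel.sum()


def mcfadden_r2(fit: OrdinalFit, null_fit: OrdinalFit) -> float:
    """McFadden's pseudo-R² = 1 - logL(model) / logL(null)."""
    if null_fit.spec.terms:
        raise ValueError("null_fit must be the random-occurrence model")
    if fit.n != null_fit.n:
        raise ValueError("fits compare different datasets")
    if null_fit.loglik == 0:
        raise ValueError(
            "degenerate data: null log-likelihood is zero, pseudo-R² undefined"
        )
    return 1.0 - fit.loglik / null_fit.loglik


@dataclass(frozen=True)
class SelectionTable:
    """Per-model selection results for one group."""

    group: str
    fits: dict[str, OrdinalFit]
    frame: pd.DataFrame

    def fit(self, name: str) -> OrdinalFit:
        return self.fits[name]


def build_selection_table(data: OrdinalDataset) -> SelectionTable:
    """Fit all five candidate models and assemble the selection table.

    Weights are computed over converged fits only; an unconverged
    candidate is flagged in the table and triggers a warning.
    """
    fits = {name: fit_mle(data, ModelSpec.from_name(name)) for name in TABLE_ORDER}
    bad = [name for name, f in fits.items() if not f.converged]
    if bad:
        warnings.warn(
            f"candidate model(s) {bad} did not converge; "
            "weights computed over the remaining models",
            stacklevel=2,
        )
    ok = [name for name in TABLE_ORDER if fits[name].converged]
    aics = {name: aic(fits[name]) for name in ok}

    w_full = dict(zip(ok, akaike_weights([aics[n] for n in ok])))
    main_ok = [n for n in MAIN_EFFECTS_SET if n in ok]
    w_main = dict(zip(main_ok, akaike_weights([aics[n] for n in main_ok])))

    best = min(aics.values())
    null = fits["random"]
    rows = []
    for name in TABLE_ORDER:
        f = fits[name]
        rows.append(
            {
                "model": name,
                "group": data.group,
                "K": f.spec.K,
                "AIC": aics.get(name, np.nan),
                "delta_AIC": aics[name] - best if name in aics else np.nan,
                "weight_full": w_full.get(name, np.nan),
                "weight_main": w_main.get(name, np.nan),
                "pseudo_R2": (
                    np.nan
                    if name == "random" or name not in aics
                    else mcfadden_r2(f, null)
                ),
                "converged": f.converged,
            }
        )
    return SelectionTable(group=data.group, fits=fits, frame=pd.DataFrame(rows))


def render_table(table: SelectionTable) -> pd.DataFrame:
    """Publication-style rendering of a selection table.

    Weights round to 2 decimals, with values ≥ 0.995 shown as ">0.99"
    and < 0.005 as "<0.01"; pseudo-R² drops the leading zero; the
    random model's pseudo-R² and the non-main-effects models' reduced
    weights print as "NA".  Full precision stays in ``table.frame``.
    """

    def w(value: float) -> str:
        if np.isnan(value):
            return "NA"
        if value >= 0.995:
            return ">0.99"
        if value < 0.005:
            return "<0.01"
        return f"{value:.2f}"

    def r2(value: float) -> str:
        return "NA" if np.isnan(value) else f"{value:.2f}".lstrip("0")

    src = table.frame
    return pd.DataFrame(
        {
            "Model": src["model"],
            "Group": src["group"],
            "K": src["K"],
            "AIC": src["AIC"].round(2),
            "dAIC": src["delta_AIC"].round(2),
            "AICw": src["weight_full"].map(w),
            "AICw_main": src["weight_main"].map(w),
            "R2": src["pseudo_R2"].map(r2),
        }
    )
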