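"""Synthetic archipelago generator.

Produces island tables with the statistical structure the incidence
analysis assumes: a heavy-tailed island-size spectrum (log10 areas
normal, spanning roughly four orders of magnitude in km²), optionally
correlated log10 isolations, ordered occupancy states drawn from a
cumulative-logit model in the log10 predictors, and sparse island ages
assigned independently of occupancy.  Everything is seed-deterministic.

This generator supports parameter-recovery, power and CI-coverage
simulations without any download; it makes no claim to geophysical
realism (no vicariance timing, no sea-level history) — only to the
structure the inference relies on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import GROUPS, IslandRecord
from .model import category_probs


@dataclass(frozen=True)
class OccupancyParams:
    """Generative truth for one taxonomic group."""

    theta: tuple[float, float]
    beta_area: float
    beta_iso: float = 0.0

    def __post_init__(self) -> None:
        if not self.theta[0] < self.theta[1]:
            raise ValueError("theta must be strictly increasing")


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions of a simulated archipelago.

    ``theta_true`` / ``beta_area_true`` / ``beta_iso_true`` define the
    occupancy model for both groups unless ``params_colubrids``
    overrides the colubrid side (shared geography, independent states).
    Areas are km², isolations km, ages ky.
    """

    n: int = 83
    theta_true: tuple[float, float] = (0.0, 2.0)
    beta_area_true: float = 1.5
    beta_iso_true: float = 0.0
    area_log10_mean: float = 0.0
    area_log10_sd: float = 1.0
    iso_log10_mean: float = 0.3
    iso_log10_sd: float = 0.6
    iso_corr: float = 0.0
    age_fraction: float = 0.3
    age_log10_mean: float = 1.1
    age_log10_sd: float = 0.35
    seed: int = 0
    params_colubrids: OccupancyParams | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.area_log10_sd > 0:
            raise ValueError("area_log10_sd must be > 0")
        if not abs(self.iso_corr) < 1:
            raise ValueError("|iso_corr| must be < 1")
        if not self.theta_true[0] < self.theta_true[1]:
            raise ValueError("theta_true must be strictly increasing")
        if not 0 <= self.age_fraction <= 1:
            raise ValueError("age_fraction must be in [0, 1]")

    def group_params(self, group: str) -> OccupancyParams:
        base = OccupancyParams(
            theta=self.theta_true,
            beta_area=self.beta_area_true,
            beta_iso=self.beta_iso_true,
        )
        if group == "colubrids" and self.params_colubrids is not None:
            return self.params_colubrids
        return base


def _draw_states(
    rng: np.random.Generator,
    params: OccupancyParams,
    x_area: np.ndarray,
    x_iso: np.ndarray,
) -> np.ndarray:
    eta = params.beta_area * x_area + params.beta_iso * x_iso
    probs = category_probs(params.theta, np.array([1.0]), eta[:, None])
    u = rng.random(len(eta))
    cum = np.cumsum(probs, axis=1)
    return (u[:, None] > cum).sum(axis=1)


def generate(config: SyntheticConfig) -> list[IslandRecord]:
    """Draw one synthetic archipelago.

    States above 2 are never generated (the model lives on bucketed
    states, so state 2 becomes a count of exactly 2); the loader's
    bucketing of raw counts is exercised separately with hand-made
    tables.
    """
    rng = np.random.default_rng(config.seed)
    z_area = rng.standard_normal(config.n)
    z_iso = rng.standard_normal(config.n)
    x_area = config.area_log10_mean + config.area_log10_sd * z_area
    rho = config.iso_corr
    x_iso = config.iso_log10_mean + config.iso_log10_sd * (
        rho * z_area + math.sqrt(1.0 - rho**2) * z_iso
    )

    counts = {
        group: _draw_states(rng, config.group_params(group), x_area, x_iso)
        for group in GROUPS
    }

    n_aged = int(round(config.age_fraction * config.n))
    aged = rng.choice(config.n, size=n_aged, replace=False)
    ages = np.full(config.n, np.nan)
    ages[aged] = 10.0 ** (
        config.age_log10_mean + config.age_log10_sd * rng.standard_normal(n_aged)
    )

    width = len(str(config.n))
    return [
        IslandRecord(
            name=f"isla-{i + 1:0{width}d}",
            area_km2=float(10.0 ** x_area[i]),
            isolation_km=float(10.0 ** x_iso[i]),
            count_rattlesnakes=int(counts["rattlesnakes"][i]),
            count_colubrids=int(counts["colubrids"][i]),
            age=None if np.isnan(ages[i]) else float(ages[i]),
        )
        for i in range(config.n)
    ]


# Generative truths whose ANALYTIC crossings sit at the minimum-area
# thresholds reported for the Gulf of California snake fauna
# (0->1 at 1.8 / 1.7 km², 1->2+ at 37.1 / 6.7 km²), so the fixture
# emulates the study conditions.  These are synthetic stand-in
# parameters, not estimates from the real island table.
FIXTURE_RATTLESNAKES = OccupancyParams(theta=(0.389, 3.259), beta_area=2.0)
FIXTURE_COLUBRIDS = OccupancyParams(theta=(0.105, 2.007), beta_area=2.0)

# packaging seed: first integer for which the fixture satisfies its
# contract (area model ranks best for both groups, both crossings exist,
# every state has >= 5 islands)
FIXTURE_SEED = 1

FIXTURE_CONFIG = SyntheticConfig(
    n=83,
    theta_true=FIXTURE_RATTLESNAKES.theta,
    beta_area_true=FIXTURE_RATTLESNAKES.beta_area,
    params_colubrids=FIXTURE_COLUBRIDS,
    seed=FIXTURE_SEED,
)


def fixture_83() -> list[IslandRecord]:
    """A seed-fixed SYNTHETIC 83-island table emulating the study system.

    NOT real survey data: a packaged synthetic stand-in with the
    same marginal structure (right-skewed areas, most islands below
    10 km², a few above 100 km², two species-count columns, sparse ages)
    for tests and demonstrations that need a realistic table without any
    download.
    """
    return generate(FIXTURE_CONFIG)
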