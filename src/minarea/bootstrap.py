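"""Percentile bootstrap confidence intervals for minimum area thresholds.

Islands (rows) are resampled with replacement; each replicate refits the
area-only model and re-locates both crossings.  The 0.025 and 0.975
empirical quantiles of the resampled thresholds, on the km² scale, give
the 95% interval.  Replicates whose refit fails to converge, whose
resample contains fewer than two distinct states, or whose curves do not
cross are dropped (never retried) and accounted for via ``b_effective``.

Both transitions are estimated from the SAME resample stream so their
dependence is preserved.  All randomness flows from a single user
seed through deterministic per-replicate substreams
(``numpy.random.SeedSequence.spawn``), so results are bit-identical for
identical (data, seed, b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import OrdinalDataset
from .model import ModelError, ModelSpec, fit_mle
from .thresholds import (
    ThresholdEstimate,
    default_search_interval,
    thresholds_from_fit,
    thresholds_report,
)

#: Percentile pair defining the 95% interval.
CI_PROBS = (0.025, 0.975)


def quantile_pair(samples, probs=CI_PROBS) -> tuple[float, float]:
    """Empirical quantiles under the linear-interpolation (type 7) rule.

    Type 7 is the default of R and NumPy, fixed here so interval
    endpoints are reproducible across implementations.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("cannot take quantiles of an empty sample")
    lo, hi = np.quantile(samples, probs, method="linear")
    return float(lo), float(hi)


@dataclass(frozen=True)
class BootstrapResult:
    """Resampled threshold distribution and its percentile CI (km²)."""

    transition: str
    b_requested: int
    b_effective: int
    samples: np.ndarray
    ci_low: float
    ci_high: float
    seed: int
    point_estimate: ThresholdEstimate
    reliable: bool

    @property
    def failure_fraction(self) -> float:
        return 1.0 - self.b_effective / self.b_requested


def bootstrap_thresholds(
    data: OrdinalDataset,
    b: int = 10_000,
    seed: int = 0,
) -> tuple[BootstrapResult, BootstrapResult]:
    """Percentile bootstrap CIs for both minimum area thresholds.

    Returns one :class:`BootstrapResult` per transition
    (zero_to_one, one_to_two_plus).  A result is flagged unreliable when
    fewer than half the requested replicates yielded a crossing.
    """
    if b < 1:
        raise ValueError("need at least one bootstrap replicate")
    point = thresholds_report(data)
    search = default_search_interval(data)
    area_spec = ModelSpec.from_name("area")
    # warm-start replicates from the full-data fit: same optimum, fewer steps
    full_fit = fit_mle(data, area_spec)
    warm = (full_fit.theta[0], full_fit.theta[1], full_fit.beta)

    streams = np.random.SeedSequence(seed).spawn(b)
    samples: dict[str, list[float]] = {t.transition: [] for t in point}
    for stream in streams:
        rng = np.random.default_rng(stream)
        idx = rng.integers(0, data.n, size=data.n)
        resample = data.subset(idx)
        if len(np.unique(resample.y)) < 2:
            continue
        try:
            refit = fit_mle(resample, area_spec, start=warm)
        except ModelError:
            continue
        if not refit.converged:
            continue
        for est in thresholds_from_fit(refit, search):
            if est.exists:
                samples[est.transition].append(est.area_km2)

    results = []
    for est in point:
        draws = np.asarray(samples[est.transition], dtype=float)
        if draws.size == 0:
            raise RuntimeError(
                f"no bootstrap replicate produced a {est.transition} crossing"
            )
        reliable = draws.size >= 0.5 * b
        if not reliable:
            warnings.warn(
                f"only {draws.size}/{b} replicates yielded a "
                f"{est.transition} crossing; interval flagged unreliable",
                stacklevel=2,
            )
        lo, hi = quantile_pair(draws)
        results.append(
            BootstrapResult(
                transition=est.transition,
                b_requested=b,
                b_effective=int(draws.size),
                samples=draws,
                ci_low=lo,
                ci_high=hi,
                seed=seed,
                point_estimate=est,
                reliable=reliable,
            )
        )
    return tuple(results)
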