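# Methods

## Model

Occupancy of an island by a taxonomic group is recorded as an ordered
state Y ∈ {0, 1, 2+} (counts are bucketed at two or more species, since
higher counts are rare on real archipelagos and the comparisons of
interest stop at coexistence). The cumulative-logit model

    logit P(Y ≤ j) = θⱼ − η,   η = β·x,   θ₁ < θ₂

assumes proportional odds: one slope vector shared by both category
transitions, with the cutpoints carrying the shift between them. The
sign convention θ − η (the one used by the R `clm`/`polr` family) makes
a positive area slope mean richer states on larger islands; all
downstream modules assume it. Predictors are log₁₀ area (km²) and
log₁₀ isolation (km); both must be strictly positive, and islands
recorded with zero isolation are rejected unless the caller explicitly
supplies a measurement-resolution floor (silent flooring is never
applied, since a zero policy is a substantive choice).

Five candidate models are fitted: area; isolation; area + isolation;
area × isolation (always with both main effects, so K = 2 cutpoints +
3 slopes); and the cutpoints-only random-occurrence null. Selection is
by plain AIC (not AICc), with Akaike weights reported both over all
five models and over the main-effects subset {area, isolation, random},
and McFadden's pseudo-R² against the null. Weights are stored at full
precision; the table renderer rounds to two decimals with ">0.99" /
"<0.01" endpoints and a leading-zero-free R², the conventions of the
field's printed selection tables.

## Fitting

Maximum likelihood by BFGS on the negative log-likelihood with an
analytic gradient. The cutpoint order constraint is enforced by
optimizing (θ₁, log(θ₂ − θ₁)); estimates are reported on the natural
scale. Starting values are the closed-form null MLE (logits of the
empirical cumulative state proportions, lightly clipped away from 0/1)
with zero slopes, so fits are deterministic — no random restarts.
Convergence: scipy's BFGS success flag, with a fallback gradient-norm
check at 1e-5; default gtol 1e-8, max 500 iterations. Category
probabilities are floored at 1e-300 before logging (never NaN), and
floored evaluations are counted on the returned fit. Complete
separation is detected as parameter divergence (|β| > 50 on the log₁₀
scale — a slope that steep over a four-decade area range is not a
biological signal) and flagged rather than raised; this matters mainly
inside bootstrap replicates, where separated resamples are simply
dropped. Fits with fewer than two observed states, or fewer than K+1
islands, are refused as unidentifiable.

## Thresholds

The minimum-area thresholds are the crossings of adjacent
category-probability curves of the **area-only** model along the
log₁₀-area axis: P₁ over P₀, and P₂₊ over P₁. They are located by a
coarse scan (4,096 points) over the observed log₁₀-area range padded by
±2 decades — generous but bounded, since no finite data can inform a
crossing many decades outside it — followed by Brent root refinement to
|Δx| < 1e-6. Curve differences smaller than 1e-12 are treated as zero
before sign analysis: in the far tails both probabilities underflow and
the difference is rounding noise, which would otherwise fabricate sign
changes. A genuine second sign change is impossible under the model and
raises (it would indicate a bug), and thresholds are never reported
from unconverged fits.

For this model the crossings have a closed form: both exist iff
d = θ₂ − θ₁ > ln 2, and then with c = ln(1 − 2e^(−d)),

    x*₀→₁ = (θ₁ − c)/β,   x*₁→₂₊ = (θ₂ + c)/β.

The search-based estimator is the implementation (it mirrors how the
statistic is defined and generalizes beyond the logit link); the closed
form supplies generative truths for simulations and an independent
check in the tests. Thresholds always come from the area-only model
even when the additive model carries some weight: the statistic is
defined on the incidence-versus-area curves of the AIC-selected model
family, and adding a negligible isolation term would make thresholds a
function of an arbitrary reference isolation.

## Bootstrap

Nonparametric percentile bootstrap, resampling whole islands with
replacement. Each replicate refits the area-only model (warm-started
at the full-data optimum — same likelihood surface, fewer iterations)
and re-runs the crossing search for both transitions from the same
resample stream, preserving their dependence. Replicates that fail —
fewer than two distinct states in the resample, non-convergence or
separation, or no crossing in the search interval — are dropped, not
retried (retrying would bias toward easy resamples), and reported via
`b_effective`; a result with `b_effective < b/2` is flagged unreliable.
Quantiles use the linear-interpolation (type 7) definition, the default
of both R and NumPy, so interval endpoints are reproducible across
implementations. Randomness: one user seed feeding
`numpy.random.SeedSequence.spawn`, one substream per replicate, making
results bit-identical for identical (data, seed, b).

## Age check

Sparse and unreliable island ages preclude joint modeling, so age
enters as a confounding check: the area-only model is fitted on all
islands, each aged island gets the residual (observed state minus the
modal predicted state, an integer in −2…2; modal ties break toward the
lower state, a deterministic and conservative rule), and the residuals
are regressed on log₁₀ age by OLS. A slope near zero says age adds
nothing beyond area. No formal test machinery beyond the line and R²
is built in; the null simulation in the tests computes significance
externally.

## Synthetic archipelagos

The generator draws log₁₀ areas from a normal size spectrum (default
mean 0, sd 1 — a lognormal area distribution spanning roughly four
decades, matching the shape of Gulf-of-California-style island tables:
most islands under 10 km², a few over 100 km²), log₁₀ isolations
jointly normal with configurable correlation (default mean 0.3, sd 0.6
in log₁₀ km, i.e. typically a few km from the mainland), states from
the cumulative-logit model at the true parameters, and ages (ky,
default ~12 ky median, lognormal) on a random subset of islands
(default 30%), independent of state — giving a true-null fixture for
the age check. States above 2 are never generated; the loader's
bucketing of raw counts is exercised separately with hand-made tables.

`fixture_83()` is a packaged, seed-fixed 83-island synthetic table.
Its generative parameters (θ = (0.389, 3.259), β = 2.0 for
rattlesnakes; θ = (0.105, 2.007), β = 2.0 for colubrids; shared
geography, independent states) were chosen so the TRUE analytic
crossings sit at 1.8 / 37.1 km² and 1.7 / 6.7 km² respectively — the
reported threshold scale for the two snake groups this kind of analysis
was built for — with a slope of 2 per log₁₀ km² giving a realistically
sharp incidence transition. The packaging seed is the first integer at
which the realized table satisfies the fixture contract (area model
ranks best by AIC for both groups, both crossings exist, every state
has at least five islands). What a fixture analysis does *not* show:
agreement of fitted values with any real survey — at n = 83 the fitted
thresholds scatter around the generative truths (e.g. a 2+ threshold of
~51 km² against a true 37.1), and the fixture's pseudo-R² is lower than
a real table with strong geographic clustering would give.

## Problem sizes and calibration checks

The test suite verifies the likelihood core against a three-stage dense
grid search (final spacing 1e-3) on a 12-island toy and against
statsmodels' `OrderedModel` on the fixture; crossing existence against
a brute-force 1e-4 grid scan; slope recovery (|β̂ − β| < 0.1 at
n = 2000, ≥ 80/100 seeded runs); and bootstrap coverage of the analytic
threshold (200 archipelagos of n = 200, b = 1000, nominal 95% ± 4
points). The acceptance script uses b = 10,000 bootstrap replicates on
the fixture and 50 recovery runs at n = 2000 — sizes chosen to keep the
full reproduction inside a coffee break on one core while leaving
Monte-Carlo error well below the quantities' own precision.

## Known limitations

- Only the logit link and strictly proportional odds; no partial or
  non-proportional odds, no more than three ordered states.
- Thresholds are a property of the area-only fit; no multimodel
  averaging of coefficients or thresholds.
- Percentile intervals only (no BCa or basic bootstrap) — the
  procedure under study is strictly the nonparametric percentile one.
- The generator reproduces statistical, not geophysical, structure;
  isolation is "distance from the peninsular mainland as given" with no
  GIS computation, and age units are whatever the table uses,
  consistently.
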