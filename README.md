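# minarea

Minimum island-area thresholds from ordinal species incidence functions.

## The problem

On land-bridge archipelagos, which islands a taxonomic group occupies is
largely a question of island area: extinction risk falls as area (and
hence population size) grows. Classical incidence-function work fits a
binary logistic regression of presence/absence on island attributes.
`minarea` extends that to an **ordinal** incidence function: the number
of species of a group present on an island — bucketed into the ordered
states 0, 1, and 2-or-more — is modeled as a function of log₁₀ island
area and log₁₀ isolation with a cumulative-logit (proportional-odds)
model. The payoff of the ordinal view is a pair of interpretable
statistics per group:

- the **minimum area for supporting one species** — the area at which
  the fitted probability of one species present first exceeds that of
  zero species, and
- the **minimum area for supporting two or more species** — the area at
  which P(2+) first exceeds P(1).

The first speaks to energetic/ecological efficiency (how small an
island can sustain any population); the second to the intensity of
competition within and between species of the group (how much more room
coexistence requires). Comparing these thresholds between groups —
e.g. rattlesnakes versus colubrid snakes on desert islands — needs only
two or more species per source pool, sidestepping the difficulties of
comparing species–area curves across groups of very different richness.

## The model

For island *i* with ordered state *Yᵢ* ∈ {0, 1, 2+} and linear
predictor η*ᵢ* = **β**·**x**ᵢ (x = log₁₀ area, optionally log₁₀
isolation and their product),

    logit P(Yᵢ ≤ j) = θⱼ − ηᵢ ,   j = 0, 1,   θ₀ < θ₁ ,

so category probabilities are differences of adjacent logistic curves
and a positive area slope moves probability toward richer states on
larger islands. Five a priori candidate models (area; isolation;
area + isolation; area × isolation with both main effects; and a
cutpoints-only random-occurrence null) are fitted by maximum likelihood
and compared by AIC, Akaike weights w<sub>i</sub> ∝ exp(−ΔAIC<sub>i</sub>/2),
and McFadden's pseudo-R² = 1 − logL(model)/logL(null).

Thresholds are the crossings of adjacent category-probability curves of
the area-only model along the log₁₀-area axis, located by grid scan and
bisection; for this model they exist iff θ₁ − θ₀ > ln 2, and then are
unique. Uncertainty comes from a nonparametric percentile bootstrap:
islands are resampled with replacement, the model refitted and the
crossings re-estimated per replicate, and the 0.025/0.975 empirical
quantiles give the 95% CI.

## Worked example

The package ships a seed-fixed **synthetic** 83-island table
(`fixture_83()` — a stand-in archipelago with the same statistical
structure as a Gulf-of-California-style island system, *not* real
survey data):

```python
from minarea import (fixture_83, to_ordinal_dataset, build_selection_table,
                     render_table, thresholds_report, bootstrap_thresholds)

records = fixture_83()
data = to_ordinal_dataset(records, "rattlesnakes")
print(render_table(build_selection_table(data)).to_string(index=False))
for res in bootstrap_thresholds(data, b=10_000, seed=1):
    print(f"{res.transition}: {res.point_estimate.area_km2:.1f} km^2 "
          f"(95% CI: {res.ci_low:.1f}-{res.ci_high:.1f}), "
          f"effective replicates {res.b_effective}/{res.b_requested}")
```

prints

```
      Model        Group  K    AIC  dAIC  AICw AICw_main  R2
       area rattlesnakes  3 120.29  0.00  0.66     >0.99 .22
  isolation rattlesnakes  3 151.14 30.86 <0.01     <0.01 .01
   additive rattlesnakes  4 122.25  1.96  0.25        NA .22
interaction rattlesnakes  5 124.13  3.84  0.10        NA .22
     random rattlesnakes  2 150.04 29.75 <0.01     <0.01  NA

zero_to_one: 1.7 km^2 (95% CI: 0.9-3.8), effective replicates 10000/10000
one_to_two_plus: 51.4 km^2 (95% CI: 14.0-347.6), effective replicates 9978/10000
```

Reading this: the area-only model wins decisively (ΔAIC ≈ 31 over the
isolation and null models; among main-effects models its weight is
>0.99), so area, not isolation, structures occupancy. An island of
~1.7 km² is where one resident rattlesnake species becomes more likely
than none; supporting a second species takes ~51 km², with a wide upper
CI because few islands are that large. The same calls with
`--group colubrids` / `"colubrids"` give the colubrid table.

The same analyses are available from the shell via the `minarea` CLI
(`simulate`, `fit`, `select`, `thresholds`, `bootstrap`, `age-check`).

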