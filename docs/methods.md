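# Methods

## Destination choice and the accessibility logsum

The core model is a multinomial logit over destinations. A trip-maker in
zone *i* assigns destination *j* the systematic utility
`V_ij = β t_ij + X_j γ` and chooses with probability
`P_ij = exp(V_ij)/Σ_{j'} exp(V_ij')`. The log of the denominator,
`A_i = log Σ_j exp(V_ij) + C`, is the expected maximum utility of the
choice set and serves as the accessibility of zone *i*: it rises with
lower impedance, better destinations, and more destinations. `C` is not
identifiable, so the package fixes `C = 0` and labels every logsum
surface a *relative* measure; a `standardized()` method subtracts the
regional mean (unweighted by default, household-weighted on request)
when a "below regional average" classification is needed.

Two impedance forms are supported. `t_auto` is the car travel time in
minutes. `mcls` is the logsum of a fixed-coefficient mode-choice model
over driving, transit, and walking:

* `V_auto   = −0.028·t_auto`
* `V_transit = −4 − 0.028·t_iv − 0.056·wait − 0.372·access`
* `V_walk   = −5 − 0.028·t_walk − 1.12·d (d < 1.5 mi) / −5.58·d (d ≥ 1.5 mi)`

These coefficients are configuration (`ModeCoefficients`), not estimated
quantities; the defaults are values typical of regional travel-demand
models and can be replaced wholesale for another region. Unavailable
modes are *dropped from the logsum* rather than entered at a large
penalty — a missing cost component means the mode does not exist for
that pair, and a zero or even large-but-finite cost would still leak
utility into the sum. A pair with no available mode is unreachable and
is excluded from choice sets and accessibility sums.

The walk-distance term is written with a coefficient *selected* by the
1.5-mile threshold and applied to the full distance, producing a utility
discontinuity at 1.5 miles. This "literal" dialect is the default; a
"marginal" dialect (`b_short·min(d,1.5) + b_long·max(d−1.5,0)`) gives
the continuous alternative. The literal reading is kept as default
because it reproduces the stated mode-utility arithmetic exactly;
sensitivity to the dialect is confined to walk trips near 1.5 miles.

When driving dominates (transit sparse, walks long), MCLS collapses to
`−0.028·t_auto` pairwise, so a model estimated with MCLS impedance must
return a coefficient near `−β_car/0.028`. This near-collinearity is a
deliberate test surface: the suite fits both forms on an auto-dominated
synthetic region and checks the proportionality and that the non-nested
likelihood test cannot distinguish the two fits.

## Estimation

Datasets are built by simulating trips from an aggregate flow table:
each of `n_trips` (default 10,000) draws a (zone, chosen resource) pair
with probability proportional to the observed flow count, then pairs it
with `n_alt` (default 10) non-chosen resources sampled uniformly without
replacement, independently per observation. Uniform sampling of
alternatives leaves the MNL estimator consistent without correction
terms; the cost is some efficiency, which is acceptable at these sample
sizes. An observation containing any unreachable pair or non-finite
covariate is dropped whole — never thinned — so every retained
observation keeps the same choice-set size; drop counts are logged and
recorded on the dataset.

The likelihood is maximised by Newton–Raphson with analytic score and
Hessian and step-halving, declaring convergence when the largest score
component falls below 1e-6 (never on parameter change, which can stall
early on flat ridges). A non-positive-definite Hessian triggers a BFGS
fallback. Two failure modes are detected explicitly: a covariate that is
constant within every choice set differences out of the logit and raises
a non-identification error before optimisation (the model can instead
drop such covariates with a warning, which the CLI enables because small
synthetic regions occasionally draw an amenity that every resource
shares); and perfect separation, which in a logit drives every chosen
probability to one along a ridge of unbounded likelihood — it is
detected at the stopping point (all chosen probabilities within 1e-6 of
one) rather than by coefficient blow-up, because the vanishing gradient
otherwise masquerades as convergence.

Standard errors come from the inverse observed information at the
optimum; t-statistics are plain Wald ratios, with no sandwich or cluster
correction. The null log-likelihood is the equal-shares model over each
observation's choice-set size, `Σ_i ln(1/J_i)` (with the default design,
`n·ln(1/11)`), and McFadden's rho-squared is `1 − LL/LL0` under exactly
that convention — the one that reproduces published rho-squared values
from their printed log-likelihoods and sample sizes to three decimals.

Non-nested specifications fitted to the same observations are compared
with the Horowitz bound in its adjusted-rho-squared form: with
`z = ρ̄²_high − ρ̄²_low` and `ρ̄² = 1 − (LL − K)/LL0`,

    p ≤ Φ( −√( −2 z LL0 + (K_high − K_low) ) ),

reported explicitly as a one-sided upper bound.

## Accessibility surfaces and equity accounting

The logsum surface applies the fitted coefficients to the *full*
resource inventory — alternative sampling was an estimation device only.
Buffer access uses the closed inequality `t_ij ≤ t*` (a resource exactly
at the threshold counts), with default thresholds of a 5-minute drive
for grocery stores, 5-minute walk for parks, and 10-minute drive for
libraries; the cumulative variant counts qualifying resources. Gravity
access is `Σ_j S_j f(t_ij, β)` with exponential decay by default and a
power option whose travel time is floored at one minute to keep the
kernel finite; the decay form and rate are explicit configuration
because no single convention is standard.

Equity accounting classifies a zone as low-access under the buffer
definition when it is outside *all three* resource buffers, and under
the utility-based definition when its logsum is *strictly below* the
regional mean for all three resource types. Household counts sum zone
households over flagged zones; low-income counts attribute each zone's
households fractionally by its low-income share (aggregate zone data
admit nothing finer) and round half-even once, at table level, so the
inclusion bounds (overlap ≤ each marginal, low-income ≤ total) hold
exactly.

## The synthetic region

The generator emulates a mid-size suburban county with one dense
north–south corridor. Defaults, chosen once to resemble published
block-group summary statistics for such a county:

* 50 zones on a jittered grid over a 20 × 40 km rectangle; households
  lognormal with median 500; low-income share a logistic function of
  distance from the corridor (≈0.27 at the spine falling to ≈0.03 at the
  periphery, mean ≈0.16) plus noise.
* 30 parks, 12 grocery stores, 8 libraries, positioned with
  Laplace-distributed offsets from the corridor. Park acreage lognormal
  (median ≈4.5 acres), library square footage lognormal (median ≈15k
  sqft), registers 1 + Poisson(6); amenity indicators Bernoulli with
  rates between 0.1 and 0.7.
* Skims from straight-line distance × 1.3 circuity: driving at 40 km/h
  plus a 2-minute terminal time, walking at 4.8 km/h and available only
  within 10 km, transit at 25 km/h only when both endpoints lie within
  3 km of the corridor, with wait = half a 15-minute headway and
  access/egress walked to the spine; all paths capped at 2 hours.
* Generating coefficients mirror full-model estimates for this kind of
  study (car time ≈ −0.27 to −0.31 per minute; log-size elasticities
  ≈ 1.2–1.3; a strong playground draw).
* Visit flows: 200,000 device-trips drawn from the generating model over
  the full choice set, origins proportional to households. The flow
  volume deliberately exceeds the 10,000-trip estimation sample by 20×:
  commercial location-based-services tables aggregate far more devices
  than any estimation sample, and resampling an estimation dataset from
  a flow table of equal size would double-count sampling noise and
  understate standard errors (empirically, Wald coverage drops from
  ~95% to ~83% if the two sizes are equal).

One global seed expands into fixed per-stage offsets (region +11, flows
+13 + rtype index; trip sampling +101 and alternative sampling +202
relative to the dataset seed), so every stage is independently
reproducible.

What the generator does *not* emulate: street-network routing (distances
are scaled Euclidean, so skims are metric up to the terminal time —
real networks are not), device-location measurement error, trip-purpose
misattribution, within-zone heterogeneity of trip-makers, and any
segmentation of preferences by demographic group (flows come from a
single pooled model). Passing recovery tests therefore validate the
estimation machinery and the measure constructions, not the behavioural
realism of any particular coefficient set on real data.

## Problem sizes in tests

The recovery suite runs 20 replicates of the default region (50 zones,
30 parks, 10,000 trips, 10 sampled alternatives) and checks that 95%
Wald intervals cover the generating coefficients at the nominal rate
(binomial test at α = 0.01) with median absolute relative bias of the
impedance coefficient under 5%; a replicate whose drawn amenities are
constant across all resources estimates only the identifiable terms.
The collinearity and dispersion checks use one default-scale region
each; the remaining suites run on hand-built fixtures of a few zones and
resources where every expected value is hand arithmetic, a closed form,
finite differences, or a dense grid search.

## Known limitations

* Coordinates are assumed planar and projected; there is no CRS
  handling.
* The estimator covers plain MNL only — no nested, mixed, or
  latent-class structures, and no importance sampling of alternatives
  with correction terms.
* Buffer/cumulative and gravity measures use a single mode's time; a
  generalised-cost buffer is out of scope.
* Low-income attribution is fractional at zone level; with strongly
  skewed within-zone income distributions the counts are approximations.
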