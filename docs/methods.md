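# Methods

## Epidemic and production model

Human agents carry one of five health states: susceptible, infected
undetected, infected detected (always quarantined), recovered (permanently
immune) and dead. Transitions:

- **Infection.** A susceptible agent within the contact radius of `g`
  circulating infectious agents (undetected infected; quarantined and dead
  agents never transmit) escapes infection over an activity block of `T`
  one-hour ticks with probability `(1 − ν·IR)^(g·T)`, where `IR = 0.337` is
  the per-contact-event infection probability and `ν` is the probability
  per tick that a nearby pair actually has a transient contact event
  ("near or passing"). This aggregation is exact for per-tick Bernoulli
  contacts at static positions and is what makes 100-repetition
  experiments cheap.
- **Detection.** A new case is detected with probability 0.51 — the
  detected-to-total case ratio — decided once at onset (default
  `detection_mode="onset_only"`). Detected ⇒ quarantined at home until
  recovery. The alternative `daily_hazard` mode additionally re-tests
  undetected agents every day at the same rate; under it nearly every case
  is quarantined within ~2 days, the mean infectious period collapses to
  about a day, and no contact-rate setting sustains epidemic activity
  beyond one month — which is why onset-only is the default: the 49%
  never-detected cases circulate for their full recovery time and carry
  the multi-month dynamics.
- **Recovery/death.** Recovery time is uniform on 14..42 integer days. At
  expiry the agent dies with probability IFR = 0.0188, else recovers; a
  fresh recoveree immediately returns to the susceptible pool with the
  recovered-to-susceptible probability (default 0.9), else is immune for
  the rest of the run. Applying re-susceptibility once, at the moment of
  recovery, is a modelling choice; the delayed return of recovered agents
  is what produces damped epidemic cycles (second waves) when the
  probability is high.

Days have a 16-tick home block and an 8-tick work block. Rice-mill (RMU)
workers commute every day (essential sector); office workers and students
commute on weekdays; freelancers roam to a random point in their city
during work blocks. Under a travel restriction, students stay home and
office workers attend with probability 0.25 per work block (expected
office-time share 25%). Restrictions are re-evaluated every 7 days per
city: restricted iff the city's per-capita death rate is above the
cross-city mean, its per-capita recovery rate below the mean, or its
active-case count above the mean (strict comparisons; zero-population
cities excluded).

Production: each day every RMU adds `rate × (workers neither quarantined
nor dead)` tons, at 1 ton/worker/day by default; undetected infected
workers still work. The normal year has no disease, so normal-phase
production is the fully staffed constant, and with infection rate 0 the
pandemic year equals it exactly.

### Calibration of the unpublished scales

The source case study does not state population sizes, mill counts,
contact radius or per-worker throughput, so its absolute production and
case magnitudes are not reproducible and not attempted. Defaults were
chosen once for epidemiological plausibility and speed: 5 cities × 100
houses × 3 inhabitants (1,500 agents), 2 RMUs / 4 offices / 2 schools per
10×10 city rectangle, contact radius 0.8, contact-event rate ν = 0.04 per
tick, workstation scatter sd 2.0 around each job site, and 5 undetected
seed cases per city at the start of the pandemic year. Under these
settings an epidemic ignites reliably, runs for months, triggers
restrictions, and shows the qualitative sensitivity signature: multi-wave
case curves are common at re-susceptibility 0.9 and essentially absent at
0.6. Tests assert that direction statistically, not any published
frequency.

## Validation statistics

`O_i = (mean_normal − mean_covid)/mean_normal` pools production over all
regions before the per-repetition ratio (region weighting is a choice; the
pooled form weights regions by output). The GoF statistic
`χ² = Σ (O_i − E)²/E` with constant `E = 0.0328` retains H0 iff strictly
below `chi2.ppf(1 − α, k − 1)`. Note the test's power is low for small
deviations because `E` is small and constant; only drastic departures
(production collapse) are rejected at k ≲ 100.

Wave counting smooths daily new detected cases with a centered 14-day
moving average; a wave is a maximal run above 10% of the global smoothed
peak, and runs separated by sub-threshold gaps shorter than the window
merge. Window and threshold are configurable; the defaults suppress
reporting noise while separating genuine resurgences.

## Uncertainty sets

Scenario "all_data" keeps every pandemic-phase (day, value) point per
region; "top15" keeps the `ceil(0.15·n)` largest values (ties: earlier
day, then lower repetition), retaining original day indices. The nominal
is the per-day mean of the scenario dataset; deviations are
`u = value − nominal(day)`. The polyhedron is the 2-D convex hull of the
`(t, u)` cloud (monotone chain, collinear vertices dropped, rows
normalized to unit normals) — minimal by construction, one inequality per
hull edge. Degenerate collinear clouds become a 2-row slab padded by 1e-6
tons so the set has interior; that slab is unbounded along its line, the
one deliberate exception to boundedness. The independent cross-check in
the tests is Qhull (`scipy.spatial.ConvexHull`) plus an LP certificate of
row non-redundancy.

## Robust counterpart

The optimizer is a single-period model, so the 2-D per-region sets are
consumed through a planning-day slice: at day `t*` (default: the pandemic
day with minimal total nominal production — the worst planning day;
clamped into each region's own day coverage for the sparse top-15%
datasets) each region's nominal capacity is the day-`t*` nominal and its
scalar uncertainty is the interval `{u : (t*, u) ∈ set}`, floored so
capacity cannot go negative.

For each hub flow-balance constraint the worst case over `{ζ : Mζ ≤ q}`
enters by LP duality as `P = Σ f̄ y − qᵀv`, `Mᵀv = y-loading`, `v ≥ 0`:
maximizing fulfillment drives `qᵀv` to the dual optimum, which equals the
worst-case (minimal) inflow. The cost objective becomes an epigraph
`z ≥ nominal transport cost + qᵀv₁ + qᵀv₂` with the symmetric
(worst-case-maximal) dual blocks. With the singleton set {0} every dual
term vanishes and the robust counterpart is the nominal model; on small
instances the optimum equals an explicit scenario-expanded MILP over the
hull vertices (both facts are tested). Demand-side attachments use the
same machinery and are off by default; transport-cost uncertainty is not
attached.

The fulfillment objective is implemented as revenue of delivered tons,
`Σ v_ci d_ci Σ_j w_cji` (Rp), rather than price-weighted fulfillment
*fractions*: `v` is a price per ton, so only the tons form is
dimensionally a value, and the fraction form would strictly prefer the
smaller-demand member of two equally-priced regions, contradicting the
distance tie-break the case study describes. With the tons form,
equally-priced regions tie at stage 1 and the cost stage resolves the tie
toward the cheaper destination.

Scalarization is lexicographic by default: stage 1 maximizes fulfillment;
stage 2 minimizes cost subject to the stage-1 value within a relative
tolerance of 1e-9. The tolerance is deliberately tight: fulfillment values
sit near 1e10 Rp, and a looser 1e-6 slack would let the cost stage trade
~0.03 tons of deliveries for transport savings, visible at the 3-decimal
reporting precision. MIP relative gap is 1e-9 (HiGHS via
`scipy.optimize.milp`); the fixture-size problems solve in well under a
second. A weighted scalarization (`max fulfillment − λ·cost`) is
available.

`verify_robustness` re-evaluates the uncertain constraints at every hull
vertex plus Dirichlet-sampled interior points and reports the maximum
violation; robust solutions show violations at solver tolerance, nominal
solutions exposed to adverse deviations do not.

## The West Java fixture

Published values: worst-case capacities per scenario, three demands, the
price ordering (Depok City highest; Bekasi City = Bekasi Regency second)
and the relative-distance statement (Bekasi City closer to Depok City).
Everything else is constructed: planar coordinates approximating the real
road-relative geography (Bekasi City ≈ 22 km from Depok City, Bekasi
Regency ≈ 35 km beyond Bekasi City, the Bogor corridor south of Depok),
transport cost 3,000 Rp/ton/km × Euclidean distance, handling 150,000
Rp/ton, hub development 6×10⁷ Rp. Candidate hub sites are the three
consuming regions — the two Bogor regions are producers only; allowing a
hub there would let a producing region host a zero-inbound depot, which
the case never does. The per-region uncertainty sets are hulls of
synthetic rectangular deviation clouds whose slice at the planning day
(180) spans `[worst-case − nominal, +2% of nominal]`, with the nominal set
to 1.10 × that scenario's worst case (the nominal is the scenario
dataset's own daily mean, which sits near its worst case). These choices
were verified to make the published hub/flow pattern the unique
lexicographic optimum of both scenarios; tests assert the published
outputs and the stated orderings, never the invented magnitudes.

## Synthetic series generator

`SyntheticSpec` draws i.i.d. normal production around a baseline
(1,000 ± 50 tons/day per region) in the normal year and scales the
baseline by `1 − dip` (default 0.0328, the expected pandemic reduction)
over a configurable window of the pandemic year, truncated at zero. It
emulates the magnitude structure of a simulated series — a stationary
normal year and a proportionally reduced pandemic year — but none of the
epidemic mechanics: no waves, no restriction feedback, no worker-level
autocorrelation. Pipeline tests on synthetic data therefore exercise the
statistics, set construction and optimizer wiring, not epidemiology; only
the agent-based runs speak to epidemic behaviour, and neither speaks to
real-world West Java magnitudes.

## Problem sizes used in tests

Acceptance-style checks run at deliberately compact scales: the case-study
solves are instant; hull cross-checks use 100 clouds of ≤ 200 points;
robust-counterpart cross-checks use 20 instances of ≤ 3×3×3 with ≤ 6
hull vertices; the sensitivity trend uses 30 repetitions per probability
(the published analysis used 100) on the default five-city population.

## Known limitations

- No inter-city travel or commuting: agents act within their hometown, so
  cities are epidemiologically independent except through the shared
  restriction averages.
- Grain supply to mills is unlimited; only labour limits output.
- The chi-square gate has little power against moderate deviations (see
  above); it is a coarse sanity gate, not a calibration.
- Per-region uncertainty is attached independently (no cross-region joint
  sets), and the single-period optimizer sees one planning day, not the
  full season.
- The paired worst cases are constraint-wise: production is at its minimum
  in the flow balance and at its maximum in the cost epigraph
  simultaneously, the standard (conservative) robust-counterpart reading.
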