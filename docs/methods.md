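# Methods

This note records the model as implemented: its assumptions, the parameters
that matter, the numerical choices made where the design was genuinely open,
and what the synthetic landscapes used in the tests do and do not show.

## Model structure and scheduling

The simulator is an individual-based model on vector-polygon landscapes.
Four polygon parameter maps (movement, food, risk, suitability) plus a point
release map define the environment; all coordinates are planar meters and
layers are assumed pre-projected (no CRS math is performed). Each map must
tessellate the shared rectangular extent — a gap is a validation error,
because every animal location must yield attributes for all four maps. A
point falling on a shared edge resolves to the feature with the smallest id;
the tie-break exists purely for determinism. The four maps may use
independent tessellations. All vector I/O is GeoJSON; it is plain JSON, reads
and writes without extra dependencies, and keeps every output diffable.

Time is discrete: step length (minutes), season length (days), years, and
the hour the season starts. Day boundaries fall at midnight, so a season
started at 18:00 rolls to day 2 after six hours. The inter-dispersal period
is a single discrete step (resident survival, then breeding). Map-swap
events are instants (year, day, hour); the map in force at time t is the
replacement of the latest event with timestamp ≤ t, making the schedule
piecewise constant and right-continuous. When a suitability map is swapped,
occupancy flags are re-projected onto the new map from the live home-range
registry, which is authoritative.

Each step, residents take their aspatial mortality draw first (so freed
ranges are available within the step), then dispersers act in id order. Ids
are reassigned each year geographically, north → south then west → east.
The per-animal sub-step pipeline is fixed: bout check, modifier resolution,
vigilance draw, activity-mode check, movement, energy cost, foraging gain,
starvation check, predation draw, perception/memory update, settlement
attempt. The intra-step ordering is this implementation's choice; only the
sequential inter-animal order is inherent to the model. All randomness comes
from one seeded numpy Generator consumed in pipeline order, which is what
makes (config, seed) determine every output byte.

## Movement

Headings follow a correlated random walk. Turning angles are wrapped
Cauchy(0, ρ), sampled by the exact inverse-CDF transform
θ = 2·atan(((1−ρ)/(1+ρ))·tan(π(u−½))); ρ = 1 short-circuits to the previous
heading bit-exactly so straight-line paths are exactly straight. Step
lengths are Normal(μ, σ) clamped at 0 (clamping, not redraw — the bias is
negligible at the σ/μ ratios used and the loop is bounded).

A step's tortuosity, length, energy cost — and the food and risk attributes
used later in the pipeline — are all taken from the polygon containing the
step's *origin*: one deterministic query point per step.

The step ray is walked through the movement tessellation. At each boundary
between different features the animal crosses with probability
P = q_to/(q_from + q_to). Any crossing rule only needs to favour
higher-ranked classes while honouring the absolutes; this odds form was
chosen because it is symmetric, invariant to rescaling the ranks, and makes
the absolutes exact — a rank-0 class is never entered, and an animal can
always leave one. Each boundary hit within
a step gets an independent draw, in traversal order. A refused crossing
truncates the step at the boundary and forfeits the remaining distance (no
heading redraw); the map extent reflects specularly. Numerically, a refused
crossing stops just short of the boundary with a guaranteed perpendicular
clearance of 1e-9 m (escalating pull-back), and crossing detection uses a
5e-10 m threshold below that clearance — the pairing guarantees a boundary
refused in one step cannot be silently tunnelled in the next, which is what
makes the never-enter guarantee hold over arbitrarily long walks. When the
clearance cannot be gained (the animal is pinned against the boundary), the
step is forfeited entirely rather than letting the clearance erode.

The perceptual window of a step is the realized path buffered by the
(modifier-resolved) perception radius, with round caps; radius 0 yields an
empty window.

## Behaviour

Modifiers multiply baseline parameters by sex, behavioural state
(risky/safe × searching/foraging), hour-of-day window and date window.
Windows are half-open [start, end) — a value is never modified twice at a
boundary — and hour windows may wrap midnight. Probabilities and tortuosity
are clamped to [0, 1] after multiplication. Absent keys multiply by 1, so a
run with every multiplier at 1 is byte-identical to one with the machinery
disabled; that identity is tested and is the package's null-model
convention.

The activity-mode switch is strict: foraging iff E < threshold (ties go to
searching, so the boundary is deterministic); it is symmetric in both
directions and disabled by `threshold=None`. Vigilance takes one uniform
draw per step compared against the current mode's switching probability;
animals start each season risky. Run lengths under a constant probability p
are geometric with mean 1/p (tested against the closed form).

Activity/rest bouts are drawn per animal per season: alternating
Normal(mean, sd) durations (hours), truncated below at one time-step,
starting active at the season's start hour. The mean active+rest cycle must
tile 24 h exactly (12+12 once a day, 4.5+7.5 twice, ...); a continuously
active species (rest mean and sd 0) gets one season-long bout. Resting
animals do nothing at all — no movement, cost, foraging or predation — on
the reading that mortality and foraging are scoped to dispersal activity.

## Energetics and mortality

Within a step, cost and gain are applied together and starvation (E < E_min)
is evaluated once afterwards — a single evaluation point avoids
order-dependent double deaths. Gains clamp the reserve at E_max. Prey sizes
are Normal clamped at 0, consistent with step lengths. Every dead animal
carries exactly one cause — starvation, predation, or season_end — so
cause-specific mortality rates partition the overall rate by construction.

## Memory and home-range establishment

Memory is an append-only, time-stamped sequence of perceived regions with
suitability/occupancy flags; the effective status at a point is the latest
record covering it. The eligible region for settlement (suitable, not
occupied by the animal's own sex) is maintained incrementally: each new
record first masks the old eligible region, then rejoins it if its status
qualifies — an exact realisation of latest-wins that keeps settlement
attempts O(1) in the number of records. Memory persists across failed
settlement attempts; nothing in the model suggests a reset. There is no
memory decay and no perception error.

The settlement trigger counts active steps or distinct suitable, un-occupied
suitability polygons entered. Once triggered, up to 30 candidate points are
drawn uniformly from the eligible remembered region (batched rejection
sampling from its bounding box, capped at 10^4 draws per point). Candidates
are scored W = Q·exp(−d/w): the exponential proximity kernel has a single
interpretable scale w (meters), a very large w makes selection
distance-blind, and Q is 1 (closest), max-normalized expected food gain
p_capture·prey-size (food), max-normalized survival 1 − p_mortality (risk),
or their product (integrated). Normalizing by the candidate-set maximum
makes food and risk magnitudes comparable without user tuning. The site is
*sampled* with probability ∝ W — selection is quality-weighted but
stochastic.

The range polygon has 12 vertices at a uniformly rotated equal angular
spacing with radii Normal(r0, 0.15·r0) truncated positive, where r0 makes
the regular 12-gon attain exactly the sex's minimum area A_min; generation
retries (≤ 100) until the polygon is simple with area ≥ A_min. The animal
relocates to the chosen center instantly (pathing to it is not re-simulated
and incurs no travel-time hazards). Settlement succeeds iff the polygon,
clipped to suitable habitat minus the union of existing same-sex ranges,
still covers the center and holds ≥ A_min; the *clipped* region is stored as
the home range. Storing the clipped region is what reconciles the
subtract-occupied-area acceptance rule with strictly zero same-sex overlap —
both are enforced, and both are tested. On failure the animal resumes
dispersal and a disc of radius sqrt(A_min/π) around the failed site (the
area the range would have needed) is remembered as unsuitable. Occupancy is
recorded both as flags on the suitability map's features and in the live
range registry; the registry is authoritative for exclusion. Residents
initialized from a roster are assumed already established: their polygons
are clipped only against previously placed same-sex residents, not against
suitability, so roster setups remain robust on arbitrary landscapes.

Dispersers still unsettled at the last season step die (season_end).

## Demography

Inter-dispersal survival is a single Bernoulli trial per resident; deaths
clear occupancy. Surviving females (survival first, then breeding) are
pregnant with probability p_preg; litter sizes are round(Normal(μ, σ)) with
round-half-away-from-zero and negatives mapped to 0; offspring sexes are iid
Bernoulli(p_female). Offspring enter the next season's roster at their
mother's range center. No male requirement is imposed on breeding, mating is
not modeled, and there is no density dependence or age structure.

## Synthetic landscapes and the packaged studies

All end-to-end runs use the synthetic-landscape generator rather than
digitized field GIS layers: grid or
clipped-Voronoi tessellations whose patches draw attribute classes from a
seeded stream, with optional per-class variant maps (e.g. scarce vs
superabundant food) as swap-schedule inputs. Same spec + seed produces
byte-identical files.

Two study conditions are packaged (`dispersim.studies`), sized to run in
seconds while keeping field-realistic parameter scales where they bind:

* **food_swap** — raccoon-frame: 150-day season, 1-h steps, 12 h nocturnal
  activity from 18:00, energy 3750 start / 1800 floor / 10000 ceiling,
  trigger 168 active steps, integrated criterion; a 4 km × 4 km 10 × 10
  matrix with 8 suitable woodlots; food scarce (p_capture 0.18, prey 10,
  cost 2 — slightly negative net energy) for days 1–37, superabundant
  (p_capture 0.9 — strongly positive) days 38–113, scarce again after.
  Sparse suitable habitat and a 30 m perception radius spread settlement
  times across the swap, which is what lets the pre- vs post-swap energy
  split emerge. Home-range minima are 5·10^4 m² so ranges fit inside a
  woodlot patch.
* **threshold_study** — marten-frame: 60-day season, 1-h steps, 4.5/7.5-h
  bouts (SD 0.8 h) from 04:00, energy 4548 start / 5003 ceiling, trigger 270
  active steps, minimum ranges 4.25 / 2.32 km² on a homogeneous suitable
  5 km × 5 km map; searching loses 5 units per active step in expectation,
  and a foraging-state modifier quadruples capture success so foraging gains.
  With the forage/search threshold at 4250, settler energies oscillate
  around the threshold; with the switch off they decline monotonically. The
  starvation floor is set low (1000) so that the switched-off comparison
  runs produce settlers rather than starving, which is what the paired
  comparison needs; a floor near the marten's field value (~3866) would
  confound the contrast with mortality. Bout SDs are 0.8 h — an SD
  comparable to the bout means would make the schedule degenerate; the
  simulator itself accepts any SD ≥ 0.

What these synthetic runs show: the mechanisms (swap-timing energy split,
threshold oscillation, same-sex exclusivity, never-enter classes) operate as
specified. What they do not show: quantitative agreement with any real
landscape — real GIS layers have irregular patch geometry, correlated
attributes across maps, and empirically calibrated ranks and probabilities
that no tessellated fixture reproduces.

## Numerical choices and limitations

* Problem sizes: packaged studies use 10–20 released animals and seasons of
  60–150 days at 1-h steps; Monte-Carlo checks use 10^4–10^5 draws. These
  sizes give closed-form checks tolerances of ~1% while runs complete in
  seconds to tens of seconds.
* Geometry tolerances: map coverage within 1e-6 of extent area; same-sex
  overlap within 1e-6 m²; boundary clearance/detection 1e-9 / 5e-10 m as
  above. A spatial index (STRtree) accelerates point and region queries;
  results are identical with or without it.
* Degenerate inputs: zero-length steps buffer to discs in perception;
  perception radius 0 sees nothing; empty candidate sets leave the animal
  dispersing; empty rosters run to completion with valid empty outputs.
* Limitations: no raster landscapes or reprojection; landscape change is
  scheduled a priori, never state-responsive; no inter-animal interaction
  beyond same-sex range exclusion; no memory decay; floaters do not persist
  across seasons; breeding is aspatial. Shapefile input is not supported —
  convert to GeoJSON.
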