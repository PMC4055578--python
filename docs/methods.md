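# Methods

## Model overview and assumptions

`glossim` propagates a *density* of flies, not individuals: every
operation is a linear (or piecewise-linear) map on a nonnegative field
over the habitat lattice, so runs are exactly reproducible and
population size only sets the output scale.  The cohort is closed — no
reproduction, no immigration — and is followed for a single 6-day
hunger cycle; flies leave the simulation by feeding, being caught or
killed at a bait, dying of background causes, or starving at the end of
day 6.

Space is a grid of square cells (default 200×200 cells of 10 m).  Map
edges adjoin mirror-image copies, so the flux leaving at any edge cell
re-enters there; totals are conserved to floating-point accuracy (the
test suite asserts ≤1e-12 drift per step and a ≤1e-9 global bookkeeping
identity per cohort step, enforced by the engine itself).

## Movement

Each step moves a fraction *h*/4 of every cell's flies toward each of
the four orthogonal neighbors.  *h* calibrates the orthogonal walk
against the classical isotropic walk; the closed forms used are

* classical mean displacement after *n* steps of length *x*:
  *D* = *x*·√(π·*n*)/2 (the Rayleigh mean; 124.07 m at *x* = 10,
  *n* = 196, conventionally printed 124.1 m);
* orthogonal displacement scaling *d*(*h*) = *d*(1)·√*h*;
* matching *x·h·*√*n* = *d*(1)·√*h*, giving
  *h* = (*d*(1)/(*x*√*n*))² = π/4 exactly, or 0.7858 when solved from
  the rounded 124.1 m anchor.  The package default is 0.7858.

Displacement statistics are density-weighted means of center-to-center
Euclidean distance from the seed cell (not RMS — the 124.1 m anchor is
a Rayleigh mean).  On homogeneous habitat the deterministic operator
reproduces the closed form within 3% at *n* = 196 and scales as √*n*
within 2% over *n* = 100…1600; a seeded stochastic single-walker
simulation with the same rules agrees within 3 standard errors (test
suite, 10⁵–1.2·10⁵ walkers).

**Vegetation crossing.** Entry probabilities are good 1.0 / poor 0.1 /
no-go 0.0.  Movement into an equal-or-better cell always succeeds;
into a worse cell with probability *p(dest)/p(source)*; failures
return to the source-cell center.  This rule satisfies detailed
balance, so the stationary density is proportional to entry
probability within each connected habitable component; `stabilize`
iterates from a uniform field over habitable cells until the largest
per-cell change is below `tol` (default 1e-10, cap 10⁶ iterations).
Flies in poor cells use the same movement kernel — vegetation enters
only through the crossing ratio.

## Baits and stimulus footprints

Visual range: 6 m × (mass/50 kg)^(1/3) — detection distance
proportional to linear body size.  Olfactory range: 90 m ×
(mass/470 kg)^(1/2) — a compromise between metabolic (3/4-power) dose
scaling and sublinear plume-length growth with dose.  The four named
hosts (lizard 2 kg, warthog 42 kg, kudu 333 kg, elephant 5196 kg) give
visual/olfactory ranges of 2/6, 6/27, 11/76 and 28/299 m.

The visual disc is rasterized as the square block of whole cells with
the same area (1×1, 2×2, 5×5 for warthog, kudu, elephant; even-sided
blocks anchor the bait on the upper-left-of-center cell).  The plume
is an isosceles triangle with apex at the bait-cell center, axis along
the wind (fixed easterly by default, i.e. along horizontal bands) and
edges 26° off axis; a cell belongs to the plume iff its center lies
strictly inside the triangle (apex cell always included).  Rasterized
plume cell counts match an independent point-in-triangle oracle
exactly (test suite, shapely).

Sub-cell baits stimulate a fraction of their single cell: lizard 0.5
(0.8 with odor, folded into the one cell since its 6 m plume does not
reach the next cell center), tiny target 0.25 (two-sided visibility of
a flat 0.06 m² screen, hence half the lizard's 0.5).  The large target
takes the kudu's visual range reduced to a 1×2 block along the wind
axis (a flat target is visible from its two faces) and, when dosed
with ox odor, a fixed 60 m plume.  Natural mammalian hosts can be
given their odor plumes via `has_odor=True`; the feeding/starvation
drivers default to visual-only hosts.

## The per-step cohort update

Within each day, 25-step host-searching blocks alternate with 25-step
general blocks, starting with host-searching; daily step counts
(150, 300, 600, 1200, 2400, 1350) scale by the mobility multiplier
(1/3, 1, 3 for the low/standard/high-mobility conditions) rounded to
whole block pairs.  Each step applies, in order:

1. background mortality, the daily 3% converted geometrically over the
   day's steps;
2. wild-host feeding at 0.00125 × *f*(day) per step (every step, both
   block types) — with this, and no mapped baits, 2.69% of the cohort
   starves per cycle, reproducing the 2.7% calibration anchor, and
   `goal_seek_wild_prob` inverts the run to recover 0.00125;
3. recruitment of flies standing in stimulus cells (host-searching
   steps only; see semantics below);
4. dispersal;
5. recruitment of flies arriving in stimulus cells;
6. partition of recruited flies: fraction *f* removed and tallied
   (fed/caught), 1−*f* into the bait's inactive pool;
7. at the last host-searching step of each block, pools are released
   evenly over the good-habitat cells of the bait's visual footprint.

Field-experiment baits operate only during the second half of each
day's steps ("afternoon"); targets and natural hosts operate
throughout.  Capture devices use fixed *f* = 0.6; probing responses
rise 0.1 → 0.6 over days 1–6.

**Recruitment semantics for sub-cell stimuli.**  For whole-cell
stimuli (fraction 1.0) the stimulus cell empties every step and stages
3/5 are unambiguous.  For sub-cell stimuli the treatment of a fly that
was offered the stimulus, refused, and stayed in the cell admits three
readings, all implemented (`CohortSimulation(standing_recruitment=…)`):

* `"arrivals"` (default): standing occupants are offered when a
  host-searching block opens; thereafter the offer goes to every fly
  arriving at the cell center — stepping in from a neighbor or bounced
  back from a failed crossing.  Rationale: the stimulated zone covers
  a fixed part of the cell, so a perched fly is not re-stimulated by
  the clock, but a fly that flew and returned has re-randomized its
  position.
* `"every_step"`: standing refusers re-offered at every step.
* `"block_start"`: offers only at block opening and on true re-entry.

The default reproduces the widest set of published anchors (single-cell
catch degeneracy >99.9%, block feeding success 65%, band starvation
risks); `"block_start"` matches the 25% band feeding-success figure
more closely (26.7 vs 29.1) but degrades the single-cell degeneracy to
92.8%, and no single reading reproduces every printed value — see
Limitations.

**Starvation probability part-way through the cycle** is a competing-
fates calculation: the cohort runs (with its hosts) to the end of day
*d*, the still-unfed field is renormalized and continued to day 6, and
the probability reported is starved/(starved + fed) — background
mortality censors a fly's feed-or-starve fate non-informatively.  The
published values above the 0.97^(6−d) all-survivors-starve ceiling
confirm this definition.

## Experiment drivers and problem sizes

* **Crossover catches** (`crossover_catch`, `odor_efficacy`,
  `catch_table`): two baits at sites on the habitat's medial axis
  ~1 km apart, swapping daily for six days; catches normalized as
  100 × catch × (good area, km²)/(initial total).  Odor efficacy —
  100 × (catch_vo − catch_v)/catch_v — and all cross-habitat orderings
  are normalization-independent.
* **Target efficacy**: targets placed singly and evenly at a density
  per km² of habitat, operating continuously; kill percent per cycle.
* **Feeding success**: mapped hosts only (wild-host probability 0),
  scored cumulatively at the 4- or 6-day horizon.
* **Starvation tables**: host × habitat × days-completed × mobility.
* **Long bands**: host spacings at low density in a 10 m band (1 km at
  100 lizards/km², 6.25 km at 16 kudu/km²) exceed one 2-km map.  The
  drivers therefore build bands as long thin grids with reflecting
  ends — exactly equivalent to the bent (serpentine) band fitted onto
  square maps, without plume cross-talk between adjacent serpentine
  runs.  Default sizes: 20 lizard spacings (20 km) or 4 kudu spacings
  (25 km); end effects are a ≲1-cell perturbation of one spacing.
* **Nearest-bait geometry**: mean over good cells of distance to the
  nearest evenly placed bait (38.5 m at 100/km² in the block, 250 m in
  the 10 m band, matching the ≈40/250 m published contrast).

A full 6000-step cohort run on the 200×200 map takes ~2–3 s on one
CPU; the complete test suite runs in about a minute, and
`scripts/acceptance.py` in under ten seconds.

## Numerical choices

* Exact conservation by construction: each directional flow is
  subtracted from its source and added to its destination.
* The engine validates the bookkeeping identity (active + pools +
  tallies = initial) at every step and raises on >1e-9 violation.
* Footprints extending off-map are clipped with a warning (the
  reflecting boundary makes clipping conservative); deployed-bait
  footprints must be disjoint and overlapping deployments raise.
* Degenerate inputs: a grid with no habitable cell, a seed in no-go
  vegetation, an empty unfed population in the starvation calculation
  and a non-bracketed goal-seek all raise descriptive errors.

## Known limitations

* The published 4-day feeding-success values for *grouped* lizards
  (2% in the band, 11% in the block at 100/km²) are not reproduced
  (9.4% and 50.6% here).  They lie below the perfect-absorber flux
  bound of the movement model itself: with along-band step variance
  *h·x*²/2, the day-1–4 spread is σ ≈ 297 m, so stations 4 km apart
  can remove at most ≈12% of a uniform cohort even capturing every
  visitor instantly.  Since the same engine reproduces the singly-
  distributed feeding and starvation values to ~0.1–1 point, the
  grouped figures appear to involve an additional unstated condition;
  they are reported as computed.
* The absolute normalization of published crossover catches differs
  from ours by a roughly constant factor (~4.5); all ratio and
  ordering results are unaffected.
* No wind meander or vegetation-modified plume structure; plumes are
  rigid triangles.  No correlated or anisotropic movement.  Reptile
  metabolic correction to plume length deliberately omitted (odor
  effectiveness of small hosts is thus, if anything, over-estimated).
* The synthetic landscapes (blocks, bands, checkerboards, bush
  generators) are stylized: bush patterns are parameterized stand-ins
  for hand-drawn arrangements, and real vegetation mosaics, seasonal
  change and host movement are outside the model.  Passing tests show
  the engine reproduces the deterministic model's behavior, not that
  the model captures any particular field site.
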