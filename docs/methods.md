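# Methods

`culturesim` is an event-based, spatially explicit individual-based model of
group foragers that learn *what* to eat and *how* to process it, together
with the repertoire metrics used to quantify traditions and cumulative
cultural change. This note documents the model, its numerical choices, the
reduced "desk" scenario the test suite runs, and what those reduced runs can
and cannot show.

## The model

### World

A square torus holds `n_patches` circular patches (radius 10 m) of resource
items. Each of `R` resource types has a quality `Q_r ~ N(0.1, 0.1)` (the
maximal per-item energy reward; negative draws are kept by default — food
that is never worth eating once learned), a practice time `H_r` for
half-maximal processing skill (one global `H` per run), and a shape exponent
`S_r` drawn uniformly from {1,2,3,4}. Patches belong to patch types; a patch
type owns five resource types found nowhere else and every patch carries a
random three of its type's five. Consumed items vanish until the annual
growth step restores them in place. Environmental change replaces a random
type (new `Q`, new `S`, naive foragers) at a per-minute probability of
`EC / year_minutes`.

Torus wrap-around avoids edge artifacts; patch centers may overlap; both are
free choices where the published geometry is silent.

### Behavior

After every completed action a forager runs one decision cascade:

1. **CHECKSAFE** — safe iff enough groupmates (9 at full scale) are within
   SAFESPACE (17 m). Unsafe foragers MOVETOGROUP toward the centroid of the
   other members; on regaining safety the heading is aligned with neighbors
   in ALIGNSPACE (20 m). During CHECKSAFE a random *demonstrator* is drawn
   from groupmates within COPYSPACE (20 m) that are currently eating.
2. **OBSERVE** with probability `omega_i` (duration `tau_i`) — the hook for
   observational learning.
3. **NOTHING** (1 min) when the stomach is full (20 items).
4. **EAT** (1 min) a held food target within reach (0.9 m), else
   **MOVETOFOOD**.
5. **MOVE** `delta_i` m forward after a fruitless SEARCH, else **SEARCH**
   (1 min): up to 20 items within view (2 m, forward half-disc) are assessed
   in sequence; the first accepted item becomes the food target.

Acceptance of an item of type r is `P_F = min(1, (a_ir/a_ie)^sigma_i + P_E +
P_S)`: the learned attractiveness of the type relative to the expected
quality of the environment, plus exploration `P_E = epsilon_i (1 -
min(1, c_ir))` and social stimulation `P_S = gamma_i` if a groupmate was
seen eating r within the last 30 min. `a_ie` self-tunes at every digestion
(100 min): times `1 - phi` after an unfilled stomach, times `1 + phi` after
a full one, so selectivity equilibrates near maximal intake. Becoming
satiated triggers a 100-min aversion to the stomach's modal type (the
reading of "satiated with a given resource type" we adopt; `all`-of-one-type
and `any`-type-present readings are config options).

### Learning

Per consumption of type r: experience `t_ir += 1` min; skill
`s_ir = t^S/(H^S + t^S)`; realized reward `e_ir = Q_r s_ir + N(0, Z)`
(`Z = 0.005`); Rescorla-Wagner reinforcement `a_ir += lambda_i (e - a)`;
certainty `c_ir = (1-lambda) c + lambda (1 - min(1, |(e-a)/e|))`, with the
`e = 0` case treated as maximal discrepancy so a worthless type never gains
certainty from division noise. There is no forgetting. Observational
learning transfers experience `dt = max(K (o/M)(t_kr - t_ir), 0)` with
`o = min(tau_i, time left of the demonstrator's EAT)`, `K = 0.1`, `M = 1`
min; it carries no reward information. Local enhancement is never coded
explicitly — it emerges from cohesive grouping.

### Demography and selection

Energy: per-minute metabolism; food energy credited at digestion;
reproduction costs energy. Death at age 20 y, at `h <= 0`, or by a
per-minute stochastic hazard. Every death immediately triggers a birth: the
parent is drawn with probability `h_i^W / sum h_j^W` (`W = 3`; energies
floored at a tiny positive value so the lottery is always defined; the dying
forager is excluded), keeping the population at exactly N at every instant.
Offspring are born naive at the parent's position and in its group; with
mutation enabled each heritable parameter mutates with probability 0.05 to
`N(parent, max/5)` clipped to bounds. Groups exceeding G split uniformly at
random into two halves.

Newborns start with a positive energy stake (config `initial_energy`) —
starting at zero would flag them as starved at the very next minute-tick,
before their first digestion could credit any food.

### Scheduling

Foragers sit in a priority queue keyed by action completion time (FIFO on
ties); actions overlap in time. Life-history bookkeeping (metabolism,
digestion, deaths/births, splits) and environmental-change trials run on a
one-minute tick interleaved with the queue; ticks at an instant resolve
before forager events at the same instant. Annual growth is applied at the
year boundary before that minute's change trial. Three independent RNG
streams (environment, behavior, mutation) make the paired-environment
design expressible: runs sharing the environment seed see the same world
and the same schedule of environmental change, bit for bit.

A run is flagged inviable and halted when deaths exceed a churn limit
(default 20 N within one year): that death rate only arises when the
population cannot pay its reproduction costs from foraging income, the
operational form of "average energy never rises above the cost of giving
birth".

## Cultural metrics

The repertoire of forager i is its vector of lifetime consumption counts
`d_i`. Similarity between groups is the mean pairwise cosine of member
repertoires (same-forager pairs excluded; the mean is over the pairs
actually summed; all-zero repertoires are dropped with a warning).
**Traditional difference** = within-group similarity across a
generation-spanning interval minus between-group similarity against an
environment-matched paired run at the later year — the pairing controls for
population-wide convergence on the same high-quality types. **Cumulative
change** of a measure (total energy intake, diet-proportion-weighted
quality, Shannon diversity with natural log over consumed types, average
skill) is the proportional change of the population mean between an early
year representing one full lifetime of learning and a late year.
Significance uses one-sample Wilcoxon signed-rank tests (continuity
corrected, one-sided greater) at a Bonferroni-corrected per-test alpha of
`familywise / #conditions`.

## The desk scenario

The published scenario (250 types, 24 500 patches x 1200 items, N = 100,
120 years of 360 x 720-minute days) needs cluster-scale compute. The test
suite instead runs a reduced scenario chosen once, on scaling grounds, and
used unchanged everywhere:

* **World**: 50 resource types in 10 patch types, 200 patches x 150 items,
  570 m world — the same ~19% patch cover as the full scale, with the type
  pool reduced 5-fold rather than 25-fold. Items per patch are scaled so
  that a *lifetime's consumption relative to the type pool* stays in the
  published regime rather than matching raw item density: with the
  compressed year below, full-density patches would let every forager
  consume thousands of items per type pool and saturate every diet, and
  between-group repertoire differences are only expressible while diet
  breadth and concentration stay well below saturation.
* **Time**: a compressed year of 30 days x 120 min = 3600 min, lifespan 5
  years. All *absolute* time constants that drive the learning dynamics
  (1-min actions, 100-min digestion, 30-min SE window, `H` in minutes) are
  untouched; compression only reduces items consumed per lifetime, i.e.
  makes learning somewhat more protracted relative to a lifetime.
* **Population**: N = 20 in two groups, G = 12 (a few births of headroom
  above the starting group size, so lineages are not reshuffled by a split
  after every net birth). Safety requires 6 groupmates within SAFESPACE —
  more than half the group, mirroring the role of 9-of-up-to-19 at full
  scale; a requirement at or below half lets two stable sub-clusters drift
  apart and strands foragers between them. For groups too small to supply
  the count, the requirement is capped at group size - 1 (a shrunken group
  would otherwise be permanently unsafe and starve in place).
* **Traditions design** (`tradition_config`): a single full-size group of
  20 per run. Births exactly balance deaths in a one-group population, so
  the group lineage is never reshuffled by splitting and the group
  repertoire has a stable carrier with a large pair sample; the
  between-group reference comes entirely from the environment-matched
  paired run. Safety needs 11 of 19 groupmates (above half, so the group
  cannot fission) and regrouping is re-evaluated every 15 m of travel.
  Patches hold 900 items (a patch must feed the whole group for a few
  digestion cycles, as 1200 items feed ~20 foragers at full scale) spread
  over 500 patches on a 900-m torus (same ~19% cover): a single group in a
  smaller world re-treads its own depleted backtrail, and a group that
  cannot fill its stomach cannot express selectivity at all — its
  environment expectation a_ie collapses until every type is acceptable
  and diets become route noise rather than learned preference.
* **Environmental change**: 1 type/year = 2% of the pool per year, the same
  fraction as the published default (5 of 250).
* **Energetics** (the published metabolism and hazard constants are not in
  the main text and are config here): metabolism 0.004 energy/min,
  reproduction cost 50, newborn stake 100, hazard 2e-5/min (expected
  accidental lifespan far beyond 5 y, so old age dominates). Chosen so that
  a competent forager runs a clearly positive energy balance and the
  population is comfortably viable, while reproduction still costs a
  nontrivial share of lifetime surplus.
* **Stand-in "evolved" parameters** (the published values live in a
  companion study and are inputs here): `delta = 5` m, `phi = 0.05`,
  `sigma = 10`, `epsilon = 0.05`, `lambda = 0.9`, `tau = 1` min, and per
  mechanism `gamma = 0.3` (SE) or `omega = 0.1` (OL). A high learning rate
  and strong selectivity follow the published qualitative description (the
  selection rule approaches the zero-one diet rule as sigma grows);
  exploration sits at the low end that still lets solitary foragers
  bootstrap a diet — the familiarity-bias feedback only operates when
  exploration does not resample every type continually.
* **Movement discretization**: MOVETOGROUP covers up to 10 m per event
  (20 s; 15 m in the traditions design) instead of 1 m per 2-s event —
  same speed, coarser re-evaluation — purely to keep desk event counts
  manageable. Each regroup event budgets the full travel quantum even when
  the centroid is nearer: an unsafe forager already at the centroid of a
  dispersed group can only wait for the others to close in, rather than
  re-check every two seconds.

## Numerical choices

* Probabilities are evaluated lazily: the `(a/a_ie)^sigma` term is taken as
  0 for `a_ir <= 0` and as 1 for `a_ir >= a_ie` (avoiding overflow for
  large sigma and undefined powers of negative ratios).
* `a_ie` is floored at 1e-12 (perpetually hungry foragers would otherwise
  underflow it to zero, where the food-choice ratio is undefined); it is
  initialized at the environment's mean quality.
* Heading gets a small Gaussian jitter (sd 0.1 rad) per MOVE so travel
  paths meander instead of tracing closed geodesics on the torus.
* Action durations are floored at 0.01 min so the queue always advances.
* Heritable-parameter bounds for mutation: probabilities in [0,1], `tau` in
  [0.01, 1], `delta` and `sigma` in [0, 20] (unbounded above in the
  original description; the cap covers the illustrated regimes with
  headroom and gives the one-fifth mutation rule a finite scale).
* Environmental change reuses the type *slot*: the replaced id keeps its
  items but receives fresh `Q`, `S` and zeroed forager memories — equivalent
  to retiring one id and minting another, without renumbering.
* Alignment happens only on the unsafe-to-safe transition (the alternative,
  aligning on every safe cycle, measurably degrades foraging in this
  implementation: groups turn constantly and eat less).
* A stale food target is re-validated when the forager next considers it;
  targets claimed by another forager are dropped there.

## What the desk runs do and do not show

Passing desk-scale tests demonstrate that the implemented mechanisms
interact as described — protracted skill learning plus grouping yields
group-specific repertoires that out-persist any individual, observational
learning yields cross-generation skill gains that asocial learning in the
same environment does not — at a 20-fold reduced population-time budget.
They do not reproduce the published effect *magnitudes* (cluster-scale), do
not exercise the evolutionary dynamics of the heritable parameters (the
engine supports mutation + selection, but all headline analyses run
non-evolutionary, as in the source design), and the desk world's 50 types
cannot exhibit the long tail of rare resources a 250-type world has.
Problem sizes used by the suite: the traditions check runs 5 replicate
pairs (focal + environment-matched paired run) per task difficulty
(H = 0.1 vs 1) of 15 desk years each; the cumulative-skill check runs 6
independent-environment replicates per difficulty (H = 0.1 vs 10) with the
early reference year at one full lifespan; the familiarity-bias check runs
5 solitary foragers for 2 years against 400 multinomial resamples per
forager. A 15-desk-year run takes roughly half a minute on one core.
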