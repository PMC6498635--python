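# Model and methods

## Scope and shape of the model

`humoralsim` simulates a microscopic, spatially homogeneous volume of the
humoral phase (blood/lymph).  Because the phase is well mixed, no positions
or motion are modelled: agents pick random interaction partners.  What *is*
resolved is the **shape** of receptors and ligands, as points of a discrete
planar shape-space lattice; geometric proximity of a receptor to a ligand's
mirror image encodes binding affinity.  Two lattices of identical geometry
are kept: the peptide lattice (TCR vs MHCII+peptide) and the antigen lattice
(BCR/antibody vs antigen).  A self or foreign population uses the same
coordinates on both (clonal populations; pathogen diversity is expressed by
location, growth speed and initial count, not by intra-population
variation).

B and Th cells are individually tracked agents (receptor, activation state,
timers); self cells, pathogens, bone marrow cells, antibodies, danger
signals and interleukins are counted populations.  The state evolves by a
stochastic scheduled-event list: each pending event with expected waiting
time τ fires with rate 1/τ, the next event is drawn proportionally to its
rate, and the clock advances by an exponential draw with mean 1/Σrates.
This memoryless (Gillespie) reading is the simplest model consistent with
parameterising events by expected waiting times; recurring events (actions,
controls) simply stay in the race after firing, one-shot events (deaths)
remove their owner.  Deterministic milestones (start of marrow output at
day 10, scheduled infections) interleave with the race.  A single
`random.Random` stream seeded from the configuration makes a run a pure
function of (parameter set, seed).

## Binding

The similarity metric is the l-infinity distance
`d(z1,z2) = max(|x2−x1|, |y2−y1|)`; a receptor `(x,y)` is perfectly
complementary to a ligand `(x,−y)`.  Two layers sit on top of the metric:

* a **hard ball test** — interaction is geometrically possible only within
  the actor's action radius (`r0` for B cells, `thrad` for Th recognition,
  `ab_radius` for antibodies); selection domains (negative-selection balls,
  regulatory rings) are hard sets, so survivor fractions equal exact
  lattice-area ratios;
* a **graded affinity weight** `w(d) = (1 − d/(r+1))^alpha` (default
  `alpha = 2`) applied to the *success* of B-cell engulfment and antibody
  killing.  Perfect complements always succeed, marginal binders rarely do.
  The weight is what gives affinity maturation its selection gradient
  (better-fitting mutants present and divide more) and what makes clones at
  a self mirror — possible only without negative selection —
  pathologically efficient.  Th-side recognition stays a hard threshold:
  receptor editing and maturation are B-cell phenomena here.

Mutated offspring falling off the lattice are clamped to the nearest
lattice point, preserving repertoire mass at the boundary.  The lattice has
hard (non-wrapping) edges.

## Selection

* **B cells** (bone marrow): a candidate whose BCR lies strictly inside the
  ball of radius `b_negsel_radius` (50) around any self-antigen mirror is
  deleted.  The surviving repertoire shows empty domains around the self
  mirrors.
* **Th cells** (thymus), with `d*` the distance to the nearest self-peptide
  mirror: under ERS (`comptype=0`), `d* < ring_inner` deletes,
  `ring_inner ≤ d* ≤ thrad` yields a **regulatory** clone of that peptide's
  characteristic ring, and larger `d*` yields a conventional cell.  Under
  CRS (`comptype=1`) everything with `d* ≤ thrad` is deleted and no
  regulatory compartment exists.  Ring membership is inherited exactly
  (Th receptors do not mutate), so every live regulatory cell provably sits
  in its annulus at all times.

`ring_inner = 50` and `ring_outer = thrad = 80` were chosen so the annulus
scales with the Th action radius; both are configuration keys.

## The three interaction-and-division kinds

* **Weak (ERS only, `weakrepr`)** — homeostatic self-surveillance.  A naive
  B cell that engulfs self antigen presents the self peptide; a regulatory
  clone of the matching ring docks at the activation-control event,
  refreshing the survival contact on both sides and occasionally dividing
  weakly (`pweak_t`); the B cell itself divides weakly with probability
  `pweak`.  Weak division rates are set below the break-even point of the
  engulfment-driven loop, so weakly self-reactive clones persist without
  expanding — surveillance without autoimmunity.
* **Intermediate (ERS only, `medrepr`)** — the polyclonal first line.  A
  foreign peptide in the MHCII blocks regulatory docking; once the cell has
  been unattended longer than `tcrit_stress` it becomes *activated* and
  emits danger signals.  Each danger molecule alerts a uniformly random Th
  cell (intermediate division, interleukin burst); each interleukin signals
  a uniformly random B cell, and only cells that have lost regulatory
  control respond with intermediate divisions.  Danger in the air also
  biases Th surveillance toward foreign presenters (chemotaxis weight 4);
  without danger — always, in CRS — surveillance of presenting cells is
  unbiased.
* **Strong (both models)** — the specific two-signal response.  A Th cell
  whose TCR recognises a presented foreign peptide strongly activates both
  partners; helped blasts divide immediately (with mutation, so maturation
  can bootstrap from a low-affinity founder; repeated help to an already
  committed blast is much less proliferative).  Strongly activated blasts
  cycle fast (`taub_strong`), home to the infection (they sample foreign
  antigen only), and after `plasma_after` strong divisions differentiate
  into plasma cells whose antibodies carry their BCR shape.  Strong
  offspring become memory cells with probability `pmem`, throttled by a
  memory-niche capacity.

Additional rules that the narrative description leaves open were fixed as
follows and are all exposed as configuration keys:

* **Antigen-driven activation**: engulfment at distance below
  `auto_activation_radius` (40, i.e. above the central-tolerance affinity
  threshold) activates a naive cell outright.  Clones in that regime exist
  only when negative selection is off (or, against foreign antigen, after
  maturation); this rule is what turns the negative-selection knockout into
  the rapid self-destruction phenotype.
* **Presentation decay and blast contraction**: a loaded MHCII empties
  after `pres_life` steps; an activated cell with nothing presented settles
  back to naive, and a strongly activated blast that finds no antigen
  within `pres_life` dies.  Effector (strongly activated) Th cells carry a
  shortened lifespan (`th_strong_life`), so the expanded helper clone
  contracts after clearance while a sizeable rest persists as T memory.
* **Memory recall**: a memory B cell that engulfs foreign antigen
  re-activates directly — no critical waiting period, no danger cascade —
  which is the mechanism behind the faster secondary response.
* **Regulatory protection**: a transient miss of one ring while other
  regulatory clones stand is tolerated; only total collapse of the
  regulatory compartment (a pathological state, e.g. every ring emptied)
  lets self presenters run the stress clock.  With the compartment absent,
  every presenting B cell eventually activates — but self presentation
  never emits danger signals, so the alarm cascade stays specific to
  nonself.

## Mutation

At division, a B offspring's BCR is displaced with probability `pmut` by a
uniformly drawn point of the l-infinity sphere whose radius is uniform in
`[rmin, round(rmin/cr)]` — the `(rminnew, crnew)` pair for maturation
(intermediate/strong) divisions and `(rminsprd, crspread)` for weak ones.
This reading of the four radius parameters is a package choice; the
defaults give mutation steps of 5–6 lattice units.

## Parameters

The thirteen core parameters keep their reference names and defaults:
`r0=150`, `pmem=0.3`, `crnew=0.9`, `rminnew=5`, `crspread=0.9`,
`rminsprd=5`, `thrad=80`, `pmut=0.4`, `taub0=5`, `tauth0=2`,
`tcrit_stress=2`, `nr=350`, `tr=60`; the model switch is
`medrepr/weakrepr/comptype/tauthm = 1/1/0/5` (ERS) vs `0/0/1/30` (CRS).
Times are in steps of 0.1 day.

The remaining constants (lifespans, carrying capacities, pool time
constants, burst sizes, the affinity exponent) are not fixed by the
reference description.  They were calibrated, in the same spirit in which
the original model was tuned against normal immune behaviour, so that the
default ERS world shows the canonical patterns: roughly equal B and Th
census (~150–200 each), logistic self growth from 450 cells toward
saturation with no erosion, stable regulatory rings from around day 150,
first-infection elimination in about six days with a second exposure
cleared three times faster, and the ERS>CRS survival ordering.  Highlights
(all in `config_io._SCHEMA`, all overridable): naive lifespans
`b_life = 1500`, `th_life = 800` steps with `th_strong_life = 120` for
effectors and `memory_life = 2000`; capacities `b_capacity = 300`,
`th_capacity = 400` (marrow throttles), `b_strong_capacity = 1200`,
`th_strong_capacity = 300` (clonal expansion), `memory_capacity = 50`;
blast cycle `taub_strong = 2.5`; plasma cells live `plasma_life = 40` steps
and emit `ab_burst = 5` antibodies every `ab_prod_tau = 2` steps; an
antibody amount acts every `ab_action_tau = 2` steps killing up to
`ab_kill = 25` within `ab_radius = 100`, and decays with mean
`ab_decay_tau = 12`; danger/interleukin bursts of 5 with action/decay means
2/5 steps.

## Experiments and their statistics

* **Outcome classification**: a run *wins* iff every injected population
  drops under 50 cells before the horizon and never reaches 4000 (host
  death).  Elimination times are measured from the matching injection, at
  event granularity (populations log their threshold crossings, so the
  census sampling stride cannot hide a crossing).  A population re-injected
  with the same shape merges, arming a fresh elimination clock.
* **Fisher one-sided exact test**: the upper hypergeometric tail at the
  observed ERS-win cell, computed with log-gamma terms and a log-sum-exp,
  so tables of hundreds of runs per arm do not underflow.  Zero-margin
  tables return 1.  The implementation is cross-checked in the tests
  against scipy and against exact rational arithmetic for every table with
  total ≤ 40.
* **Welch t-test** (two-tailed, Satterthwaite df) for equality of the two
  mean elimination times; degenerate equal zero-variance samples return 1.
* **Memory experiment**: the same pathogen (`nr`, `tr`) injected at days
  300 and 315; among runs clearing both, the two elimination-time samples
  are summarised and compared.
* **Survival grid**: for each (initial count, division wait) arm, both
  models are run against an injection at day 300 and wins are tabulated
  with the win ratio and the Fisher p-value.
* **Sensitivity analysis**: the thirteen core parameters are sampled
  uniformly in their documented ranges, each sample runs to day 305 against
  a random-type infection at day 300 (sampled `nr`, `tr`, uniform random
  shape), and the seven census outputs are correlated with the inputs
  (Pearson, rounded to one decimal; zero-variance outputs report 0).

Desk-scale problem sizes: batch experiments default to ~100 replicates
(the reference used 500), run with a 3400–3500-step horizon and stop early
once the outcome is decided; the acceptance script uses 60–120 replicates.
Replicate seeds are drawn from one master generator, so every batch is
reproducible from a single seed.

## What the synthetic world does and does not capture

All inputs are synthetic: the initial world is three self populations of
150 cells at the documented lattice positions, and infections are
parameterised point populations.  The generator reproduces the *patterns*
the model is about — homeostasis, ring formation, the polyclonal/specific
response cascade, memory, autoimmunity under broken tolerance — with
population sizes two to three orders of magnitude below physiology, a
two-dimensional shape space (the literature estimates roughly five
dimensions), no antigen-presenting cells other than B cells, no innate
immunity, and no spatial structure.  Passing tests therefore certify the
internal logic and the direction and rough magnitude of the comparative
claims, not quantitative immunology.  Elimination-time distributions are
heavier-tailed than the reference's (sd ≈ 27 vs 13 steps at matched means),
because a desk-scale repertoire occasionally starts without a high-affinity
clone; the batch means agree.

## Numerical notes

* The event race keeps an incrementally updated total rate with a periodic
  exact re-summation (every 16384 draws) to bound float drift; a queue
  whose remaining total is pure float residue signals exhaustion.
* Population-level rates (logistic divisions, pool actions/decays) are
  singleton race entries whose rates are refreshed whenever the underlying
  count changes.
* Determinism: identical (parameter file, seed) re-runs produce
  byte-identical time series; dictionary iteration orders are insertion
  orders and therefore reproducible.
* Elimination thresholds are strict (`count < 50`); a population ending
  exactly at 50 is a loss.  Division-kind gates raise `RuleViolation` if a
  disabled kind is requested, rather than silently ignoring it.
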