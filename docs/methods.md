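# Model and methods

## The model

`ncstream` simulates chick cranial neural crest cells (NCCs) as off-lattice
overlapping spheres migrating through a two-dimensional fibronectin (FN)
matrix that the cells themselves remodel. The domain is an open square,
500 µm × 500 µm (x ∈ [0, 500], y ∈ [−250, 250]); the left boundary stands
for the neural tube, and cells emerge from an entrance strip of width
`l_entr` centred on y = 0. All boundaries reflect ("bounce back"), which
also flips the stored velocity components so the two-step integrator does
not carry outward motion.

Two cell phenotypes exist. *Secretory* (leader) cells are initialised as a
column at x = `R_cell`, evenly spaced and non-overlapping inside the
entrance strip (7 cells at the defaults), and may deposit new FN puncta.
*Non-secretory* (follower) cells enter later at the initial leader
positions whenever no cell center sits within 2·`R_cell` of the site, and
cannot deposit. Both phenotypes can convert puncta they cover into
oriented fibers and re-orient existing fibers; the experiment switches
(`secretion_scope`, `remodeling_scope`) restrict either ability per
phenotype for the knockout conditions.

The FN matrix starts as an isotropic square lattice of unoriented puncta
with spacing `lambda_fn`; the first column sits `R_cell` + 0.5·`R_filo`
to the right of the leader centers so every leader senses at least one
punctum at t = 0. FN never moves, diffuses or decays; elements are only
added (secretion) or converted in place (punctum → fiber).

### Forces and velocity

Cell i's velocity obeys an overdamped force balance,
v(i) = (F_ECM + F_rep + F_contact)/η with η = 1. A cell senses FN in the
annulus `R_cell` < d ≤ `R_filo` (covered elements, d ≤ `R_cell`, are
invisible) and other cells within `R_filo`.

*Magnitudes.* Each sensed FN element or neighbouring cell exerts a
radially oriented force whose strength decays quadratically,
w·(1 − d/R_filo)², vanishing at the sensing radius. The magnitude of the
cell–ECM (resp. repulsion) force is the **sum of the individual
strengths** with unit weights (resp. the acting cell's phenotype-specific
repulsion strength c_i); the *direction* is set entirely by the sampled
cues below, so a cell in a symmetric environment still generates traction
but has no preferred heading. (See "Design choices" for why the summed
form rather than the norm of the vector sum is used.)

*Directions.* The haptotaxis heading is drawn from a von Mises
distribution whose mean is the direction of the FN density gradient
∇S_FN = γ_FN Σ_j ∇ exp(−d_j²/(2(R_filo−R_cell)²)) and whose
concentration is the **per-element mean** gradient norm, clamped at
`kappa_cap`. An isolated punctum therefore draws a nearly deterministic
approach, while a symmetric surround (e.g. the interior of the pristine
lattice, which the Gaussian kernel smooths essentially flat) yields an
almost uniform heading. Contact guidance is the normalised mean of the
sensed fibers' orientation unit vectors (antiparallel fibers cancel). The
cell–ECM direction blends the two unit cues as
(χ·F̂_hap + (1−χ)·F̂_cg)/‖·‖; a missing cue contributes a zero vector, and
if the blend cancels the ECM force is dropped for that step. The
repulsion heading is von Mises about the *negative* cell-density gradient
(kernel width `R_cell`, height γ_cell), again with mean-normalised
concentration, so cells at long range may align while cells in dense
spots head for low density.

*Contact mechanics.* Overlapping cell bodies (d < 2·R_cell) additionally
repel deterministically along the line of centers with strength
`contact_strength`·(1 − d/(2 R_cell))², the standard overlapping-spheres
contact force. This is what keeps the stream a monolayer-like packing
(mean nearest-neighbour distances ~10 µm) instead of letting the
stochastic repulsion alone fight the ECM traction, under which cells
stack 2–3 deep.

*Speed caps and persistence.* The speed is the raw force norm capped at
`s_fn_max` when the cell senses FN and at `s_off_max` otherwise
(chemokinesis: cells are fast in FN-rich regions). A cell that senses
neither FN nor neighbours keeps its previous velocity unchanged. When the
corridor guiding force applies to a cell (weight z, scope
none/leaders-only/both), only the *direction* is re-blended,
normalize((1−z)·F + z·x̂), with the speed unchanged; z = 1 forces motion
strictly along +x.

Positions advance by a second-order Adams–Bashforth step
x_{n+1} = x_n + Δt(3/2 v_n − 1/2 v_{n−1}); a cell's first step after
entry is forward Euler.

### ECM remodeling

Secretory cells deposit a punctum at their center when their exponential
clock (mean `T_ave`; `T_ave_follower` for secreting followers) has
elapsed *and* they currently sense at least one other FN element; the
clock then resamples. Any moving, remodeling-enabled cell converts
covered puncta into fibers aligned with its current velocity, and nudges
covered fibers by one Euler step of dφ/dt = (ln 2/`T_half`) sin(θ − φ)
toward its heading θ (linearised half-angle time `T_half`). When several
cells cover the same element in a step they act sequentially in ascending
cell id, which fixes the result for reproducibility. Cells at rest have
no heading and leave covered FN unchanged. A punctum deposited this step
can be converted in the same step by its (moving) depositor.

### What drives migration

The emergent mechanism is a leader-paved relay: leaders march into the
lattice (the one-sided FN edge at the start gives a real gradient),
convert the puncta they pass over into +x-oriented fibers and add their
own deposits (instantly converted) to the trail; followers then combine
noisy haptotaxis with contact guidance along the trail, which rectifies
their headings because the heading error is drawn afresh each step around
a *static* environmental cue. Haptotaxis on the intact lattice is
essentially isotropic noise; its directed role is short-ranged (isolated
puncta, deposit trails, the lattice edge). This is why contact-guidance
upregulation (χ ↓) lengthens streams, faster leader secretion thickens
the relay, and uniform secretion by both phenotypes pollutes it with
misoriented fibers.

## Parameters

| name | default | units | meaning |
|---|---|---|---|
| `R_filo` | 27.5 | µm | filopodial sensing radius |
| `R_cell` | 7.5 | µm | cell body radius |
| `l_entr` | 120 | µm | entrance strip width |
| `T_ave` | 30 | min | mean secretion interval (leaders) |
| `T_half` | 30 | min | fiber reorientation half-angle time |
| `s_fn_max` | 0.8 | µm/min | speed cap when sensing FN |
| `s_off_max` | 0.05 | µm/min | speed cap when not sensing FN |
| `dt` | 0.1 | min | time step |
| `gamma_fn` | 300 | a.u. | haptotaxis kernel height (von Mises concentration scale) |
| `gamma_cell` | 100 | a.u. | repulsion kernel height |
| `lambda_fn` | 20 | µm | initial lattice spacing |
| `chi` | 0.5 | — | haptotaxis weight (1 = pure haptotaxis, 0 = pure contact guidance) |
| `c_leader`, `c_follower` | 0.5 | a.u. | repulsion strengths per phenotype |
| `z` | 0 | — | guiding-force weight |
| `contact_strength` | 10 | a.u. | overlap contact repulsion strength |
| `duration` | 720 | min | simulated time (12 h) |
| `kappa_cap` | 700 | — | numerical clamp on von Mises concentration |

`chi_leader`/`chi_follower` and `gamma_fn_leader`/`gamma_fn_follower`
(default `None` → global value) let gain/loss-of-function conditions
target one phenotype, as several of the stream-break rescue experiments
require.

## Design choices at genuinely open points

- **Force magnitude = summed strengths.** Read literally as the norm of
  the vector sum of radial unit forces, symmetric FN surroundings cancel
  the magnitude and cells on the intact lattice crawl at ≤0.16 µm/min,
  capping 12-hour migration at ~115 µm — incompatible with the reported
  behaviour this model family exhibits (near-baseline migration with
  secretion disabled, ~300 µm baselines). The summed-strength form keeps
  the printed quadratic per-element law and leaves all directional
  information to the sampled cues.
- **Mean-normalised von Mises concentration.** With the raw summed
  gradient norm, γ_FN = 300 makes a handful of nearby elements an almost
  deterministic attractor; secreted trails then tether their own leaders
  (deposits behind the leader pull it back with κ ≈ 25) and dense deposit
  fields trap followers. Normalising by the number of sensed elements
  makes κ an intensive "signal coherence" quantity: isolated elements
  and strongly one-sided configurations remain sharp cues, crowded
  symmetric configurations are noisy, and a ten-fold γ_FN increase (the
  haptotaxis-bias rescue condition) meaningfully sharpens cues.
- **Contact repulsion as explicit mechanics**, strength 10 (the
  characteristic default of overlapping-spheres frameworks), exposed as
  `contact_strength`. The stochastic long-range repulsion with c = 0.5
  cannot by itself prevent multi-layer stacking once ECM traction points
  inward.
- **Leader placement**: the largest N with (N−1)·2R_cell < l_entr −
  2R_cell, evenly spaced strictly inside the strip (7 at defaults).
- **Entry-site coverage**: a site counts as covered while any cell
  center is within 2·R_cell (a new cell would overlap).
- **Sensing closures**: sensed iff R_cell < d ≤ R_filo; covered iff
  d ≤ R_cell. Coincident agents are skipped in gradients (undefined
  direction).
- **Degenerate cues**: zero gradient → uniform heading (κ = 0); zero
  blend vector → no ECM force this step; zero raw force with no guiding
  → zero velocity.
- **Remodeling order**: ascending cell id, then element id, applied
  sequentially (exactly reproduced by the compiled counting-sort pass).

## Numerics and performance

The per-step update is vectorised across cells; the per-pair inner loops
(FN accumulation, cell–cell accumulation, contact forces, the sequential
remodeling sweep) are numba-compiled. Neighbour search uses a KD-tree
over the (immovable) FN positions with a slack-radius pair cache: pairs
within `R_filo` + 4 µm are collected at most every 25 steps (cells move
at most 0.16 µm per step, so the cache remains a superset of the true
neighbourhood) and spliced incrementally when FN is deposited or cells
enter; tests check the cache against an all-pairs oracle. One
`numpy.random.Generator` per realization supplies every draw in a fixed
documented order (leader clocks at initialisation; per step: haptotaxis
headings in ascending cell id, repulsion headings, secretion resamples,
follower clocks), so runs are bit-reproducible given (parameters, seed).
A baseline realization (7,200 steps, ~150 cells, ~800 FN elements) takes
roughly 2–4 s on one CPU; dense uniform-secretion conditions (~2,000+
elements under the stream) are several-fold slower.

State is checked finite every step; a NaN/∞ raises with the step index.

## Statistics and experiment catalog

Per-realization statistics are computed on the final snapshot: stream
front travel (max x − R_cell, floored at 0), lateral spread (y range),
mean nearest-neighbour distance, mean leader-to-nearest-follower
distance, circular mean follower heading, mean fiber |cos φ|. A run is
*jammed* if the front travelled < 100 µm in 12 h and *broken* if the
leader–follower separation exceeds 30 µm (two cell diameters); an
ensemble rescue succeeds if at least half its realizations are unbroken.
A realization in which no follower ever entered is recorded as broken.
Two-arm comparisons use the two-sided Mann–Whitney U test with a
Bonferroni correction and report percent changes of ensemble means.

The named condition catalog covers: secretion perturbations (leader
overexpression T_ave = 10; no secretion; both phenotypes secreting at 30
or 10 min), remodeling knockouts per phenotype, the sparse 60 µm lattice
with its contact-guidance (χ = 0.33), repulsion (c = 5) and secretion
(T_ave = 10) rescues, guiding-force sweeps z ∈ {0.25, 0.5, 0.75} × {both,
leaders-only}, and the stream-break rescue catalog layered on the
demonstrated break inducer (leader-only guiding at z = 0.75): χ = 0.33
(both/followers-only), leader T_ave = 10, follower secretion at 90 min,
repulsion c = 0.05 or 2 (both/leaders/followers), and γ_FN = 3000
(both/followers-only).

## Sensitivity analysis

The eFAST implementation samples SALib-style per-factor search-curve
blocks (interference factor M = 4; principal frequency (Ns−1)/(2M);
low complementary frequencies; phase-randomised resampling curves) over
R_filo ∈ [30, 75], χ ∈ [0.25, 1], c ∈ [0, 5] plus a dummy factor that
never reaches the simulator, with the analysis-specific fixed regime
R_cell = 10, l_entr = 150, T_half = 60, s_fn_max = 0.75, λ_FN = 35.
First-order indices come from the spectral power at the principal
frequency's harmonics, total-order indices from the complement of the
low-frequency band; factors are compared against the dummy's per-curve
indices with two-sample t-tests. Estimators are validated against
analytic Sobol decompositions (linear functions and the Ishigami
function) to ±0.05. PRCC rank-transforms inputs and output, residualises
against the other varied factors, and is cross-checked against an
independent partial-correlation implementation to 1e−8.

## Problem sizes used in the shipped checks

The test suite and the acceptance script rerun the in-silico experiments
at reduced ensemble sizes chosen as the package's own verification
scale: 15 replicates per arm for the two-arm comparisons, 10 per
guiding-force arm, and a 36-point random-uniform design with 2 ABM
replicates per point for the PRCC sign checks (the full eFAST pipeline
is exercised end-to-end on analytic test functions, where the truth is
known exactly). Percent-change estimates at these sizes carry
Monte-Carlo standard errors of a few points, which the acceptance tests
account for explicitly.

## What the simulations do and do not show

The generator-free design means every experiment is fully synthetic: the
initial lattice, cell column and parameters define the study conditions.
Passing tests show the implementation reproduces the *model's* emergent
behaviour (relay-driven migration, jamming in sparse or uniformly
secreting matrices, guiding-force narrowing and stream breaks, rescue by
contact guidance), not that the model is a validated description of any
particular embryo. Known limitations:

- Migration in this implementation leans more heavily on the leader
  deposit trail than the original model family reports: disabling all
  secretion reduces front travel by far more than the few percent
  reported there. The discrepancy survived every defensible reading of
  the force law we tested and is documented rather than patched.
- Follower influx at baseline (~140–200 cells) runs somewhat above the
  1–140 range reported for the original implementation.
- 2D only; no cell division, death, phenotype switching, FN decay or
  mechanical strain; no chemotaxis beyond the abstract guiding force.
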