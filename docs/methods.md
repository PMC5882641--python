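# Methods

This note documents the model implemented in `dendrisnip`, its assumptions,
the tunable parameters and their defaults, and the numerical and design
choices made where the underlying literature leaves the model open.

## 1. Neuron representation

A neuron is a forest of rooted trees of cylindrical *segments* attached to
the soma (origin of a right-handed Cartesian frame, μm units). Each segment
stores its own ID, its parent's ID, geometry (start, end, radius) and a
damage state (`intact`, `damaged`, `repaired`, `snipped`, `removed`).
Segments are grouped into *branches* — maximal unbranched chains — joined at
*branch points* (strictly binary bifurcations). Per-entity IDs make every
structural change attributable to a specific segment, which is what the
damage model needs.

Counting conventions: "branch number" (BN) counts maximal unbranched
sections, so BN = 2·BP + (number of primary dendrites) for binary trees with
BP branch points, and tips = BP + primaries. Repaired segments count as
undamaged in every read-out; removed segments are excluded everywhere.

I/O: standard 7-column SWC (soma as a single type-1 point, basal/unspecified
dendrite type 3, apical type 4, 1-based indices, forward parent references
tolerated) and a lossless JSON dump that additionally preserves states and
IDs. SWC cannot represent damage states; writing a damaged neuron warns and
drops them.

## 2. Dendritic growth model

Growth proceeds tip by tip, in segment steps with aspect ratio 1:1 (step
length = twice the segment's radius). At every step a tip either branches,
with probability

    P_br = alpha(order) * (1 - exp(-beta * L_i)),

or elongates. `L_i` counts the steps grown since the soma or the last branch
point (a configuration switch `li_units="um"` interprets it in μm instead;
the per-step reading is the default because β = 0.264 comes from a discrete
per-step formulation, and with μm units the probability saturates within a
couple of proximal segments, giving implausibly bushy trees).

* **Elongation** tapers the radius by `taper_rate` per step (floored at the
  0.2 μm tip radius), sets the length to twice the new radius, and perturbs
  the direction by a small Normal wobble (σ = 3° per step).
* **Branching** spawns two daughters with equal radii R_p/√2 (cross-
  sectional area conservation, floored at 0.2 μm) at half-angles drawn from
  a clipped Normal in a random plane containing the parent axis, on opposite
  sides, so the full bifurcation angle averages twice the half-angle mean
  (28° for GCL → 56°; 24.5° for CA1 → 49°).
* **Self-avoidance**: a candidate segment collides when its axis comes
  within `collision_tolerance × (r₁ + r₂)` of a non-adjacent segment's axis
  (capsule–capsule distance). Adjacent means the parent, siblings, and the
  parent's siblings — capsules that share a joint or branch point and
  therefore formally touch. The tolerance default of 0.5 allows the partial
  interpenetration that is geometrically unavoidable where daughters fan out
  of a branch point (at step = 2r the contact margins scale with the taper
  per step, i.e. a few percent), while still vetoing retracing or crossing
  trajectories. On collision — or on leaving the compartment's bounding
  volume — the candidate is retracted and a fresh direction is drawn
  (first retry: wobble; later retries: uniform tilt up to 75°), up to
  `max_retraction_retries` (10), after which the tip terminates. A
  bifurcation whose daughters cannot be placed falls back to elongation.
* **Termination**: when the radius reaches the 0.2 μm floor the tip stops
  branching and continues for a per-branch terminal length drawn from
  Gamma(shape 4, mean `terminal_length_mean`). A Gamma tail (CV = 1/2)
  rather than an exponential keeps single-neuron totals realistically
  dispersed; exponential tip lengths would make 10-neuron population means
  far noisier than the morphometric variability reported for real
  populations. Orders beyond the deepest entry of the `alpha_schedule` do
  not branch at all; without this depth cutoff the branching cascade at the
  radius floor (0.4 μm steps with per-step hazard α) would produce unbounded
  branch counts.

Bounding volumes: GCL — cone at the soma, half-angle 35°, height 220 μm;
CA1 apical — cone, half-angle 40°, height 250 μm; CA1 basal — hemisphere of
radius 150 μm opposite the apical axis. All configurable.

### Calibrated defaults

The branching-law constants the literature does not pin down (the α
schedule, taper rate, terminal length, bounding volumes) were calibrated
once with `scripts/calibrate_growth.py` so that 10-neuron populations land
inside the reported 1-SD bands of young-adult mouse morphometry:

| class / field | α (orders) | taper/step | r₀ (μm) | L_term (μm) | targets |
|---|---|---|---|---|---|
| GCL | 0.10 (1–4) | 0.022 | 3.0 | 34 | tL 926 μm, BP 12.9, BN 26.7, angle 56° |
| CA1 apical | 0.13 (1–4) | 0.030 | 3.0 | 36 | tL 855 μm, Sholl peak ≈ 100 μm |
| CA1 basal ×3 | 0.13 (1–3) | 0.035 | 1.3 | 25 | tL 734 μm, Sholl peak ≈ 50 μm |

Populations use one counter-based RNG stream per neuron, seeded from
(base_seed, index), so members are independent and individually
reproducible.

## 3. Morphometry and Sholl analysis

`summarize` recomputes branch-level quantities topologically from the
surviving segments, so a branch point whose daughter subtree was removed is
no longer a bifurcation and its two incident branches merge. It reports
total length, BP, BN, primaries, mean branch length, the mean bifurcation
angle (measured between the first segments of the two daughters), and
per-order branch counts/lengths. `sholl` counts segments whose endpoints
straddle concentric spheres about the soma (default step 10 μm; the
radius-0 entry reports surviving primaries). Segments are short relative to
the step, so chord crossings with both endpoints outside a sphere are
neglected; the unit tests check the counts against a brute-force
per-(segment, sphere) enumeration. Growth characterisation reports SD over
neurons; irradiation experiments report SEM over trials × neurons.

## 4. Radiation damage model

Damage is evaluated with the average segment dose (uniform dose to every
segment — appropriate for low-LET radiation; no microdosimetric spectrum).

1. **Assignment.** Each segment of volume V_s = π r² L (μm³) is
   independently damaged with P_d = 1 − exp(−D/D_d), where
   D_d = D_m V_s^η/(K + V_s^η) is the characteristic dose at which 37% of
   segments stay undamaged. V_s is fixed in μm³, so K carries units
   μm^(3η); K = 0.01 places the radiosensitivity transition at segment radii
   of roughly 0.2–0.5 μm (the distal branch orders) and leaves proximal
   orders uniformly resistant. Damaged segments are ordered by increasing
   P_d (ties by ID).
2. **Kinetics.** Damaged segments are repaired (α_R) or snipped (α_S) under
   first-order competing kinetics, solved exactly with Gillespie's direct
   method because segments are discrete; conservation S₀ + S_d + S_s holds
   by construction and the asymptotic snipped fraction is α_S/(α_R + α_S)
   (= 2/3 at the default repair fraction 0.5). Acute exposure only: the
   dose-rate driven damage term (α_d·dD/dt) is parsed but not simulated.
3. **Snip application.** Snip events are assigned, in trajectory order, to
   the highest-P_d segment still in the damaged pool (repair events to the
   lowest-P_d). A snipped segment and everything distal to it is removed;
   a snip site distal to a more proximal snip is absorbed by the same
   removal pass (removal = union of distal subtrees, verified against
   brute-force enumeration). Read-out times are checkpoints of a single
   trajectory, and snips take effect as the events occur.
4. **Population correction.** (X/X₀)_population = exp(−D/D₀) ·
   (X/X₀)_single, with D₀ the 37% neuron-survival dose.

Shipped parameter sets (per neuron type / radiation quality):

| preset | K | D_m (Gy) | η | D₀ (Gy) |
|---|---|---|---|---|
| GCL-gamma | 0.01 | 3000 | 3.5 | 25 |
| GCL-proton | 0.01 | 2000 | 3 | 18 |
| CA1-apical-proton | 0.01 | 2000 | 2 | — |
| CA1-basal-proton | 0.01 | 2000 | 3.5 | — |

CA1 presets ship without D₀ because CA1 comparisons are single-neuron
(Golgi-stained) measurements; requesting population ratios without D₀ is a
configuration error.

### The dose-dependent snip rate

α_S(D) = aD + bD² with α_R = 0.5 α_S. The literature fixes the functional
form and two qualitative constraints — essentially complete resolution of
damaged segments by ~30 days post exposure, and a visible difference between
10-day and 30-day read-outs — but not the coefficients. The two constraints
cannot both hold at every dose under an increasing linear-quadratic rate:
requiring 99% resolution by 30 d at 0.5 Gy forces α_S(10 Gy) ≥ 2/d, which
resolves a 10 Gy exposure within ~2 days. The defaults a = 0.205 /Gy/day,
b = 0.004 /Gy²/day prioritise the resolution constraint (≥ 99% of damaged
segments repaired or snipped by 30 d at all doses ≥ 0.5 Gy) because it
underlies the robust, testable late-time behaviour (30 d ≈ 42 d read-outs);
the 10 d-vs-30 d difference then appears at the low end of the dose range,
where kinetics are still running at 10 d.

## 5. What the synthetic populations do and do not capture

The generator reproduces the population *statistics* of young-adult mouse
GCL/CA1 morphology (totals, branch counts, angles, Sholl peak locations)
and realistic tree topology, which is what the damage model consumes. It
does not emulate reconstruction artefacts of real imaging (z-collapse,
diameter quantisation), inter-animal variability beyond the shipped
parameter spread, spines, or non-binary branch points occasionally seen in
reconstructions. Passing tests therefore validate the model's behaviour on
idealised arbors; absolute dose–response magnitudes additionally depend on
how finely terminal branches are discretised at the 0.2 μm radius floor,
since the thinnest segments dominate the damage-probability budget.

## 6. Numerical choices and degenerate inputs

* RNG: `numpy.random.default_rng`; every stochastic entry point takes a seed
  or Generator; experiment trials use per-(neuron, dose, trial) streams
  seeded from tuples, so any single trial can be replayed in isolation.
* Capsule–capsule distances use the standard clamped closest-point
  algorithm, vectorised over the existing arbor.
* Problem sizes: default acceptance/characterisation runs use 10 neurons per
  class (matching the reported experimental summaries); the test suite's
  Monte-Carlo checks use 1000-trial kinetics ensembles and 100 random trees
  for the snip-propagation oracle, and smaller fast-growing trees for
  engine property tests.
* Degenerate inputs: zero dose yields no damage and unit ratios exactly;
  an empty damaged pool yields a flat trajectory; zero-α schedules give a
  single unbranched dendrite per primary; summarising an empty compartment
  warns and returns zeros; ratios against a zero control raise.
* Validation (`validate`) always checks IDs, contiguity, forest structure,
  branch consistency and the counting identity; the geometry contracts
  (length = 2r, radius ∈ [0.2, 3] μm) are opt-in because hand-built toy
  fixtures and externally reconstructed SWC morphologies need not obey the
  growth model's discretisation.

## 7. Known limitations

Acute low-LET exposure only; no heavy-ion track structure; no spines; no
microglial or age-dependent terms; fragmentation ("snipping") is the only
damage mechanism — retraction-based pruning is not modelled; 2-D projected
Sholl analysis (as in some imaging studies) is not implemented, spheres are
3-D.
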