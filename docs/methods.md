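# Methods

## Model

The plant is the intravenous Bergman minimal model for a type 1
diabetic subject: plasma glucose `x1` (mg/dl), remote insulin action
`x2` (1/min), plasma insulin `x3` (mU/l), insulin infusion `u`
(mU/l/min), and a meal disturbance `d` (mg/dl/min) that decays with
rate `c5` (first-order appearance of a meal in the glucose
compartment).  `c1` is the insulin-independent glucose effectiveness
(zero in T1D), `c3/c2` the insulin sensitivity, `c4` the insulin
degradation rate.  Nominal values and ±30% ranges:

| parameter | nominal | range | units |
|---|---|---|---|
| c1 | 0 | — | 1/min |
| c2 | 0.015 | [0.0105, 0.0195] | 1/min |
| c3 | 2e-6 | [1.4e-6, 2.6e-6] | L/(min·mU) |
| c4 | 0.2 | [0.14, 0.26] | 1/min |
| c5 | 0.05 | [0.045, 0.055] | 1/min |

with basal glucose `Gb = 80` mg/dl and basal insulin `Ib = 7` mU/l.

For synthesis the model is written in deviations from `(Gb, 0, Ib)`
and the meal state is appended, giving a four-state system whose gains
(observer `L`, feedback `K`) are 4-vectors.  The linear part of the
glucose row carries `-Gb` on the insulin-action column; the bilinear
residual `phi(xd) = (-x1d·x2d, 0, 0, 0)ᵀ` is kept separate so that
`phi(0) = 0`.  Parametric deviations enter as `ΔA(t)` with a
worst-case spectral norm `δ` computed by corner enumeration of the
ranges (affine dependence makes corners extremal); with the table
ranges, `δ ≈ 0.06`, dominated by the ±0.06 swing of `c4`.

**Operating box.** All worst-case bounds refer to an axis-aligned box
of deviated states: glucose deviation in [-80, 320] (absolute glucose
0–400 mg/dl), remote action in [0, 0.05], insulin deviation in
[-7, 93] (absolute 0–100 mU/l), meal state in [0, 10] (the largest
protocol meal).  Lower corners follow from non-negativity of the
physical variables; upper corners are the physiologically plausible
extremes.  The state-norm bound `X₊` is the farthest box corner and
the disturbance bound `D₊ = 10` mg/dl/min the protocol maximum.

## Synthesis

Observer and controller certificates follow the attractive-ellipsoid
construction: a quadratic storage function satisfying
`V' ≤ -α V + ε (δ² X₊² + D₊²)` yields exponential convergence into the
ellipsoid `{z : zᵀ P_attr z ≤ 1}`, `P_attr = α/(ε(δ²X₊²+D₊²)) P`, with
ultimate bound `ε (δ² X₊² + D₊²)/α` on `V`.  For fixed `(α, ε)` the
conditions are LMIs (see the `design` module docstring for the exact
blocks); the bilinear dependence on the scalars is resolved by an
outer grid search, `α ∈ {0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1}` 1/min
and `ε ∈ logspace(-4, 2, 13)`, one SDP per point, keeping the design
with the smallest `tr(P_attr⁻¹)` (the quantity that actually shrinks
the ellipsoid; ties — e.g. in the zero-uncertainty limit where every
feasible point certifies a point ellipsoid — break toward the fastest
decay rate).  The controller problem uses identity off-diagonal blocks
in its first LMI (the form the congruence derivation produces) and
majorises the square `X²` by a slack `Q` via a Schur complement.

**SDP solver.** The programs are small (≤ 8×8 blocks, 24 scalar
unknowns), so they are solved by a built-in dense log-barrier
interior-point method with exact Newton steps: phase I minimises a
uniform slack to find a strictly feasible point or certify
infeasibility (the barrier duality gap dropping below the positive
slack proves emptiness), phase II path-follows the objective.  Strict
inequalities are enforced with a margin of 1e-9, feasibility gap
1e-7.  A large analytic box `|θ| < 1e9` on the variables keeps the
analytic centre finite.  The solver reproduces the closed-form
minimum-trace Lyapunov solution on a reference problem to 1e-4.

**Coordinates.** The LMIs contain the isotropic terms `ε L_φ² I` and
`-ε I`, which weigh all state directions equally although the
physiological coordinates span five orders of magnitude (glucose
deviations of hundreds against remote action of a few 0.01).  All
SDPs therefore run in box-normalised coordinates `z = x/w`, where `w`
is the vector of largest absolute box corners per axis.  Gains map
back exactly (`L = w ∘ L'`, `K = K'/w`); the quadratic certificates
transform congruently, so decay rates and ellipsoid membership are
preserved verbatim in physical coordinates.

**Handling the bilinear term.** The Lipschitz constant of `phi` over a
box is `sup sqrt(x1d² + x2d²)` (320 over the default box; in scaled
coordinates `w2·sup sqrt(z1²+z2²)`, about 0.07).  A closed-form
necessary condition shows the scalar Lipschitz channel cannot certify
this: in any diagonal scaling, the remote-action row of the LMI can
absorb a Lipschitz charge of at most about
`sqrt(c2² + (Gb·w2/w1)²)`, while the scaled Lipschitz constant is at
least `max x2d · sqrt((x1d,max/w1·w2/w2)² + 1)`; whenever the glucose
box extends beyond `Gb` the charge exceeds the capacity, for every
`w`.  The packaged defaults therefore certify the bilinear term by
two exact reformulations that keep the printed LMI structure with
`L_φ = 0`:

* **controller** — the term is `-x2d(t)·x1d` with `x2d` confined to
  `[0, 0.05]`, i.e. a bounded time-varying coefficient on the glucose
  row; it is folded into the model-error bound, `δ → δ + max x2d`.
  This embedding is exact: every trajectory of the bilinear plant
  inside the box is a trajectory of the bounded-LTV family.
* **observer** — the estimation-error residual
  `|x1 x2 − x̂1 x̂2| ≤ 2·max|x1d|·max|x2d|` is a bounded perturbation
  and is folded into the disturbance level.

The verbatim Lipschitz channel remains available and is feasible — and
property-tested — over narrow near-equilibrium boxes (e.g. glucose
deviation within ±3 mg/dl), where its premise holds.

**Gain selection.** Minimising the ellipsoid trace flattens the
ellipsoid along the measured (observer) and actuated (controller)
directions, and those axes can be squeezed without limit by ever
larger gains: the optimisation criterion leaves the gain magnitude
unbounded above.  A second SDP pass selects, among certificates whose
ellipsoid size is within 1% of the optimum, the one of smallest
gain-variable max-norm.  Even so, trace-optimal designs remain very
stiff (closed-loop eigenvalues of order 1e8 1/min); they are valid
certificates but impractical actuation policies.  For closed-loop
simulation the package defaults to a moderate **reference gain pair**
for the nominal augmented model,

```
K_ref = ( 0.16, -727.41, -0.036, -3.13 )
L_ref = ( 23.13, -2.69e-5, -3.03e-5, -8.26e-5 )ᵀ
```

which `verify_gains` certifies (both loops Hurwitz, quadratic
Lyapunov certificates found at decay rate 0.01/min).  Such moderate
gains cannot be minimisers of the trace criterion itself — selecting
them requires an explicit gain budget that the optimality criterion
does not provide.

## Closed-loop simulation

Plant (instantaneous, modulated parameters) and observer (nominal
matrices) are integrated jointly, 8 states, with LSODA at
`rtol 1e-8 / atol 1e-10`, segment-wise between meal events; a meal
resets the disturbance state to its magnitude (impulse) after which it
decays at `c5`.  Dense output is sampled on a 1-min grid.  Control is
`u = max(0, K x̂)` evaluated continuously; the clamp count is logged.
The observer starts from the measured glucose deviation and zero
estimates elsewhere.  Halving the integrator tolerances moves the
reported crossing times by well under a minute.

**Scenario I** (single-meal recovery): nominal subject, absolute
initial state (200, 0.001, 7), initial meal disturbance 8 mg/dl/min,
800 min (long enough to cover basal settling with margin).  Reported
metrics: first *sustained* crossing below 180 mg/dl (at least 10
consecutive minutes below), time to basal, and peak infusion.  *Time
to basal* is the first attainment (crossing) of `Gb`; if the
trajectory approaches without crossing, the entry time into the
±2 mg/dl band around `Gb` with no later exit is used.  The crossing
definition was chosen because the monotone closed-loop approach enters
the ±2 band some 50 min before actually reaching 80 mg/dl, and "time
at which glucose reaches its basal value" names the latter event.

**Scenario II** (free living): three days, three meals per day with
timing uniform in the breakfast/lunch/dinner windows
([420, 540], [660, 780], [1140, 1260] min, repeating daily) and
magnitude uniform in [5, 10] mg/dl/min; sinusoidal parameter
modulation with circadian period 1440 min and per-parameter random
phases.  The run starts at the basal equilibrium: the scenario probes
meal response under variability, and starting it from the
hyperglycemic Scenario-I state would place the start-up undershoot
trough (which occurs 150–400 min into a run) inside the assessment
window and conflate two different experiments.

## Virtual cohort

Inter-patient variability: each of `c2..c5` drawn independently and
uniformly from its range (`c1` pinned at 0).  Intra-patient
variability: the sinusoidal modulation above, with each patient's
amplitude clipped per parameter to the distance from the drawn base
value to the nearer range endpoint, so that the *total* parametric
excursion stays within the ±30% population ranges at all times
(drawing at ±30% and then modulating by a further ±30% would produce
±69% total, which is not the stated variability).  Per-patient
randomness derives from the master seed through per-index spawn keys,
so enlarging a cohort never reshuffles earlier subjects.

## Metrics

Per run: min/max glucose, sustained 180-crossing time, time to basal,
peak infusion, severe-hypoglycemia flag (any sample < 50 mg/dl), and
fraction of time in the 70–180 mg/dl euglycemic range.  CVGA: one
point per run — (min BG, max BG) over the run excluding the first
120 min, clipped to [50, 110] × [110, 400] — classified on the
standard 3×3 grid (boundaries at min 90/70 and max 180/300; ties to
the lower-risk zone).  Zone percentages over the cohort sum to 100.

## What the generator does and does not emulate

The virtual cohort emulates bounded parametric diversity and
slow intra-day parameter drift in the minimal model with ideal
intravenous glucose sensing and infusion.  It does **not** emulate
meal absorption dynamics (meals are single-compartment impulses),
subcutaneous sensing lag or noise, pump quantisation, insulin-on-board
constraints, or correlations between physiological parameters.
Passing cohort tests therefore speak to robustness of the control law
within the minimal-model abstraction, not to clinical performance.

## Numerical choices

Strictness margin 1e-9 on all "< 0" constraints; SPD floors 1e-8 on
certificate variables; SDP feasibility gap 1e-7; grid ties broken
toward larger decay rate; integrator LSODA `1e-8/1e-10` with
event-split meals; per-patient sub-seeding via spawn keys; all
randomness flows from a single master seed.

## Known limitations

* **Cohort-level safety claims depend on the sampling scheme.**  With
  independent uniform draws, a subject can combine high insulin gain
  (`c3` at the top of its range) with slow insulin-action decay and
  slow insulin clearance (`c2`, `c4` at the bottom).  For such
  subjects the clamped controller (which cannot command negative
  insulin) overshoots after large meals: post-meal minima reach
  35–50 mg/dl, and at n = 200 a few percent of runs cross the severe
  hypoglycemia threshold; the CVGA mass splits roughly 56% zone B /
  44% Lower D.  If instead all parameters are scaled by a single
  common factor per subject (the sampling implied by the
  nominal/maximum/minimum showcase triple, under which the insulin
  sensitivity `c3/c2` stays nominal), minima stay above 50 mg/dl and
  the CVGA mass concentrates in zone B at the low-90s percent with a
  few percent in Lower C/D — i.e. the optimistic population result is
  reproduced only under correlated sampling.  The package ships the
  independent-uniform sampler; the corresponding acceptance checks
  are strict and fail under it, by design rather than oversight.
* The attractive-ellipsoid certificates for the full physiological box
  use the bounded-coefficient/bounded-residual reformulations above;
  the resulting ultimate bounds are conservative (large ellipsoids),
  and the sharp Lipschitz-channel guarantee holds only near
  equilibrium.
* The output-feedback loop has no integral action: with `c1 = 0` the
  open-loop glucose dynamics are neutrally stable, and after insulin
  action decays the closed loop parks slightly below basal (settled
  value ≈ 78.3 mg/dl for the nominal Scenario-I run — within the
  ±2 mg/dl basal band but not exactly 80).
* Observer estimates of the meal state are essentially inert under
  the reference injection gain (its fourth component is ~1e-4), so
  the feedback's meal-feedforward term contributes little; meal
  compensation is reactive through the glucose channel.
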