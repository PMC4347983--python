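# Model and methods

`kinteam` simulates a cargo pulled along a microtubule (MT) by a team of
one to five kinesin-1 motors. Everything lives on a one-dimensional axis
along the MT with the plus end positive; binding sites sit every
a = 8 nm. Units are nm, pN, s throughout (energies in pN·nm,
kBT = 4.1 pN·nm at ~297 K).

## Mechanics

Each bound motor is coupled to the cargo through two neck linkers
(stiffness K_n, in parallel) in series with a cargo linker (K_c), giving
the equivalent stiffness

    K_e = 2 K_n K_c / (2 K_n + K_c).

The linkage has a slack length L_c: for |x_c − x_r| < L_c (x_c cargo
position, x_r anchor = head midpoint) it transmits no force; beyond it,
it is a linear spring, so the cargo potential of one bound motor is the
three-branch piecewise form ½K_e(x_c − x_r ∓ L_c)² plus the external
load term F_L·(x_c − ⟨x_c⟩). F_L is positive toward the minus end
(hindering). The force on a motor is reported axis-signed (positive =
pulled plus-ward), so mechanical balance reads F_L + ΣF_k = 0; the
chemistry takes the hindering component −F_k.

The cargo is overdamped (drag γ_c) and relaxes exponentially toward the
balance point ⟨x_c⟩ with time constant γ_c / (n_bound·K_e); the update
uses the exact exponential solution, so the engine step need not resolve
the mechanical time scale. Using n_bound·K_e rather than the count of
currently *engaged* (non-slack) linkers is a deliberate simplification:
the step is ≪ the relaxation time, and the fixed point is exact either
way. Thermal motion of the cargo is not simulated as noise; it enters
statistically through the Boltzmann position distributions used for
rebinding (below).

Defaults: K_n = 2 pN/nm, K_c = 0.3 pN/nm (K_e ≈ 0.279 pN/nm),
L_c = 20 nm, γ_c = 9.4·10⁻⁴ pN·s/nm (Stokes drag of a 0.5 µm bead in
water). These are order-of-magnitude standards for kinesin–bead assays
and are config-overridable.

## Mechanochemical cycle

Bound states: [K+MT] → [K·ATP+MT]₁ → [K·ATP+MT]₂ → [K·ADP·Pi+MT] →
[K+MT]. The exit from [K+MT] (ATP binding + neck-linker docking,
completed by the diffusive 16-nm relocation of the trailing head) *is*
the step: the anchor moves ±8 nm. State 1 is treated as instantaneous —
it is far shorter than the dwell — and exists only as the stepping
checkpoint where direction and checkpoint unbinding are decided. The two
remaining states split the rest of the cycle with equal,
force-independent rates.

Load dependence sits on the [K+MT] exit as a Boltzmann factor
exp(−F·δ/kBT) in the hindering load F (assisting loads do not speed the
cycle). Under a large resisting load the motor therefore sits nearly
motionless in [K+MT] — the "anchor" phenotype behind highly loaded
behavior (HLB). Calibration anchors (all single-molecule standards):

* unloaded velocity 800 nm/s at 2 mM ATP → cycle time 10 ms;
* k_on(ATP) = 2·10⁶ M⁻¹s⁻¹ → t_ATP(2 mM) = 0.25 ms, hence the composite
  post-stepping time t_mech = 9.75 ms (k_mech = 2/t_mech per state);
* dwell 70 ms under 5 pN at 2 mM ATP → δ = (kBT/5)·ln((70 ms −
  t_mech)/t_ATP) ≈ 4.50 nm.

The zero-load velocity then follows Michaelis–Menten kinetics with
v_max = 8 nm/t_mech ≈ 820 nm/s and K_m = 1/(k_on·t_mech) ≈ 51 µM; the
property test checks the simulated curve against these model-implied
constants.

Backward steps: at the checkpoint the head lands on the rear site with
probability 1/(1 + exp((F_s − F)/w)), F_s = 7 pN (stall: forward and
backward balance), w = 1 pN. Only the stall anchor is constrained by
data; the logistic shape and width are model choices.

## Unbinding

Detachment from [K·ATP+MT]₂ and [K·ADP·Pi+MT] is neglected (both heads
strongly bound). The two pathways:

* [K+MT]: first-order hazard k_D0 = k_D0,0·exp(|F_k|·d₀/kBT), giving
  P_D0(t) = 1 − exp(−k_D0·t) with P_[K+MT] + P_D0 = 1;
* stepping checkpoint: single per-step probability
  P_D1 = min(1, P_D1,0·exp(|F_k|·d₁/kBT)) (the cap is ours; a
  probability cannot exceed 1).

Constants (fitted upstream to measured single-kinesin run lengths, used
verbatim): k_D0,0 = 0.01633 s⁻¹, P_D1,0 = 0.01, d₀ = 0 (the [K+MT]
pathway is force-independent), d₁ = 1.272 nm. They are intended for
teams of 1–5 motors; the engine enforces that range unless overridden.

In the engine the [K+MT] race between ATP binding and detachment is
resolved by accumulating both hazards against exponential targets drawn
at cycle start, with analytic crossing times inside each step — exact
for piecewise-constant rates, no time-step bias. With d₀ = 0 the
integrated and frozen-force hazards coincide; with d₀ > 0 the hazard is
integrated over the dwell as the force evolves.

At 2 mM ATP this model makes the stepping checkpoint the dominant
unbinding route (>90 % of events), which is exactly what produces HLB:
a heavily loaded motor rarely steps, is therefore rarely tested for
unbinding, and stays bound as an anchor while teammates rebind.

## Rebinding

An unbound motor stays tethered to the cargo; its heads fluctuate much
faster than the bound-motor dynamics, so the fluctuating attachment rate
is replaced by its time average, computed as a spatial average (ergodic
conversion):

1. cargo pdf ∝ exp(−E_c/kBT) from the bound motors' piecewise potential
   (truncated where E − E_min > 30 kBT, 0.1 nm grid);
2. relative pdf of (x_u − x_c) from the unbound motor's own linker
   energy — load-independent, equal to the one-motor zero-load cargo
   pdf centered at 0;
3. their convolution gives pdf(x_u);
4. each site j carries a clipped-parabola attachment profile
   k_A,j(x) = C_A·max(0, 1 − ((x − 8j)/w)²); w = 4 nm so adjacent
   profiles tile the lattice exactly (the reference drawing is
   schematic; this is the gap-free choice);
5. ⟨k_A,j⟩ = ∫ k_A,j(x)·pdf(x_u = x) dx (trapezoid);
6. per interval T: P_A,j = ⟨k_A,j⟩·P_K·T.

With tiling parabolas Σ_j k_A,j averages to (2/3)·C_A over any broad
pdf, so the load-free summed rate is ≈ 0.667·C_A; calibrating to the
~5 s⁻¹ rebinding rate of bead assays gives C_A ≈ 7.5 s⁻¹, and fixing
C_A = 7.68 s⁻¹ yields 5.12 s⁻¹ — both within a couple of percent of the
reference constants (7.68 / 5.1). The calibration is one linear ratio
because every rate is proportional to C_A. The summed rate is
essentially load-invariant (<0.1 % over 0–10 pN); what the load moves is
*where* rebinding happens — minus-ward under hindering load, ahead of
the bound motor under assisting load.

Engine specifics: the pdfs and ⟨k_A,j⟩ are refreshed every
dt_rebind = 1 ms (so cargo motion is tracked), cached per bound-motor
offset configuration (the pdf is translation-invariant), and sites under
a bound motor's head are excluded. Each unbound motor then makes an
independent Bernoulli trial: bind iff ΣP_A,j > r_a1, site by inverse CDF
over the normalized P_A,j with a second uniform. The trial is
conditional on still being unbound (P_K = 1 in the engine), giving an
exponential rebinding time at the calibrated total rate; the
unconditional P_K(t) form is available in the library. Simultaneous
binding of two motors to one site in the same refresh is not excluded
(rare); C_A calibration uses the unoccupied lattice.

## Engine

dt = 10⁻⁴ s by default: since all event instants inside a step are
analytic hazard crossings, dt only sets how often forces (and the
cargo) are refreshed; halving it moves ensemble means by less than one
standard error. The heavy high-load ensembles in the tests use
dt = 1 ms with t_max = 300 s and 200 replicates — at those loads dwell
times are 0.1–1 s, so 1 ms amply resolves the force dynamics while
keeping the suite fast. Each replicate and each motor owns a spawned
`SeedSequence` stream, so event logs are bit-identical given (config,
seed) and independent of execution order.

A run starts with motor 0 bound at site 0, cargo at balance, everyone
else unbound, and ends when all motors are detached (or at t_max). Run
length is Δx_c between start and termination; velocity is run
length / duration per replicate.

## Obstacles and virtual motors

Obstacles are constraints, not objects: a static obstacle clamps the
cargo at its position on contact; a moving one drags it minus-ward at
v_obs. Either releases permanently once the summed linker force on the
cargo exceeds F_obs. "Overcome" = the cargo advances ≥ 8 nm (one site)
past the release point before the team detaches — a lattice-scale
criterion chosen because the reference behavior is stated only
qualitatively. P_oc is the overcoming fraction over replicates, with
binomial SE; surviving n obstacles is P_oc^n.

Virtual motors ablate the ingredients of HLB. Variant 1 keeps the
per-cycle unbinding probability but spreads it evenly over the three
vulnerable states: the real per-cycle probability at the current force
is converted to a hazard and split in three equal exit checkpoints
(1 − (1−p)^⅓ each), preserving the total *exactly*. Variant 2 removes
the force dependence of the stepping transition; variant 3 does both.
Variant 2 teams step at full tempo under load, get tested for P_D1
unbinding constantly, and fail at obstacles — reproducing the
conclusion that load-slowed stepping is the heart of HLB.

## What the simulations do and do not show

The generator *is* the model: there is no external data path. Passing
tests show the implementation reproduces its own calibration anchors,
the analytic constants, and the qualitative collective phenomenology
(exponential run lengths; team advantage at every tested load; more
bound motors and longer runs at 10–12 pN than at 8 pN; obstacle
robustness orderings; assisting-load speed-up of teams). They do not
validate the model against new experimental data, and absolute team run
lengths at high load (several µm here) depend on constants (drag,
stiffnesses, backward-step width) that stand in for unpublished
supplementary values.

Known limitations:

* The exponential Boltzmann slowdown makes the single-motor
  force–velocity curve steeply convex at low load. One documented
  consequence: at a 3 pN resisting load a 2-motor team is *faster* than
  a single motor here (load sharing between engaged motors outweighs
  the retrograde cost of rebinding behind), whereas the reference
  behavior has the team slower below ~6 pN. A flatter low-force
  force–velocity relation would recover that sign but cannot be built
  from the two published dwell anchors alone.
* Motors may pass each other and (transiently) share a site when
  stepping; only rebinding respects occupancy.
* 1-D geometry: no protofilament structure, vertical forces, or cargo
  rotation; obstacles have no dynamics of their own.
* The backward-step law is a logistic stand-in pinned only at stall.
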