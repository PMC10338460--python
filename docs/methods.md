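# Methods

## Process model

The package simulates a single-column bind–elute capture step. Four
components are tracked, indexed (0) salt, (1) mAb, (2) "spent media" (sm, a
lumped impurity pseudo-component), (3) wash-buffer tracer. Only the mAb
binds; salt modulates its adsorption/desorption, and sm and the wash tracer
are inert. The column follows the general rate model: axial
convection–dispersion in the interstitial phase, film mass transfer into
uniformly distributed spherical resin particles, pore diffusion inside the
particles, and mobile-phase-modulator Langmuir kinetics on the solid phase,

    dq/dt = k_a · exp(γ c_salt) · c_p · (q_max − q) − k_d · c_salt^β · q,

with γ = 0 and β = 1 by default (the desorption rate is simply proportional
to the local salt concentration). Boundary conditions: Danckwerts at the
inlet, zero gradient at the outlet, film-flux balance at the particle
surface, symmetry at the particle centre.

Nominal column constants (SI): L = 0.197 m, A_c = 7.85e-5 m², ε_c = 0.4,
ε_p = 0.333, r_p = 4.25e-4 m, D_ax = 1e-7 m²/s, D_p = 1.2e-6 m²/s,
k_f = 8e-3 m/s, k_a = 1 s⁻¹ and k_d = 0.01 s⁻¹ and q_max = 1 g/m³ for the
mAb, timestep h = 15 s, discretization N_z = 40, N_r = 5.

Assumptions and simplifications: one spatial dimension (no radial column
inhomogeneity), isothermal operation, no pressure-drop or pump dynamics, a
single lumped impurity, and a zero-holdup flow controller (inlet streams mix
instantaneously).

## Flowsheet and chosen operating constants

Three upstream vessels (feed, elution buffer, wash buffer) hold 6e-3 m³
each — exactly exhaustible at the maximum flow of 2e-6 m³/s over one 3000 s
episode — with compositions fixed within an episode:

* feed: salt 1e-7, mAb 1e-8, sm 1e-7 g/m³ (the product is one tenth of the
  impurity level, on a trace background of salt);
* elution buffer: salt only, **10 g/m³**. This value is a design choice of
  the package: it makes the desorption time constant 1/(k_d·c_salt) = 10 s
  shorter than one 15 s control interval and the elution retention factor a
  few column volumes, so a complete load–wash–elute cycle fits comfortably
  inside an episode (a trained policy exhibits several cycles);
* wash buffer: inert tracer at 1e-7 g/m³, the feed's concentration scale.

The feed concentrations are kept exactly as specified even though they are
physically tiny; all headline metrics (purity, recovery percentages) are
ratios in which the absolute scale cancels. Absolute masses reported by this
package are therefore on the ~1e-11 g scale and are not comparable with
absolute masses quoted elsewhere for this process; percentages are.

Tank accounting credits the effluent at the end-of-step outlet concentration
times F_in·h — the same quadrature the backward-Euler column step uses —
which closes the discrete mass balance to ~1e-10 relative (the only leak is
the radial quadrature of the 2/r pore-diffusion term, which is not exactly
telescoping at the particle centre).

## Discretization and solver

Space is discretized by orthogonal collocation on finite elements: each of
the N_z (axial) and N_r (radial) equal-width elements carries a polynomial of
order N_p (default 4; unstated in the source material, chosen as the standard
order for this model class), with nodes at the element boundaries plus the
roots of the shifted Legendre polynomial of degree N_p − 1. The PDE is
collocated at interior nodes; element interfaces impose C¹ continuity;
domain boundaries impose the physical boundary conditions (algebraic rows,
mass-matrix zero). Quadrature weights exact for polynomials up to order N_p
(plain axially, r²-weighted radially) give column inventories consistent
with the grid.

Time integration is backward Euler. The constant-coefficient part of the
semi-discrete system — transport, film exchange, pore diffusion, boundary
rows, plus the low-loading linearisation k_a·q_max·c_p of the adsorption
term — is assembled once per component into a sparse matrix; the
backward-Euler matrix M − h·A(u) is LU-factorised per flow condition and
cached (the three inert components share one factorization). The remaining
binding nonlinearity is resolved by fixed-point iteration (relative
tolerance 1e-10, max 50 iterations) preconditioned by that LU. During
elution the desorption term k_d·c_salt·q has h·k_d·c_salt ≈ 1.5 > 1 and the
fixed point diverges; divergence is detected after two growing increments
and the step is redone by Newton iteration on the full residual with the
analytic binding Jacobian. Component systems are solved salt-first, since
the protein's kinetics read the new salt pore field.

Negative concentrations are never clipped. A step is rejected (raising
`NegativeConcentrationError`) if any value undershoots below 1e-9 plus 5% of
the component's running scale (the largest inlet or field value seen, or
q_max for the solid phase). Spectral collocation leaves Gibbs wiggles of a
few percent of the driving scale at sharp fronts — the salt step at elution
onset is the worst case — while genuine solver failures overshoot by orders
of magnitude, so the guard separates the two cleanly.

## Control environment

Episodes are 200 steps of 15 s. A raw policy action in [−1, 1]⁴ maps
affinely onto the three flows in [0, 2e-6] m³/s; the fourth entry is
thresholded at its midpoint (negative → waste, non-negative → product), the
natural symmetric choice for a binary valve.

Observation features per step (13): the commanded wash flow, and
per-component mass fed into the column, mass leaving the outlet, and
approximate mass held in the column. In/out masses are per control step, not
cumulative, which keeps the features bounded. Ten consecutive steps are
concatenated (left-padded with the earliest step at episode start), and each
feature is divided by a calibration maximum and clipped to [0, 1]. The
calibration maxima come from one scripted maximum-flow run on the nominal
column (half an episode loading, a quarter eluting, a quarter washing) and
are then fixed.

Reward, with tank masses in grams: Δ_mab = mab_prod − mab_waste,
Δ_sm = sm_waste − sm_prod, R_mass = α·Δ_mab + Δ_sm with α = 5;
R_conc = max(mab_prod/(mab_prod + sm_prod), 0.1), with the empty-tank 0/0
defined as the 0.1 floor; R_clean = max(mab_prod − sm_prod, 0);
R_purity = max((R_conc − 0.3)/0.7, 0); P_remaining = mab_col if the episode
is over and the column still holds more than mab_max, else 0. The cumulative
score is R = β(R_mass·R_conc + R_clean + γ·R_purity − P_remaining·I_done)
with β = 1e6, γ = 100, and the step reward is R_t − R_{t−1} (so step rewards
telescope to the final score by construction). mab_max defaults to 5% of the
mAb mass loadable in one episode at maximum flow (3e-12 g) — the penalty
should fire only on a materially unfinished elution. Reward state is taken
from the flowsheet bookkeeping, not from the normalized observations.

Column variability: each training episode redraws the perturbed parameters
(axial dispersion, pore diffusion, column porosity, particle porosity) as
x → x(1 + S·X), X ~ U(−1, 1) independently per parameter, S = 0.2 for
training. Array-valued parameters share one draw — the perturbation models a
property of the packed column, not of a solute. The hold-out set is eight
columns drawn once at S = 0.05 from fixed per-column seeds.

## Agent

TD3 with temporal-convolutional actor and critics: two 1-D convolutions over
the 10-step window (128 then 64 filters, kernel 3, stride 1, ReLU), flatten,
a 300-unit ReLU dense layer, then 4 tanh-bounded outputs (actor) or — after
concatenating the action onto the flattened embedding — 1 output (critic).
Networks, backpropagation and Adam are implemented in NumPy; single-threaded
execution makes training bit-reproducible under a fixed seed.

Hyperparameters: learning rate 4e-4 (both networks), batch 200, four
gradient rounds per four environment interactions, critic updated twice per
actor update, replay capacity 1e6. Values that had to be chosen here follow
common TD3 reference settings: discount 0.99, Polyak rate 0.005, target
policy noise 0.2 clipped at 0.5, proportional prioritization exponent 0.6
with importance weights annealed 0.4 → 1. Exploration noise is Gaussian with
a linear decay (0.3 → 0.02 over the planned interaction budget by default).
Experiences are stored as full SARSA tuples including the behaviour's next
action, but the bootstrap target recomputes the next action with the
smoothed target policy, as TD3 prescribes. Rewards are multiplied by a
training-side scale (default 1e-8 ≈ 1/(β·γ)) before entering the replay
buffer so that Q-targets are O(1) for the optimizer; reported scores are
always unscaled. Multiple worker environments (default 1) step in lockstep
feeding one buffer and one learner. The best-scoring evaluation policy is
saved during training.

## Benchmark recipe

The static benchmark cycles load (feed at maximum flow, valve to waste) →
wash (wash buffer, waste) → elute (elution buffer, product), repeating until
the episode ends, possibly mid-cycle. Because a real operator's switch times
are process knowledge not available here, they were calibrated once by a
scripted grid search (`calibrate_recipe`) over load/wash/delay/elute
durations on the nominal column — best product mass among candidates
reaching 99% purity — and frozen: load 300 s, wash 60 s, no elute delay,
elute 150 s (510 s cycle, ~5.9 cycles per episode). On the hold-out columns
this recipe reaches ~100% purity, ~95% recovered cycled mAb and ~56%
recovered total mAb.

## Metrics

purity = 100·mab_prod/(mab_prod + sm_prod) (flagged undefined on an empty
product tank); recovered cycled = 100·mab_prod/(mab_prod + mab_waste);
recovered total = 100·mab_prod/(initial feed-vessel mAb). Aggregation over
columns is the unweighted arithmetic mean. Tolerated numerical undershoot
can leave a tank mass a hair negative, so percentages are clamped to
[0, 100].

## Validation experiments and problem sizes

`chromarl.experiments` packages the validation runs used by the test suite
and `scripts/acceptance.py`; sizes were chosen so a full pass completes in
minutes on one CPU:

* **Conservation**: one full 200-step benchmark episode on the nominal
  N_z = 40 column; drift ~1e-10 relative to processed mass.
* **Oracle comparison**: inert-tracer breakthrough on a reduced column
  (N_z = 8) against an independent finite-difference method-of-lines
  reference (central differences, 250×15 grid, adaptive BDF). The fixture
  uses D_ax = 1e-4 m²/s, F = 2e-7 m³/s and h = 0.25 s: at the nominal
  parameters the axial Peclet number is ~1e5 and no practical grid resolves
  the physical front (the production configuration is numerically
  dispersion-dominated through its 15 s implicit step), so the comparison is
  run at a resolvable Peclet (~13) with a small timestep to isolate the
  spatial discretization. Agreement is ~0.3% relative L2.
* **Isotherm**: kinetics integrated to steady state at fixed pore
  concentration vs the closed form, horizons scaled to the relaxation time;
  error ~1e-13.
* **Randomization**: 10,000 draws, bounds plus Kolmogorov–Smirnov against
  U(−1, 1).
* **Toy bandit**: one-step continuous bandit with reward −(a − 0.3)²;
  TD3 with small networks (8/8 conv filters, 64 dense) reaches the optimum
  within 0.05 in ~4000 one-step episodes (~15 s).
* **Scaled-down training**: a coarse column (N_z = 6, N_r = 2, N_p = 3),
  16/16-filter networks, batch 100, 50 episodes — about two minutes per
  seed — evaluated against a seeded random policy on three S = 0.05 hold-out
  columns. The study conditions themselves (S = 0.2 training randomization,
  200 steps of 15 s, reward constants) are never changed, only grid and
  budget sizes.

## What the simulation does and does not emulate

The generator reproduces the structure of the physical problem — kinetic
capture with salt-controlled elution, column-to-column parameter spread,
partial breakthrough at high flow — so passing tests demonstrate that the
solver, environment and learner behave correctly under those mechanisms. It
does not emulate measurement noise, pump/valve dynamics, resin aging within
a run, competitive binding between proteins, or feed-composition drift; at
the specified feed scale the column never approaches capacity saturation
(breakthrough is kinetic, not capacity-driven), and the 15 s implicit step
smooths fronts far beyond the physical dispersion. Conclusions about real
column hardware would need finer time resolution, a saturating feed scale
and experimental validation.

## Known limitations

* The printed feed-concentration scale (1e-7 g/m³) is inconsistent with the
  ~1e-5 g product masses quoted in the literature comparison; only
  scale-free percentages are comparable.
* The fixed-point iteration named for the time integrator is only
  convergent because the stiff linear physics sits inside the LU matrix;
  during elution it hands over to Newton.
* The benchmark recipe is this package's own calibrated stand-in for an
  undisclosed operator recipe; its role (fixed schedule, ≥99% purity) is
  reproduced, not its exact numbers.
* Reported reward scores depend on β, γ and the vessel scale and are not
  comparable across differently scaled setups.
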