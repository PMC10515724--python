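# Methods

## Process model

The reactor is modeled as a perfectly mixed fed-batch vessel: feed inflow,
no outflow. For the concentration vector `c` (one entry per measured
extracellular species; viable cell density `Xv` is a named member of the
roster, not a special position) and culture volume `V`:

    dc/dt = v(c) * Xv + sum_k D_k * c_in_k - c * sum_k D_k
    dV/dt = V * sum_k D_k = sum_k F_k
    D_k   = F_k / V

`v(c)` is the vector of specific reaction rates (per unit viable biomass).
Assumptions inherited from this formulation: perfect mixing; density effects
of feeding are volumetric only; pH, temperature and dissolved oxygen are
externally controlled and not modeled; evaporation and sampling-volume
losses are ignored. Feeds are piecewise-constant rate schedules with
non-negative rates and compositions.

The hybrid model closes the balances with a feedforward network
`v = net(c ⊘ cmax, V/Vmax)`:

* inputs: concentrations clamped at >= 0, divided element-wise by the
  per-species absolute maximum `cmax`; optionally the culture volume divided
  by its maximum as one extra input. In the 25-species synthetic
  configuration the volume input brings the input count to 26, which is the
  only input count consistent with all published per-architecture weight
  counts for that configuration; in the 30-species configuration no extra
  input is used.
* hidden layers: `tanh` (classical/shallow regime) or `ReLU` (deep regime);
  the ReLU subgradient at 0 is taken as 0.
* output layer: affine, unscaled — the network carries the physical rate
  magnitudes directly. Weight flattening order (used by every weight-space
  Jacobian and gradient): layer by layer, connection matrix row-major, then
  the layer's bias vector.

## Integration

Classical fixed-step RK4. The step grid is the union of output (sampling)
times and feed-schedule breakpoints, each span subdivided to at most the
configured substep, so the feed rate is constant within every step and the
volume equation is integrated exactly. Default substep 0.5 h between 24 h
samples; this resolves the culture dynamics comfortably (halving it changes
simulated concentrations in the 6th significant digit). The state is
integrated unconstrained — negative concentrations are not hidden by
projection (an optional post-step projection exists, off by default) — but
network inputs are clamped at >= 0 before normalization so the kinetics
never extrapolate to negative abundances. Non-finite states abort with the
failing time.

## Objective and gradient engines

Training minimizes the weighted mean squared error over all measured scalar
residuals of the training subset (a measured value for one species at one
time point is one residual; missing values are excluded from T):

    WMSE = (1/T) * sum_t ((c*_t - c_t) / sigma_t)^2

Measurement SDs of zero are disallowed; sigmas are floored at 1e-6 x the
species' cmax.

Both gradient engines compute the exact gradient of this objective through
the discretized dynamics (forward-mode differentiation of the RK4 map, so
the gradient matches finite differences of the objective the optimizer
actually sees; sensitivities start at zero because initial conditions do not
depend on the weights):

* **Indirect**: the weight-space sensitivity matrix `S = d(state)/d(theta)`
  (shape `n_states x nw`, volume row included) is advanced through every RK4
  stage alongside the state, using the state Jacobian of the hybrid RHS
  (including the chain through the network input Jacobian and the input
  clamping/normalization) and the network weight Jacobian at each stage.
* **Semidirect**: each RK4 step is factored into an `n_states x n_states`
  propagator `A` and four `n_states x n_out` injection blocks `C_i` — the
  sensitivities of the states with respect to the network's output channels
  at the four stages. These blocks are the ODE-carried quantities and their
  size is independent of the network; the weight-space sensitivity is then
  assembled algebraically as `S+ = A S + sum_i C_i * (dv/dtheta at stage i)`.
  This factorization was chosen over the common approximation that composes
  state-vs-rate-channel sensitivities with the weight Jacobian only at
  measurement times: that approximation is exact only when `dv/dtheta` is
  constant along the trajectory (counterexample `c' = w c`), whereas the
  per-stage composition reproduces the indirect gradient to machine
  precision while keeping the carried ODE dimension fixed.

A central finite-difference engine (O(nw) objective evaluations) serves as
the independent oracle in the tests; both engines agree with it to < 1e-4
relative on random small hybrid problems and with each other to < 1e-6.

The Levenberg–Marquardt trainer additionally uses the full residual Jacobian
`dr/dtheta = S/sigma` from the indirect engine.

## Trainers

**Classical (`train_lmm`)** — damped Gauss–Newton on the weighted residual
vector: solve `(J'J + lambda I) delta = -J'r`, accept a trial step only if
the SSE decreases; `lambda` x10 on rejection (or a divergent trial
integration), /10 on acceptance, `lambda0 = 1e-3`. After each accepted step
the WMSE on a validation set is evaluated; the validation set is a
noise-augmented copy of the training data (one Gaussian draw per measured
value with SD equal to its recorded measurement SD — the augmentation route
to early stopping when no experiments can be spared). Stopping: validation
error not improving for `patience` (default 25) consecutive accepted steps,
a relative SSE improvement below `ftol`, or `max_iterations`. The whole
procedure restarts from fresh uniform(-0.01, 0.01) initializations (default
10) and the run with the lowest validation WMSE is kept; the kept weights
are those at the validation-error minimum. The augmented points are used
purely for stopping, never added to the training objective; both error
traces are recorded.

**Deep (`train_adam`)** — per iteration: sample a minibatch of experiments
(`ceil(fraction * n_train)` without replacement; the minibatch unit is a
whole reactor run because the integration/sensitivity unit is a trajectory)
and one dropout mask (inverted dropout on hidden nodes, keep probability
`1 - p_drop`; one mask held fixed for the entire gradient evaluation — all
time steps, all experiments — because per-step masks would make the ODE
right-hand side discontinuous within one evaluation); compute the
semidirect gradient of the minibatch WMSE under the mask; apply the
bias-corrected ADAM update (`alpha = 0.001`, `beta1 = 0.9`, `beta2 = 0.999`,
denominator offset `1e-7` — the canonical interpretation of the fourth
hyperparameter). The full-batch, maskless training WMSE is recorded every
iteration and the kept weights are the trace argmin (the initialization
counts as iteration 0). A single random initialization is used. Non-finite
gradients skip the iteration; more than 10 consecutive skips abort.

Dropout is never applied at evaluation/simulation time.

## Model selection

AICc is computed on the training subset as
`T ln(WMSE) + 2 nw + 2 nw (nw+1) / (T - nw - 1)` with `T` = the number of
scalar training residuals (the same T that normalizes the WMSE; the
correction requires `T > nw + 1`, otherwise AICc is undefined and recorded
as missing). Resampling draws `n_partitions` independent train/test splits
of whole experiments, shared across all structures for paired comparison;
`evaluate_structure` trains once per partition and reports mean ± SD of
train/test WMSE and AICc plus the weight count. A partition is recorded as
unstable — excluded from the means, counted in the report — when training
diverges or the final train WMSE exceeds 10x the constant-prediction
(per-species training mean) baseline. The selected structure is the stable
one with minimum mean test WMSE; AICc is reported alongside because the two
routes do not always agree. `compare_structures` reports percentage deltas:
reductions relative to the first summary, increases relative to the
reference, rounded to one decimal for display only.

## Synthetic data generator

The generator's job is the statistical structure of a process-development
dataset, not any particular published flux model. The ground truth is a
reduced CHO-like kinetic model (~30 rate constants, all documented on the
`GroundTruthModel` dataclass) with: Monod growth on glucose and glutamine
with lactate inhibition; overflow lactate production that switches to
lactate consumption on glucose depletion; glutaminolysis-driven ammonium
production with late consumption once glutamine is spent; growth-coupled,
saturating amino-acid uptake (alanine and glycine are produced); basal
death plus glucose-starvation death; and product synthesis that accelerates
at the induction time (default 96 h, emulating a production-phase
temperature shift) while growth slows. Units: hours, liters, mM (viable
cells 1e9 cells/L, product g/L); seeded at 3.0 Mcell/mL.

Defaults were calibrated once, by inspecting noiseless trajectories, so the
stated qualitative features hold across the design space: the lactate shift
occurs mid-culture, viable cells peak near 10 Mcell/mL with a gentle death
phase, and glucose depletion precedes the shift. The 2-factor central
composite design varies pre- and post-induction feed rates (center
(5e-4, 1e-3) L/h, half-ranges 50% of center, rotatable axial alpha = sqrt 2):
4 square, 4 star, 1 center run; 240 h horizon, 24 h sampling, 25 recorded
species. Noise: independent Gaussian with SD = 10% of each species' maximum
over the noiseless dataset; negative noisy values are retained; the sigma
tables stored with the dataset are exactly the SDs used. The normalization
maxima `cmax` are the per-species maxima of the noiseless data. The
intended split trains on center+square and tests on the star points — an
extrapolation test at the design extremes.

A 30-variable "experimental-style" variant pads the roster with first-order
by-product pools (glycerol, citrate, acetate, formate, tryptophan, cystine in
place of cysteine, product `P` in place of `mAb`), randomizes feed rates
(±50%) and compositions (±20%) per run, samples daily over 12 days for 24
runs, and applies the relative error model (5% product, 10% viable cells,
20% other metabolites, floored at 2% of cmax), optionally with missing
measurements.

What the generator does **not** emulate: intracellular state (the truth's
induction switch is time-triggered, so a static network of the extracellular
state can only represent it through correlates such as volume and substrate
levels — a deliberate, realistic structural bias); correlated or
non-Gaussian measurement error; sampling-volume losses; batch-to-batch
variability in the initial state. Passing tests therefore demonstrate that
the machinery recovers kinetics under the stated noise and design
conditions, not performance on any particular real process.

## Reduced-scale study conditions

The full-scale protocol (substep 0.5 h, ADAM for 1000 iterations at
alpha = 0.001, 10 LMM restarts, 10 resampled partitions) is the library
default. The bundled studies (`biohybrid.workflows`, the acceptance script,
tests) run scaled-down versions chosen as this package's study conditions:

* training integrates at a 4 h substep (6 substeps per sampling interval;
  evaluation always re-integrates at 0.5 h — the coarse-trained weights
  score within a few percent of their coarse-grid objective on the fine
  grid);
* the noise-floor study trains 26-[10,10]-25 with ADAM at alpha = 0.005 for
  800–1000 iterations on the 5 center+square runs, with standard stochastic
  regularization (minibatch 0.8, dropout 0.2);
* it uses `tanh` hidden nodes. With the prescribed uniform(-0.01, 0.01)
  initialization, ReLU networks start with roughly half their hidden units
  inactive on the all-non-negative inputs; an inactive unit has exactly zero
  subgradient, and bounded ADAM steps spend most of a short budget escaping
  the resulting plateau (deterministic full-batch ADAM converges *to* it),
  whereas Levenberg–Marquardt's large curvature steps leave it in a few
  iterations. This is a budget artifact, not a property of the method —
  documented here as a known limitation of ReLU + tiny-uniform
  initialization at reduced iteration counts;
* the structure sweep uses 2 partitions, ADAM at 100 iterations or LMM at
  15 iterations with 2 restarts.

Expected pattern at these conditions (reproduced by the acceptance script):
the generating model scores a noisy WMSE near 1 (chi-square concentration:
mean 1, relative SD sqrt(2/T)); the trained model's noise-free test WMSE
falls below its noisy test WMSE (the weighted objective filters the noise
rather than fitting it); and the noisy test WMSE lands well inside [0.8, 3].

## Numerical choices and degenerate inputs

* Feed schedules must be non-overlapping and ordered; rates and
  compositions non-negative. Outside every segment the feed rate is zero.
* `p_drop = 1` is rejected (degenerate network); `p_drop = 0` is the
  maskless network exactly.
* AICc requires `WMSE > 0` and `T > nw + 1`.
* Partition plans require `1 <= n_test < n_experiments`.
* The LM normal equations fall back to increased damping on singular
  systems; trial-point integration failures reject the step rather than
  aborting the run.
* All randomness flows through seeded `numpy.random.Generator` instances;
  both trainers are bit-reproducible for a fixed seed.

## Known limitations

* The semidirect engine's per-step factorization costs four network
  weight-Jacobian evaluations per step, like the indirect engine; its
  advantage here is the fixed carried ODE dimension, not a guaranteed
  wall-clock win at every network size.
* LM with the plain `lambda I` damping can settle in a different basin than
  trust-region solvers on wide networks; the restart mechanism, not the
  damping schedule, is the safeguard.
* The AICc values printed by `evaluate_structure` depend on the residual
  count T of the training subset; comparisons are only meaningful within a
  fixed partition plan.
* Training cost is dominated by Python-level per-step overhead for small
  networks; vectorizing across experiments would be the next optimization.
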