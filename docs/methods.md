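# Methods

## The inference problem

An agent-based system is a set of agents `a_1 … a_n` whose states
`s_i^t` (positions, velocities, discrete flags …) evolve by a shared
transition rule: each agent's next state depends on its own state and on
the states of the agents it interacts with.  Observing only trajectories,
we want to recover *who interacts with whom, and how strongly, per state
variable* — e.g. the force component a particle exerts on a neighbour's
`v_x` is generally different from its effect on `v_y`.

AgentNet frames this as next-state prediction on a fully connected graph.
Writing the pairwise part of the transition as
`h_pair(s_i, s_j, u) = Σ_q w_ij^q(s_i, s_j, u) · v_j(s_j)`,
the non-negative scalar `w_ij^q` is the interaction strength of pair
(i, j) for output variable q, `v_j` carries the neighbour's content, and
`u` is any global variable (such as an interaction length).  The network
mirrors this decomposition so that, after training, its attention weights
can be read off as estimates of `w_ij^q`.

## Architecture

* **Encoder.** One MLP `[input, 256, 3 × A]` (Mish activations,
  `f(x) = x·tanh(softplus(x))`) maps each agent's state to key, query and
  value vectors of width `A` (16 for the simulated systems, 96 for the
  swift-like spatiotemporal configuration).  Because the encoder acts per
  agent, two agents with identical states are exactly interchangeable.
* **Variable-wise neural attention.** For every output variable q an
  independent MLP (widths from the per-system table, final width 1) maps
  the concatenation `(key_i, query_j, u)` to a coefficient `a_ij^q`,
  squashed to `α_ij^q = sigmoid(a_ij^q) ∈ (0, 1)`.  There is deliberately
  *no softmax across neighbours*: α is an absolute strength, so a row may
  sum to more (or less) than one.  The diagonal is excluded; self
  information travels only through the agent's own value vector.
* **Aggregation and separated decoders.** The context for variable q is
  the mean over `j ≠ i` of `α_ij^q · value_j`.  Decoder q (an MLP
  `[2A, 128, D]`) sees only `(value_i, context_i^q)`; consequently
  `∂(output q)/∂(α^{q'}) = 0` for `q' ≠ q`, which is the property that
  makes the attention interpretable per variable (a finite-difference
  test asserts it exactly).
* **Heads.** Deterministic/binary systems emit logits.  Stochastic
  systems feed each decoder output into separate mean and variance MLPs
  `[D, 64, 1]`; variances go through `softplus(·) + 1e-6` — smooth,
  strictly positive, and the floor prevents the Gaussian NLL from
  diverging on easy targets.
* **Recurrent variant.** For systems with memory the encoder runs through
  an LSTM (hidden/cell width 128) before the key/query/value projection,
  so hidden drivers (e.g. an unobserved propulsion force) can be inferred
  from an 8-step observation window.  Hidden and cell states are
  initialized from an agent's first observed state by two dedicated MLPs
  trained with the rest of the network.
* **Baselines.** MLP/LSTM variants drop the attention core (decoder
  widened to `[2A, 256, 256, D]`, context fixed at zero — provably
  independent of other agents); GAT substitutes a single softmax-
  normalized inner-product attention (128-d projections); GAT3+ uses
  three heads.  They share the encoder and I/O contract, so attention
  comparisons isolate the attention scheme itself.

### Input handling

Inputs are standardized per variable with training-set statistics stored
inside every checkpoint.  For grid data, whose state space is tiny
(392 distinct cell states on a 14×14 board), the forward pass deduplicates
repeated (key, query) rows before the attention MLPs; this is an exact
algebraic rewrite (asserted bit-for-bit in the tests), not an
approximation.

## Ground-truth simulators

* **Cellular automaton.** 14×14 non-periodic board (edge cells simply
  have fewer neighbours; nothing in the dynamics wraps), binary states,
  the classic two-rule update (survive on 2–3 live Moore neighbours,
  birth on exactly 3).  Ground-truth interaction: indicator of Chebyshev
  distance ≤ 1 (Euclidean ≤ √2).
* **Vision-sector Vicsek flock.** Agents in continuous 2-D replace their
  velocity with the average over themselves and the agents within radius
  `r_c = 1 m` and inside their vision cone, plus independent
  `N(0, σ = 0.1)` noise per component, then move by the new velocity.
  The printed cone angle of 120° is ambiguous between a half-angle
  (240° field of view) and a total opening; both readings are a config
  switch (`sector_is_full_angle`), the half-angle reading is the default,
  and the reference study uses the total-opening reading so the recovered
  width is commensurate with the configured 120°.  Agents start uniformly
  in a disk of radius √5 with speed 0.5 m/step and random headings; an
  agent at exactly zero speed has no heading and sees nobody.
* **Active Ornstein–Uhlenbeck particles.** Overdamped Langevin dynamics
  `γ ẋ = F_ext + F_int + sqrt(2γT) η + γ f` with soft-core repulsion
  `V = exp(−r³/R³)`, harmonic confinement `F_ext = −k x` (k = 0.1), and
  hidden propulsion `τ ḟ = −f + sqrt(2 D_a) w`.  Euler–Maruyama with
  dt = 0.05; the stored "velocity" is the per-step displacement.  The
  propulsion enters the displacement as `f·dt` (the literal discrete
  table adds bare `f`, which is dimensionally inconsistent with the
  continuous equation; we integrate the equation).  Likewise the
  propulsion noise amplitude is `sqrt(2 D_a)/τ` per unit √time, which
  reproduces the stationary identity `E|f|² = 2 D_a/τ = U_0²` (checked
  against the discrete-chain closed form within Monte-Carlo error).
  Coincident particles exert zero force — the analytic r→0 limit, since
  the magnitude scales as r².  Exported trajectories never contain `f`;
  inferring it from history is the point of the recurrent model.

At high density and low temperature the repulsive particles form a
*cluster crystal*: several particles share a lattice site, and the
site lattice is hexagonal with constant ≈ 1.4 R.  A finite purely
repulsive blob without confinement expands indefinitely (we verified the
drift), so the package's validation condition keeps the weak harmonic
trap (k = 0.1) with T = 0.02 and D_a = 0.2, n = 100 particles, 5·10⁴
steps — which settles into the expected pattern (spacing/R 1.39–1.42
across seeds at R = 3; 6.9–7.0 absolute at R = 5).

## Training

Adam with the full-scale schedule as defaults: learning rate 5·10⁻⁴,
batch 32, learning rate × 0.7 whenever the test loss fails to improve by
more than 10⁻⁴ for 30 consecutive epochs.  Binary outputs train with
mean binary cross-entropy (computed stably from logits); stochastic
outputs with the sum over variables of univariate Gaussian NLLs, in
normalized units.  Multi-step training for the recurrent model feeds the
model's own samples back (reparameterized as `μ + sqrt(s²)·ε`, so
gradients flow through the rollout); teacher forcing is a config switch.
For dynamic-node sequences with unequal trajectory lengths, per-sample
weights proportional to the inverse frequency of each length class
(rescaled so the all-equal case reduces exactly to the unweighted mean)
compensate the imbalance.  A non-finite loss aborts training with a
diagnostic rather than continuing silently.

### Desk-scale reference studies

The bundled studies (`agentnet.protocols`) are sized for minutes on one
CPU core; learning rates were calibrated once on pilot runs at these
sizes (the full-scale schedule above remains the default elsewhere):

* Grid automaton: 2,000 transitions, lr 2·10⁻³, 26 epochs (~8 min).
  Learning proceeds through a plateau followed by a sharp transition in
  which the attention map collapses onto the true neighbourhood; the
  grid preset therefore initializes the final attention bias at −2
  (α ≈ 0.12 at init, a weak-coupling prior that also matches the
  near-zero attention an untrained full-scale model displays), which —
  together with the doubled desk-scale learning rate — moves the
  transition onset reliably inside the budget across seeds.  Held-out
  per-cell accuracy then reaches 100%; attention on the eight Moore
  neighbours rises toward 1 while the remaining 187 cells decay toward
  0.
* Flock: 40 agents, 1,800 one-step transitions, lr 2·10⁻³, 26 epochs
  (~6 min).  Attention-vs-membership ROC-AUC exceeds 0.99; half-maximum
  thresholding of the heading-aligned attention map recovers the
  interaction sector to within a few percent in radius and degrees.
* Active particles: the simulator-side spacing checks above.  Training
  the recurrent model end to end is an hours-scale run and is exercised
  at toy size in the test suite only; rollout correctness (42-step
  generation, attention histories) is tested independently of training
  quality.

## Dynamic nodes

Trajectories from real tracking data start and stop mid-sequence.  A
per-agent registry maps agent id → (hidden, cell, last-seen step).
Present-and-known agents advance their LSTM chain; newly entered agents
get a fresh chain from the init MLPs; absent agents are excluded from
attention aggregation (they contribute to no α and no context mean) and
from the loss.  With an all-present roster the machinery is *exactly*
(bitwise) the plain recurrent forward pass, and adding an always-absent
agent changes nothing — both are asserted in tests.  Reappearing agents
resume their stored chain by default (real occluded birds rarely
reappear; restarting is the config alternative).  The synthetic occlusion
generator assigns each agent a contiguous presence interval with
geometric lengths (median configurable, mimicking half the trajectories
lasting under ~150 frames), with an option to punch non-contiguous holes
to stress the registry.

## Estimators

* **ADE/FDE.**  Mean Euclidean error over all predicted steps; final
  error at the last step, or per-agent termination steps when
  trajectories end early.
* **Lattice spacing.**  Pair-distance histogram, bin width R/20 on
  (0, 4R), 1/r normalization; the first local maximum of the 3-bin
  smoothed curve that exceeds 1.5× the mean level *and* a 3σ Poisson
  excess is refined by quadratic interpolation.  Without a significant
  peak the result is flagged low-confidence (a uniform gas triggers the
  flag).  Because cluster crystals put several particles on one site,
  the intra-site peak near r = 0 is skipped via a search floor
  (`min_r = 0.7 R` in the studies).
* **Sector recovery.**  Points above half the maximum attention define
  the interaction region; radius = 95th percentile of their distances;
  angular width = central bearing interval holding 95% of the attention
  mass, divided by 0.95 so a uniform sector is estimated without
  shrinkage (a full disk reads ≈360°).  Heading alignment uses the
  velocity at the reference step; zero-speed agents are excluded.
* **Attention–force fit.**  Ordinary least squares of α against the
  ground-truth pair-force component magnitude; the attention scale
  factor is fitted, never assumed, since it is specific to a trained
  network's weights.

## Numerical infrastructure

The models run on a small reverse-mode automatic-differentiation core
(`agentnet.nn`) written directly on NumPy arrays: a tape of ops with
broadcasting-aware backward closures, Kaiming-uniform linear layers, an
LSTM cell, Adam, and a plateau schedule.  Gradients of every primitive
and of full models are checked against central finite differences
(relative error < 10⁻⁴).  Training uses float32 (the Mish forward and
derivative are fused into a single pass over the data); gradient checks
use float64.  Hot inner loops (Mish, pairwise forces) use numba kernels
when available, with algebraically identical NumPy fallbacks.

Saturating activations flush their extreme tails to exact zero
(magnitudes below 10⁻³⁰, e.g. the attention weight of a pair the model
has fully ruled out).  These values are far below the resolution of any
float32 sum they enter, but left alone they fill large gradient arrays
with subnormal numbers, which mainstream CPUs process up to an order of
magnitude more slowly; flushing keeps late-training epochs as fast as
early ones.  Consequently a fully saturated attention weight can reach
exactly 0.  Per-epoch test-loss evaluation is capped at 96 held-out
samples (enough signal for the plateau schedule at a fraction of the
cost).

Randomness everywhere flows from a single integer seed through named,
crc32-hashed child sequences (`agentnet.utils.subseed`), so partial
reruns reproduce exactly; identical seeds give bitwise-identical
simulator trajectories.

## What the synthetic data does and does not show

The simulators provide exact ground truth for interaction membership and
strength, which is what makes the attention comparisons quantitative.
They do not emulate measurement noise, camera calibration error, 3-D
motion, or observation-dependent occlusion (synthetic presence masks are
independent of geometry), so passing tests demonstrate that the method
recovers interactions *when the generative assumptions hold*, not that
it is robust to real-world tracking artefacts.  Higher-order (beyond
pairwise) interactions are outside the model class by construction.

## Known limitations

* The variable-separation guarantee holds at the architecture level; it
  does not prevent two variables from learning redundant attention if
  the underlying interactions are identical (as in the flock, where the
  x- and y-sectors coincide).
* Sector recovery assumes a roughly convex, heading-symmetric region;
  strongly asymmetric interaction fields would need a different
  estimator.
* The lattice-spacing estimator needs enough pairs (≳10 per peak bin);
  very small particle counts return low-confidence results.
* Desk-scale training budgets are calibrated for the bundled study
  sizes; substantially larger systems should revert to the full-scale
  schedule (lr 5·10⁻⁴, patience 30) and expect longer runs.
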