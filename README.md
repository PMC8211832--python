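# agentnet

Inferring *who interacts with whom, and how strongly, per state
variable* from observed multi-agent trajectories — with the ground-truth
simulators needed to prove the inference works.

Complex systems — flocks, active colloids, cell collectives — are driven
by microscopic interaction rules that are rarely observable directly.
This package implements a graph-attention network whose attention
weights are trained only to predict each agent's next state, yet
converge to the system's true variable-wise interaction strengths, so a
trained model doubles as a measurement instrument for hidden
interactions.  It is aimed at researchers in statistical physics,
collective behavior and systems biology who have trajectory data and
want interaction structure out.

## The model

Each agent's state `s_i` is encoded once into key, query and value
vectors.  For every output variable `q` an independent MLP (`Att_q`)
produces an attention coefficient for each ordered pair, squashed by a
sigmoid rather than a softmax so it reads as an *absolute* interaction
strength:

    a_ij^q = Att_q(key(e(s_i)), query(e(s_j)), u)
    α_ij^q = 1 / (1 + exp(−a_ij^q))            ∈ (0, 1)

The prediction for variable `q` of agent `i` uses the mean of
`α_ij^q · value_j` over the other agents, decoded by a *separate*
decoder per variable, so `α^q` provably cannot influence any other
variable's output — the property that lets `α_ij^q` be compared
directly with the ground-truth interaction strength `w_ij^q`.
Stochastic systems end in Gaussian mean/variance heads trained by
negative log-likelihood; systems with hidden drivers (e.g. a latent
propulsion force) use an LSTM encoder over an observation window.
MLP/LSTM/GAT/3-head-GAT baselines share the same I/O contract.

Three simulators provide exact ground truth:

| system | state | true interaction |
|---|---|---|
| cellular automaton (14×14) | x, y, alive flag | indicator of the 8-cell Moore neighborhood |
| vision-sector Vicsek flock | x, y, v_x, v_y | indicator of (r < 1 m) ∧ (bearing inside the vision cone) |
| active Ornstein–Uhlenbeck particles | x, y, v_x, v_y (+ global R) | soft-core pair force −∇ exp(−r³/R³) |

Everything runs on a small NumPy reverse-mode autodiff core
(`agentnet.nn`) — no GPU or deep-learning framework required.

## Worked example

The active-particle system self-organizes into a hexagonal cluster
crystal whose lattice constant is ≈ 1.4 interaction lengths.  Simulate
it and measure the spacing from the pair-distance distribution:

```python
from agentnet import protocols

est = protocols.aoup_spacing_study(seed=7, R=3.0)
print(f"lattice spacing: {est.spacing:.2f} length units "
      f"({est.spacing/3.0:.2f} R, confident={est.confident})")
```

which prints (about 10 s):

```
lattice spacing: 4.19 length units (1.40 R, confident=True)
```

`4.19` is the first significant peak of the pair-distance histogram of
the clustered steady state — 1.40 × the soft-core interaction length
R = 3, matching the known cluster-crystal periodicity.  The same study
at R = 5 yields ≈ 7.0.

Training studies work the same way: `protocols.ca_study(seed)` trains
the grid-automaton model on 2,000 transitions (its attention converges
onto exactly the eight Moore neighbors and held-out accuracy reaches
100%), and `protocols.vicsek_study(seed)` trains the flocking model and
recovers the vision sector (radius ≈ 1 m, opening ≈ 120°) from the
heading-aligned attention map.

A CLI covers the same pipeline from the shell:

```
agentnet simulate vicsek --n-samples 500 --seed 1 --out flock.csv
agentnet train --system vicsek --data flock.csv --seed 1 --out model.npz
agentnet analyze sector --ckpt model.npz --data flock.csv --out results/
```

Every command writes a manifest (config, seeds, file digests) for
reproducibility; identical seeds reproduce identical outputs.

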