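# iblopt

An instance-based-learning (IBL) model of the **Sugar Factory** dynamic
decision-making task, written as a closed mathematical recurrence over the
ACT-R declarative-memory equations — plus a continuously differentiable
(smoothed) variant and derivative-free parameter optimization.

The package is for computational cognitive modelers who want to treat a
cognitive model as an ordinary mathematical object: simulate it
reproducibly, sweep its parameter space, fit it to a human reference score,
and ask what its best achievable performance is.

## The model

In the Sugar Factory a controller picks a workforce `x ∈ {1..12}` each
round; production responds as `p' = clip(2x − p + u_r, 1, 12)` with noise
`u_r ~ uniform{−1,0,1}`, and a round scores when `p' ∈ {8, 9, 10}` (goal
p\* = 9, 40 rounds, `p₁ = 6`). The agent stores each experienced transition
`(x, p, p')` as a chunk in a preallocated declarative memory of
`N_c = 12³ = 1728` chunks and, each round, retrieves the most active chunk
for the request `(p_j, 9)`:

    A_i = ln(n_i/(1−d)) − d·ln(j − t_i + T)            base-level learning
        + P · (sim(p_j, c_i2) + sim(9, c_i3)),         partial matching
    sim(a,b) = −|a−b| / max(a,b),

acting on its stored workforce if `max_i A_i ≥ τ`, and otherwise exploring
with a clipped random walk (`±1` steps after on-goal rounds, `±2`
otherwise). Two objectives are posed over `θ = (τ, P)` on a frozen batch of
`n = 100` pseudo-random input replicates (common random numbers):

* **fit**: minimize `sqrt(mean_i (R_i(θ) − 7.9)²)`, the RMSD from the human
  reference score of 7.9 rounds on target;
* **performance**: maximize `a·mean_i R_i + b·sd_i R_i`.

The smoothed variant replaces every branch, max, |·|, clip and the argmax
selection with compositions of `H(x) = arctan(hx)/π + ½` and
`δ(x) = exp(−x²/a²)`, with separately tunable sharpness for similarity
(`h_sim`), selection (`h_argmax`) and environment clipping (`h_env`).
See `docs/methods.md` for the full formulation and design rationale.

## Worked example

```python
from iblopt import (ActivationParams, SimulationConfig, make_batch,
                    run_batch, ObjectiveWeights, run_optimizer)
from iblopt.optimize import make_objective, best_result

batch = make_batch(1, 100)                       # 100 frozen replicate streams
cfg = SimulationConfig(params=ActivationParams(tau=-3.14, P=20.0))
res = run_batch(cfg, batch)
print(f"mean={res.mean:.2f} sd={res.std:.2f} learned_mean={res.learned_mean:.2f}")

obj = make_objective("performance", batch, cfg, ObjectiveWeights(a=1, b=0))
best = best_result(run_optimizer(obj, "nelder-mead", maximize=True), maximize=True)
print(f"best mean score {best.objective_value:.2f} "
      f"at tau={best.theta_hat[0]:.2f}, P={best.theta_hat[1]:.2f}")
```

prints

```
mean=20.41 sd=6.80 learned_mean=16.71
best mean score 20.87 at tau=-5.61, P=35.00
```

i.e. at a moderate retrieval threshold and similarity weight the model is
on target 20.4 of 40 rounds on average (16.7 of them in rounds where a
learned chunk drove the choice — far above the ~7.9 typical of humans), and
multi-start Nelder-Mead over `(τ, P)` finds a best attainable mean of about
20.9 rounds for this replicate batch. Loose retrieval criteria (low τ)
help in this task; the human-like regime sits at much higher τ.

The same experiments are scriptable from the shell:

```sh
iblopt simulate       --config examples/standard.yaml --out results/
iblopt sweep          --config examples/standard.yaml --workers 4
iblopt optimize       --config examples/standard.yaml
iblopt smooth-compare --config examples/standard.yaml
```

`smooth-compare` tabulates the smoothed model's mean score against the
discrete reference per sharpness setting; with the example config it shows
the sharp-selection regime tracking the discrete model (20.37 vs 20.41)
and the score collapsing to the exploration baseline (≈ 9.0) when
`h_argmax` drops to 10³.

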