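# Methods

`iblopt` implements an instance-based-learning (IBL) model of the *Sugar
Factory* dynamic control task, formulated as a closed system of recurrence
relations over the ACT-R declarative-memory equations, together with a
continuously differentiable (smoothed) variant and derivative-free parameter
optimization. This note records the model, the conventions chosen where the
formulation was genuinely open, the numerical choices, and what the test
suite does and does not establish.

## The task and the discrete model

The Sugar Factory is a turn-based control problem: production `p` (integer,
1..12, thousands of tons) responds to the chosen workforce `x` (integer,
1..12) as

    p' = clip(2x − p + u_r, 1, 12),     u_r ~ uniform{−1, 0, 1}.

The goal is production 9; a round is scored if `p' ∈ {8, 9, 10}` (the ±1
band compensates the environment noise). An episode has `N_r = 40` rounds
starting from `p_1 = 6` (configurable; the sensitivity study also uses 1
and 9). The episode score `R` is the number of on-target rounds.

The agent stores each experienced transition `(x, p, p')` as a declarative
chunk and, before each choice, issues a retrieval request for the current
production and the goal. Memory preallocates every possible chunk — one per
triple on the `12³` grid, `N_c = 1728` — with a sentinel activation `−M` so
that only presented chunks are retrievable. A populated chunk's activation
for request `(p_j, 9)` at round `j` is

    A_i = ln(n_i / (1 − d)) − d · ln(j − t_i + T)          (base level)
        + P · (sim(p_j, c_i2) + sim(9, c_i3))              (partial matching)
        + u^n_ij,                                          (logistic noise)

with `sim(a, b) = −|a−b| / max(a, b)`, presentation count `n_i`, creation
round `t_i`, lifetime offset `T = 0.05`, decay `d = 0.5`, similarity weight
`P`, and transient noise of scale `s ≈ 0.2` (disabled — set to zero — in
every study run; its effect on the mean score is negligible, and disabling
it makes each episode a deterministic function of its input streams).

If the maximal activation clears the retrieval threshold `τ`, the agent
reuses that chunk's workforce slot; otherwise it explores: it takes the
current exploration workforce `u_w`, a random walk seeded in {7, 8, 9}
that moves by `u_on ~ uniform{−1..1}` after a goal round and by
`u_off ~ uniform{−2..2}` otherwise, clipped to 1..12. After the factory
responds, the triple `(x_j, p_j, p_{j+1})` is presented: merged into an
existing identical chunk (`n += 1`; the creation round is *not* refreshed,
so the lifetime runs from first creation) or created fresh (`n = 1`,
`t = j`).

### Conventions fixed here

The formal and behavioral descriptions of the exploration update differ,
and the choice is consequential:

* **Exploration anchor** (`exploration_anchor`, default `"last_choice"`):
  the random step is added to the workforce actually employed in the
  previous round, per the behavioral rule set the model encodes ("the step
  is added to the current workforce"). The alternative — a free-running
  walk state that ignores retrieved choices (`"walk"`) — systematically
  lowers attainable performance: on three independent 100-replicate
  batches the anchored form's best mean score is 19.2–20.8 and its best
  mean−sd objective 12.5–14.2 (matching the reference optima and their
  location near τ ≈ −6.5, P ≈ 30), while the free-running form reaches
  only 17.9–19.4 and 11.1–11.7. The anchored form is therefore the
  default study condition.
* **Walk branch test** (`on_target_rule_for_walk`, default `"exact_nine"`):
  the on-goal step size `u_on` applies when the new production equals 9
  exactly, following the formal round loop; the behavioral band variant
  (8–10) is available as `"band_8_10"`. Both conventions' score surfaces
  agree within replicate sampling noise.
* **Presentation semantics**: only the explicit merge step increments `n`.
  Counting a successful retrieval as an additional presentation is exposed
  (`count_retrieval_as_presentation`) but off by default; it changes the
  mean score by less than the batch sampling error.
* **Tie-breaking**: equal maximal activations resolve to the lowest chunk
  index (chunks are enumerated lexicographically over `(c1, c2, c3)`,
  0-based). Exact ties occur (identical content slots and identical
  `(n, t)`), so a deterministic rule is required for reproducibility.
* **Sentinel**: `M = 1000` dominates every reachable activation
  (|base level| ≤ ~2, |context| ≤ 2P ≤ 70, thresholds in [−8.5, 1]);
  it is configurable.

## Input streams

All randomness is generated a priori: per replicate, the sequences `u_on`,
`u_off`, `u_r` (length `N_r`), the initial exploration workforce, and —
when enabled — an `N_r × N_c` matrix of logistic activation noise. Streams
are spawned from a master seed via `numpy` seed sequences; replicate `i` of
a batch is independent of the batch size, and the walk/environment draws
precede the noise draws so they are identical whether or not noise is
enabled. Every simulated quantity is a deterministic function of
`(configuration, streams)`; common random numbers across parameter values
are what make the optimization objectives deterministic functions of
`(τ, P)`.

## Smoothed model

For derivative-based analysis the discrete constructs are replaced by
compositions of

    H(x) = arctan(h·x)/π + 1/2,        δ(x) = exp(−x²/a²),   a = 0.01,

with sharpness assigned per model part: `h_sim` for the similarity terms
(max and |·| in `sim`), `h_env` for production/workforce clipping (the
nested-branch form `H(p̃−12)·12 + (1−H(p̃−12))·(H(1−p̃)·1 + ...)`), and
`h_argmax` for chunk selection and the discrete-semantics tests. Defaults
`h_sim = h_env = 10`, `h_argmax = 1e7` are the regime in which the smoothed
model tracks the discrete one.

The n-ary maximum `A*` is a pairwise smooth-max fold in ascending chunk
order. Each fold step against a dominated value deflates the running
maximum by ≈ `1/(π·h)`, so `A*` sits below the true maximum by up to
`N_c/(π·h_argmax)` — ~5·10⁻⁵ at sharpness 1e7, ~0.5 at 1e3. The chunk
selection is

    w_i  = δ(A_i − A*)                       "chunk i attains the maximum"
    gate = H(A* − τ)                         "the maximum clears the threshold"
    x    = gate · Σ_i w_i · c_i1  +  (1 − gate · Σ_i w_i) · u_w,

i.e. the exploration fallback is weighted by "no chunk was retrievable" —
either the threshold failed or no chunk's activation matches the smoothed
maximum. Two properties follow. In the sharp regime the fold deflation is
far inside δ's width, the winner's weight saturates to 1, and the choice
reproduces the discrete rule exactly (to ~1e-5). At `h_argmax = 1e3` the
deflation exceeds δ's width, the selection mass vanishes, and behavior
reverts to the exploration walk: learning is replaced by random behavior,
which is the mechanism behind the score collapse in the sharpness study.
A normalized Heaviside-weight variant (`selection_weight="heaviside"`) and
an exact (non-folded) maximum (`a_star_mode="exact"`) are available for
comparison; the Heaviside variant keeps learning intact at low sharpness
and therefore does not exhibit the collapse.

The remaining discrete-semantics tests are smoothed as follows, each with a
documented rationale:

* **Presentation matching** ("does chunk `(x, p, p')` exist?"): per-slot
  windows `H(1/2 − |z|)` at `h_argmax` sharpness against each grid value
  (default `"window"`). A Gaussian-δ variant is available but brittle: the
  `h_env = 10` clipping displaces trajectories from the integer grid by up
  to ~3·10⁻² at the bounds, which exceeds `a = 0.01` and silently destroys
  memory writes even in the sharp regime.
* **Walk branch test** (`p' = 9?`): the Gaussian δ of width `a` (default),
  with the window form as an option.
* **Score indicator** (`p' ∈ {8..10}`): the band `H(3/2 − |p−9|)` at
  `h_argmax` sharpness. Using `h_env = 10` here biases every on-target
  round's contribution to ~0.94 and the episode score by ≈ −0.5 rounds,
  which would contaminate the smoothed-vs-discrete equivalence; the test
  belongs to the scoring semantics, not to the environment dynamics.

Productions, workforces, presentation masses and scores are real-valued
throughout; nothing is rounded inside the smoothed model. Chunks whose
presentation mass is below 1e-6 are held at the sentinel (a numerical
cutoff; leakage onto neighboring triples in the sharp regime is ~1e-7 per
round). The creation round of a not-yet-created chunk is refreshed each
round through a smooth freeze `t := H(n − 1/2)·t + (1 − H(n − 1/2))·j`, so
it equals the true creation round once the chunk's mass reaches 1.

### Equivalence and its limits

With *every* part sharpened (`h_sim = h_env = 1e5`, `h_argmax = 1e7`) the
smoothed episode reproduces the discrete trajectories; the mean absolute
score difference over 100 replicates is ≈ 0.1 rounds. At the reference
constants (`h_sim = h_env = 10`) individual episodes can diverge — the
similarity smoothing error at `h = 10` is ~0.01·P ≈ 0.2 activation units,
enough to flip near-tie retrievals, after which chaotic trajectory
divergence decorrelates the episode — but the 100-replicate mean scores
agree to well under half a round, which is the comparison the sharpness
study rests on.

In the soft-selection regime this implementation reverts to the *clean*
exploration walk (mean ≈ 9 rounds on target on these streams). The
reference implementation reports ≈ 5.2 there, below any pure-walk baseline
we can construct, suggesting its random-choice realization degraded
further under smoothing in ways its description does not pin down; the
collapse itself (a drop of > 10 rounds from the sharp regime) is robustly
reproduced.

## Objectives and optimization

Two objectives over `θ = (τ, P)` (decay fixed at 0.5), both evaluated on a
frozen batch of `n = 100` replicate streams:

* fit: `RMSD(θ) = sqrt(mean_i (R_i(θ) − R_ref)²)` against the human
  reference score `R_ref = 7.9`, minimized;
* performance: `a·mean_i R_i + b·sd_i R_i` (sample sd, n−1), maximized;
  studied at `(a, b) = (1, 0)` and `(1, −1)`.

The objectives are piecewise constant in `θ` (scores are integers), so the
drivers are derivative-free: Nelder-Mead (simplex) and COBYQA (quadratic
trust region) as local solvers with a parameter tolerance of 0.1 and
four corner-biased start points inside the box `τ ∈ [−8.5, 1]`,
`P ∈ [0.5, 35]`; differential evolution and dual annealing as heuristic
global solvers under an evaluation-count budget (hardware-independent,
unlike wall-clock limits). Nelder-Mead uses an initial simplex spanning
~10% of each range so the first steps cross objective plateaus. The
`(τ, P)` grid sweep evaluates the same statistics on an inclusive lattice
(the reference fine grid, step 0.05 × 0.1, has 66,086 points) and
parallelizes across grid points with results invariant to the worker
count.

## Problem sizes and expected values

Simulation studies in the tests and the acceptance script use 100
replicates of 40 rounds, the sizes at which the reference results are
stated; optimization checks average the best objective over three
independent master-seed batches to damp replicate-sampling noise
(single-batch optima vary by ≈ ±1 round). Under these conditions the
package reproduces: best-fit RMSD ≈ 4.0 (reference 4.05), best mean score
≈ 20–21 near `(τ, P) ≈ (−4, 27)` (reference 20.15), best mean−sd ≈ 13–15
(reference 13.87), and the sharpness study's 19.5-level sharp-regime mean
with a collapse of > 10 rounds at soft selection.

## What the synthetic streams do and do not emulate

The pseudo-random streams realize exactly the stochastic elements the task
definition specifies (environment noise, exploration steps, initial
workforce, activation noise); there is no human data in the package.
Reproduced quantities are therefore model-level statistics — means and
standard deviations over replicate input sequences — not fits to
individual behavior. Single-input score maps depend strongly on the
particular realization (unpublished in the reference) and are covered
qualitatively only: learning concentrated in the low-τ/moderate-P wedge,
recall suppressed in the high-τ/high-P corner, sensitivity of the score to
the initial production.

## Known limitations

* The smoothed model is continuously differentiable in a neighborhood of
  a trajectory, but at matching sharpness it is numerically piecewise
  constant; no derivative information is exposed (automatic
  differentiation is out of scope, as is the exact bi-level argmax
  reformulation).
* The low-sharpness regime's absolute score depends on unspecified details
  of the reference implementation (see above); only the collapse is
  reproduced quantitatively.
* Activation noise is supported but untested against reference values
  (the reference studies run with noise off).
* `n = 1` batches report a sample standard deviation of 0 with a warning.
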