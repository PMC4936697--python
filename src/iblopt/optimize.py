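"""Objectives, (tau, P) grid sweeps, and derivative-free optimizer drivers.

Two optimization problems are posed over the retrieval threshold ``tau`` and
the partial-matching weight ``P`` (decay ``d`` stays fixed):

* *fit*: minimize the root-mean-square deviation of per-replicate episode
  scores from a human reference score,
  ``RMSD(theta) = sqrt(mean_i (R_i(theta) - R_ref)^2)``;
* *performance*: maximize ``a * mean_i R_i + b * sd_i R_i`` with sample
  standard deviation (n-1 denominator).

Both are evaluated under common random numbers: a batch of replicate input
streams is frozen once, so each objective is a deterministic (piecewise
constant) function of ``theta`` and repeated evaluation at the same point is
bit-identical — a prerequisite for sane derivative-free optimization.

Drivers delegate to scipy.optimize: Nelder-Mead (simplex-type) and COBYQA
(quadratic-model trust region) as local derivative-free solvers, plus
differential evolution (evolutionary) and dual annealing (stochastic global
search) as heuristic global solvers with an evaluation-count budget.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize as sciopt

from .agent import SimulationConfig, run_batch
from .memory import ActivationParams
from .streams import InputStreams

__all__ = [
    "ObjectiveWeights",
    "SweepGrid",
    "OptResult",
    "fit_objective",
    "performance_objective",
    "make_objective",
    "lattice",
    "grid_sweep",
    "default_bounds",
    "default_starts",
    "run_optimizer",
    "best_result",
    "LOCAL_METHODS",
    "GLOBAL_METHODS",
]

#: Default search box: the sweep ranges for (tau, P).
DEFAULT_BOUNDS = ((-8.5, 1.0), (0.5, 35.0))

LOCAL_METHODS = ("nelder-mead", "cobyqa")
GLOBAL_METHODS = ("differential-evolution", "dual-annealing")


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights of the performance objective and the human reference score."""

    a: float = 1.0
    b: float = 0.0
    R_ref: float = 7.9


def _config_with_theta(config: SimulationConfig, theta) -> SimulationConfig:
    tau, P = (float(v) for v in theta)
    return replace(config, params=replace(config.params, tau=tau, P=P))


def fit_objective(
    theta,
    batch: list[InputStreams],
    config: SimulationConfig,
    weights: ObjectiveWeights,
) -> float:
    """RMSD between per-replicate scores at ``theta`` and ``R_ref``."""
    res = run_batch(_config_with_theta(config, theta), batch)
    dev = res.scores - weights.R_ref
    return float(math.sqrt(np.mean(dev * dev)))


def performance_objective(
    theta,
    batch: list[InputStreams],
    config: SimulationConfig,
    weights: ObjectiveWeights,
) -> float:
    """Weighted score summary ``a*mean + b*sd`` (sample sd, n-1)."""
    if weights.b != 0.0 and len(batch) < 2:
        raise ValueError("the sd term requires at least two replicates")
    res = run_batch(_config_with_theta(config, theta), batch)
    return weights.a * res.mean + weights.b * res.std


def make_objective(
    kind: str,
    batch: list[InputStreams],
    config: SimulationConfig,
    weights: ObjectiveWeights,
) -> Callable[[Sequence[float]], float]:
    """Freeze a batch into a deterministic callable over theta = (tau, P)."""
    if kind == "fit":
        return lambda theta: fit_objective(theta, batch, config, weights)
    if kind == "performance":
        return lambda theta: performance_objective(theta, batch, config, weights)
    raise ValueError(f"unknown objective kind {kind!r}")


# ---------------------------------------------------------------------------
# Grid sweep
# ---------------------------------------------------------------------------

def lattice(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive lattice ``lo, lo+step, ..., hi`` robust to float step error.

    The point count follows the closed form floor((hi-lo)/step) + 1, with the
    ratio snapped to the nearest integer when it is within 1e-6 of one.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if hi < lo:
        raise ValueError("empty range")
    ratio = (hi - lo) / step
    n = int(round(ratio)) if abs(ratio - round(ratio)) < 1e-6 else int(ratio)
    return lo + step * np.arange(n + 1)


@dataclass
class SweepGrid:
    """Mean / sd / learned-only score surfaces over a (tau, P) lattice."""

    tau_axis: np.ndarray
    P_axis: np.ndarray
    mean_score: np.ndarray
    std_score: np.ndarray
    learned_mean: np.ndarray
    n: int
    master_seed: Optional[int] = None

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.tau_axis), len(self.P_axis)

    def to_frame(self):
        """Long-format table: one row per (tau, P) lattice point."""
        import pandas as pd

        tt, pp = np.meshgrid(self.tau_axis, self.P_axis, indexing="ij")
        return pd.DataFrame(
            {
                "tau": tt.ravel(),
                "P": pp.ravel(),
                "mean": self.mean_score.ravel(),
                "std": self.std_score.ravel(),
                "learned_mean": self.learned_mean.ravel(),
            }
        )

    def meta_json(self, extra: Optional[dict] = None) -> str:
        meta = {
            "n_replicates": self.n,
            "master_seed": self.master_seed,
            "tau_axis": [float(v) for v in self.tau_axis],
            "P_axis": [float(v) for v in self.P_axis],
        }
        if extra:
            meta.update(extra)
        return json.dumps(meta, indent=2)


def _sweep_point(theta, batch, config):
    res = run_batch(_config_with_theta(config, theta), batch)
    return res.mean, res.std, res.learned_mean


def grid_sweep(
    tau_range: tuple[float, float],
    tau_step: float,
    P_range: tuple[float, float],
    P_step: float,
    batch: list[InputStreams],
    config: SimulationConfig,
    n_jobs: int = 1,
    master_seed: Optional[int] = None,
) -> SweepGrid:
    """Evaluate score statistics on the inclusive (tau, P) lattice.

    Grid points are independent, so the sweep parallelizes across workers
    with results invariant to ``n_jobs``.
    """
    tau_axis = lattice(*tau_range, tau_step)
    P_axis = lattice(*P_range, P_step)
    points = [(t, p) for t in tau_axis for p in P_axis]
    if n_jobs == 1:
        rows = [_sweep_point(th, batch, config) for th in points]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(_sweep_point)(th, batch, config) for th in points
        )
    arr = np.asarray(rows, dtype=float).reshape(len(tau_axis), len(P_axis), 3)
    return SweepGrid(
        tau_axis=tau_axis,
        P_axis=P_axis,
        mean_score=arr[:, :, 0],
        std_score=arr[:, :, 1],
        learned_mean=arr[:, :, 2],
        n=len(batch),
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Optimizer drivers
# ---------------------------------------------------------------------------

@dataclass
class OptResult:
    theta_hat: tuple[float, float]
    objective_value: float
    n_evaluations: int
    trajectory: list[tuple[float, float, float]]  # (tau, P, value) iterates
    method: str
    start_point: Optional[tuple[float, float]]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_bounds() -> tuple[tuple[float, float], tuple[float, float]]:
    return DEFAULT_BOUNDS


def default_starts(
    bounds=DEFAULT_BOUNDS, inset: float = 0.15
) -> list[tuple[float, float]]:
    """Four corner-biased start points, pulled ``inset`` into the box."""
    (t_lo, t_hi), (p_lo, p_hi) = bounds
    dt, dp = t_hi - t_lo, p_hi - p_lo
    return [
        (t_lo + inset * dt, p_lo + inset * dp),
        (t_lo + inset * dt, p_hi - inset * dp),
        (t_hi - inset * dt, p_lo + inset * dp),
        (t_hi - inset * dt, p_hi - inset * dp),
    ]


class _Recorder:
    """Wraps an objective to count evaluations and log iterates."""

    def __init__(self, objective, sign: float):
        self.objective = objective
        self.sign = sign
        self.n_eval = 0
        self.trajectory: list[tuple[float, float, float]] = []

    def __call__(self, theta):
        value = self.objective(theta)
        self.n_eval += 1
        self.trajectory.append((float(theta[0]), float(theta[1]), float(value)))
        return self.sign * value


def run_optimizer(
    objective: Callable[[Sequence[float]], float],
    method: str,
    bounds=DEFAULT_BOUNDS,
    starts: Optional[list[tuple[float, float]]] = None,
    maximize: bool = False,
    options: Optional[dict] = None,
    seed: int = 0,
) -> list[OptResult]:
    """Run a solver from each start point and record its iterates.

    Local methods ("nelder-mead", "cobyqa") use a relative parameter
    tolerance of 0.1 as their stopping rule and run once per start point;
    global methods ("differential-evolution", "dual-annealing") search the
    whole box under an evaluation-count budget (``options["maxfev"]``,
    default 2000) and ignore ``starts`` beyond the first entry.  ``seed``
    fixes the heuristic solvers' randomness.
    """
    options = dict(options or {})
    sign = -1.0 if maximize else 1.0
    bounds_t = tuple(tuple(map(float, b)) for b in bounds)
    sci_bounds = sciopt.Bounds(
        [b[0] for b in bounds_t], [b[1] for b in bounds_t]
    )
    if starts is None:
        starts = default_starts(bounds_t)
    for st in starts:
        for v, (lo, hi) in zip(st, bounds_t):
            if not lo <= v <= hi:
                raise ValueError(f"start point {st} outside bounds {bounds_t}")

    results: list[OptResult] = []

    if method in LOCAL_METHODS:
        xatol = options.pop("xatol", 0.1)
        maxfev = options.pop("maxfev", 500)
        for start in starts:
            rec = _Recorder(objective, sign)
            x0 = np.asarray(start, dtype=float)
            if method == "nelder-mead":
                # A generous initial simplex (~10% of each range) steps over
                # the plateaus of the piecewise-constant objective.
                spans = np.array([b[1] - b[0] for b in bounds_t])
                simplex = np.array([x0, x0, x0])
                simplex[1, 0] = min(x0[0] + 0.1 * spans[0], bounds_t[0][1])
                simplex[2, 1] = min(x0[1] + 0.1 * spans[1], bounds_t[1][1])
                res = sciopt.minimize(
                    rec,
                    x0,
                    method="Nelder-Mead",
                    bounds=sci_bounds,
                    options={
                        "xatol": xatol,
                        "fatol": 1e-8,
                        "maxfev": maxfev,
                        "initial_simplex": simplex,
                    },
                )
            else:  # cobyqa
                res = sciopt.minimize(
                    rec,
                    x0,
                    method="COBYQA",
                    bounds=sci_bounds,
                    options={"final_tr_radius": xatol, "maxfev": maxfev},
                )
            results.append(
                OptResult(
                    theta_hat=(float(res.x[0]), float(res.x[1])),
                    objective_value=sign * float(res.fun),
                    n_evaluations=rec.n_eval,
                    trajectory=rec.trajectory,
                    method=method,
                    start_point=tuple(start),
                )
            )
        return results

    if method in GLOBAL_METHODS:
        maxfev = options.pop("maxfev", 2000)
        rec = _Recorder(objective, sign)
        if method == "differential-evolution":
            popsize = options.pop("popsize", 15)
            maxiter = max(1, maxfev // (popsize * 2) - 1)
            res = sciopt.differential_evolution(
                rec,
                bounds_t,
                seed=seed,
                popsize=popsize,
                maxiter=maxiter,
                init="sobol",
                polish=False,
                tol=0.0,
            )
        else:  # dual-annealing
            res = sciopt.dual_annealing(
                rec,
                bounds_t,
                seed=seed,
                maxfun=maxfev,
                x0=np.asarray(starts[0], dtype=float),
                no_local_search=True,
            )
        return [
            OptResult(
                theta_hat=(float(res.x[0]), float(res.x[1])),
                objective_value=sign * float(res.fun),
                n_evaluations=rec.n_eval,
                trajectory=rec.trajectory,
                method=method,
                start_point=tuple(starts[0]),
            )
        ]

    raise ValueError(
        f"unknown method {method!r}; choose from {LOCAL_METHODS + GLOBAL_METHODS}"
    )


def best_result(results: list[OptResult], maximize: bool = False) -> OptResult:
    """The best OptResult of a multi-start run."""
    key = (lambda r: -r.objective_value) if maximize else (
        lambda r: r.objective_value
    )
    return min(results, key=key)
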