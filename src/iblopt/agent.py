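"""The instance-based learner's round loop for the Sugar Factory.

Each round the agent (1) computes the activation of every chunk for the
request (current production, goal 9); (2) takes the highest-activation chunk;
(3) acts on that chunk's stored workforce if its activation clears the
retrieval threshold, otherwise on the current exploration workforce; (4) lets
the factory update production; forms the next exploration workforce by adding
the on-goal or off-goal random step (depending on whether the new production
hit the goal) to the workforce just employed, clipping it into {1..12};
(5) scores the round if the new
production lies in {8, 9, 10}; and (6) presents the experienced triple
(workforce, production before, production after) to memory, merging it with
an identical instance if one exists.

Given a configuration and frozen input streams, an episode is fully
deterministic; all randomness lives in the streams.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import env
from .memory import (
    N_CHUNKS,
    SLOT_C1,
    ActivationParams,
    DeclarativeMemory,
    activation_vector,
)
from .streams import InputStreams

__all__ = [
    "SimulationConfig",
    "RoundRecord",
    "RunResult",
    "BatchResult",
    "run_episode",
    "run_batch",
]

WALK_RULES = ("exact_nine", "band_8_10")
EXPLORATION_ANCHORS = ("last_choice", "walk")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated Sugar Factory session.

    Defaults reproduce the standard study conditions: 40 rounds, initial
    production 6, decay 0.5, activation noise disabled, and the round-loop
    convention that the exploration walk switches between its on-goal and
    off-goal step sizes on the exact-9 test (the behavioral description of
    human play uses the 8-10 band instead; both are available via
    ``on_target_rule_for_walk``).

    ``exploration_anchor`` selects what the random exploration step is added
    to.  The default ``"last_choice"`` follows the behavioral rule set the
    model is built on — the step perturbs the workforce actually employed in
    the previous round, whether it came from memory or from exploration.
    ``"walk"`` instead evolves an exploration state of its own that ignores
    retrieved choices.  The anchored form is the one that reproduces the
    reference optimization results; see the methods note.
    """

    params: ActivationParams
    n_rounds: int = 40
    p1: int = 6
    noise_enabled: bool = False
    count_retrieval_as_presentation: bool = False
    on_target_rule_for_walk: str = "exact_nine"
    exploration_anchor: str = "last_choice"

    def __post_init__(self) -> None:
        if self.n_rounds < 1:
            raise ValueError("need at least one round")
        if not env.P_MIN <= self.p1 <= env.P_MAX:
            raise ValueError(f"initial production {self.p1} outside {{1..12}}")
        if self.on_target_rule_for_walk not in WALK_RULES:
            raise ValueError(
                f"walk rule must be one of {WALK_RULES}, "
                f"got {self.on_target_rule_for_walk!r}"
            )
        if self.exploration_anchor not in EXPLORATION_ANCHORS:
            raise ValueError(
                f"exploration anchor must be one of {EXPLORATION_ANCHORS}, "
                f"got {self.exploration_anchor!r}"
            )


@dataclass(frozen=True)
class RoundRecord:
    j: int
    x: int
    p_before: int
    p_after: int
    retrieved: bool
    retrieved_index: Optional[int]
    on_target: int


@dataclass
class RunResult:
    rounds: list[RoundRecord]
    score: int
    learned_score: int
    final_memory: DeclarativeMemory

    def to_json(self) -> str:
        return json.dumps(
            {
                "score": self.score,
                "learned_score": self.learned_score,
                "rounds": [
                    {
                        "j": r.j,
                        "x": r.x,
                        "p_before": r.p_before,
                        "p_after": r.p_after,
                        "retrieved": r.retrieved,
                        "retrieved_index": r.retrieved_index,
                        "on_target": r.on_target,
                    }
                    for r in self.rounds
                ],
            }
        )


def _walk_on_goal(p_new: int, rule: str) -> bool:
    if rule == "exact_nine":
        return p_new == env.TARGET
    return abs(p_new - env.TARGET) <= 1


def run_episode(config: SimulationConfig, streams: InputStreams) -> RunResult:
    """Simulate one episode on frozen input streams."""
    if streams.n_rounds < config.n_rounds:
        raise ValueError(
            f"streams cover {streams.n_rounds} rounds, "
            f"config asks for {config.n_rounds}"
        )
    if config.noise_enabled and streams.u_n is None:
        raise ValueError("noise enabled but streams carry no u_n")

    params = config.params
    memory = DeclarativeMemory()
    buf = np.empty(N_CHUNKS, dtype=float)  # reused activation buffer

    p = config.p1
    u_w = int(streams.w_init)
    rounds: list[RoundRecord] = []
    score = 0
    learned = 0

    for j in range(1, config.n_rounds + 1):
        noise = streams.noise_row(j) if config.noise_enabled else None
        A = activation_vector(
            memory, (p, env.TARGET), params, j, noise=noise, out=buf
        )
        i_star = int(np.argmax(A))  # ties -> lowest chunk index
        retrieved = bool(A[i_star] >= params.tau)
        if retrieved:
            x = int(SLOT_C1[i_star])
            if config.count_retrieval_as_presentation:
                memory.reinforce(i_star)
        else:
            x = u_w

        p_new = env.production_step(p, x, int(streams.u_r[j - 1]))
        anchor = x if config.exploration_anchor == "last_choice" else u_w
        if _walk_on_goal(p_new, config.on_target_rule_for_walk):
            u_w = anchor + int(streams.u_on[j - 1])
        else:
            u_w = anchor + int(streams.u_off[j - 1])
        u_w = min(env.P_MAX, max(env.P_MIN, u_w))

        r = env.on_target(p_new)
        memory.present((x, p, p_new), j)

        rounds.append(
            RoundRecord(
                j=j,
                x=x,
                p_before=p,
                p_after=p_new,
                retrieved=retrieved,
                retrieved_index=i_star if retrieved else None,
                on_target=r,
            )
        )
        score += r
        if retrieved:
            learned += r
        p = p_new

    return RunResult(rounds, score, learned, memory)


@dataclass
class BatchResult:
    """Per-replicate scores with their summary statistics."""

    scores: np.ndarray
    learned_scores: np.ndarray
    mean: float
    std: float  # sample standard deviation (n-1 denominator)
    learned_mean: float
    results: Optional[list[RunResult]] = None


def run_batch(
    config: SimulationConfig,
    streams_list: list[InputStreams],
    keep_results: bool = False,
) -> BatchResult:
    """Run one episode per replicate stream and summarize the scores."""
    if not streams_list:
        raise ValueError("empty replicate batch")
    scores = np.empty(len(streams_list), dtype=np.int64)
    learned = np.empty(len(streams_list), dtype=np.int64)
    results = [] if keep_results else None
    for i, st in enumerate(streams_list):
        res = run_episode(config, st)
        scores[i] = res.score
        learned[i] = res.learned_score
        if keep_results:
            results.append(res)
    if len(scores) > 1:
        std = float(np.std(scores, ddof=1))
    else:
        warnings.warn(
            "sample standard deviation is undefined for a single replicate; "
            "reporting 0",
            stacklevel=2,
        )
        std = 0.0
    return BatchResult(
        scores=scores,
        learned_scores=learned,
        mean=float(scores.mean()),
        std=std,
        learned_mean=float(learned.mean()),
        results=results,
    )
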