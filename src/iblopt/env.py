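"""Sugar Factory environment: production dynamics, target band, score.

The factory produces ``p`` thousand metric tons of sugar, an integer in
{1..12}.  Choosing a workforce ``x`` in {1..12} updates production as

    p' = clip(2*x - p + u_r, 1, 12)

with environment noise ``u_r`` uniform on {-1, 0, 1}.  A round counts as "on
target" when the new production lies within one unit of the goal p* = 9,
i.e. p' in {8, 9, 10}; the episode score is the number of on-target rounds.
"""

from __future__ import annotations

from typing import Iterable

__all__ = [
    "P_MIN",
    "P_MAX",
    "TARGET",
    "production_step",
    "on_target",
    "episode_score",
]

P_MIN = 1
P_MAX = 12
TARGET = 9


def production_step(p: int, x: int, u_r: int) -> int:
    """One factory update: ``clip(2x - p + u_r, 1, 12)``."""
    if not P_MIN <= p <= P_MAX:
        raise ValueError(f"production {p} outside {{1..12}}")
    if not P_MIN <= x <= P_MAX:
        raise ValueError(f"workforce {x} outside {{1..12}}")
    if u_r not in (-1, 0, 1):
        raise ValueError(f"environment noise {u_r} outside {{-1,0,1}}")
    return min(P_MAX, max(P_MIN, 2 * x - p + u_r))


def on_target(p: int) -> int:
    """1 iff production is within one unit of the goal (p in {8,9,10})."""
    if not P_MIN <= p <= P_MAX:
        raise ValueError(f"production {p} outside {{1..12}}")
    return int(abs(p - TARGET) <= 1)


def episode_score(indicators: Iterable[int]) -> int:
    """Rounds on target: the sum of per-round 0/1 indicators."""
    total = 0
    for r in indicators:
        if r not in (0, 1):
            raise ValueError(f"indicator {r} is not 0/1")
        total += r
    return total
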