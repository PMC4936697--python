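"""Reproducible pseudo-random input streams for Sugar Factory episodes.

An episode consumes four exogenous random sequences, generated a priori so
that a simulated trajectory is a deterministic function of its inputs:

* ``u_on``  — exploration step applied to the workforce after an on-goal
  round, uniform on {-1, 0, 1};
* ``u_off`` — exploration step after an off-goal round, uniform on {-2..2};
* ``u_r``   — environment noise entering the production update, uniform on
  {-1, 0, 1};
* ``u_n``   — transient activation noise, one logistic(0, s) draw per round
  and chunk (``None`` when noise is disabled, the study default);
* ``w_init`` — initial exploration workforce, uniform on {7, 8, 9}.

Replicate streams are spawned from a master seed via ``SeedSequence`` so that
replicate ``i`` of a batch does not depend on the batch size.  Within one
stream the draw order is fixed (u_on, u_off, u_r, w_init, then u_n), so the
walk/environment sequences are identical whether or not noise is enabled.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .memory import N_CHUNKS

__all__ = ["InputStreams", "make_streams", "make_batch"]

W_INIT_SUPPORT = (7, 8, 9)


@dataclass
class InputStreams:
    """One replicate's frozen pseudo-random inputs."""

    u_on: np.ndarray
    u_off: np.ndarray
    u_r: np.ndarray
    u_n: Optional[np.ndarray]  # (N_r, N_c) or None when noise is disabled
    w_init: int
    seed: int

    @property
    def n_rounds(self) -> int:
        return len(self.u_r)

    def noise_row(self, j: int) -> Optional[np.ndarray]:
        """Per-chunk activation noise for round ``j`` (1-based), or None."""
        return None if self.u_n is None else self.u_n[j - 1]

    def validate(self) -> None:
        n_r = self.n_rounds
        if not (len(self.u_on) == len(self.u_off) == n_r):
            raise ValueError("stream lengths disagree")
        if self.u_n is not None and self.u_n.shape != (n_r, N_CHUNKS):
            raise ValueError(
                f"u_n must have shape ({n_r}, {N_CHUNKS}), got {self.u_n.shape}"
            )
        for name, arr, lo, hi in (
            ("u_on", self.u_on, -1, 1),
            ("u_off", self.u_off, -2, 2),
            ("u_r", self.u_r, -1, 1),
        ):
            if arr.min() < lo or arr.max() > hi:
                raise ValueError(f"{name} leaves its support [{lo}, {hi}]")
        if self.w_init not in W_INIT_SUPPORT:
            raise ValueError(f"w_init {self.w_init} outside {W_INIT_SUPPORT}")

    # -- JSON fixtures (noise omitted when disabled) -----------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "w_init": self.w_init,
                "u_on": self.u_on.tolist(),
                "u_off": self.u_off.tolist(),
                "u_r": self.u_r.tolist(),
                "u_n": None if self.u_n is None else self.u_n.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "InputStreams":
        d = json.loads(text)
        return cls(
            u_on=np.asarray(d["u_on"], dtype=np.int64),
            u_off=np.asarray(d["u_off"], dtype=np.int64),
            u_r=np.asarray(d["u_r"], dtype=np.int64),
            u_n=None if d["u_n"] is None else np.asarray(d["u_n"], dtype=float),
            w_init=int(d["w_init"]),
            seed=int(d["seed"]),
        )


def _streams_from_seedseq(
    ss: np.random.SeedSequence,
    n_rounds: int,
    n_chunks: int,
    s: float,
    noise_enabled: bool,
) -> InputStreams:
    rng = np.random.default_rng(ss)
    u_on = rng.integers(-1, 2, size=n_rounds)
    u_off = rng.integers(-2, 3, size=n_rounds)
    u_r = rng.integers(-1, 2, size=n_rounds)
    w_init = int(rng.integers(7, 10))
    u_n = None
    if noise_enabled:
        u_n = rng.logistic(loc=0.0, scale=s, size=(n_rounds, n_chunks))
    seed = int(ss.entropy) if isinstance(ss.entropy, int) else -1
    return InputStreams(u_on, u_off, u_r, u_n, w_init, seed)


def make_streams(
    seed: int,
    n_rounds: int = 40,
    n_chunks: int = N_CHUNKS,
    s: float = 0.2,
    noise_enabled: bool = False,
) -> InputStreams:
    """Deterministic streams for one replicate from a single seed."""
    if seed < 0:
        raise ValueError("seed must be non-negative")
    return _streams_from_seedseq(
        np.random.SeedSequence(seed), n_rounds, n_chunks, s, noise_enabled
    )


def make_batch(
    master_seed: int,
    n: int,
    n_rounds: int = 40,
    n_chunks: int = N_CHUNKS,
    s: float = 0.2,
    noise_enabled: bool = False,
) -> list[InputStreams]:
    """``n`` replicate streams with deterministically derived sub-seeds.

    Sub-streams are spawned from ``SeedSequence(master_seed)``, so replicate
    ``i`` is identical for any batch size ``n > i``.
    """
    if n < 1:
        raise ValueError("need at least one replicate")
    children = np.random.SeedSequence(master_seed).spawn(n)
    out = []
    for i, child in enumerate(children):
        st = _streams_from_seedseq(child, n_rounds, n_chunks, s, noise_enabled)
        st.seed = master_seed  # replicate i of this master seed
        out.append(st)
    return out
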