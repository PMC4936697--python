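"""ACT-R declarative memory for the Sugar Factory instance-based learner.

The declarative store preallocates every chunk ``(c1, c2, c3)`` with slot
values on the integer grid ``{1..12}^3`` (workforce chosen, production before,
production after), ``N_c = 12^3 = 1728`` chunks in total.  A chunk that has
never been presented reports the sentinel activation ``-M``; a presented chunk
carries a presentation count ``n`` and a creation round ``t`` from which its
base-level activation is computed.

Activation of chunk *i* for a retrieval request ``(p_j, p*)`` is

    A_i = B_i + C_i + noise,
    B_i = ln(n_i / (1 - d)) - d * ln(L_i),          L_i = j - t_i + T,
    C_i = P * (sim(p_j, c_i2) + sim(p*, c_i3)),     sim(a, b) = -|a-b|/max(a,b),

with decay ``d``, partial-matching weight ``P``, and lifetime offset ``T``.
Retrieval returns the highest-activation chunk if that activation clears the
threshold ``tau``, otherwise nothing (the agent then falls back to random
exploration).  Transient activation noise is logistic with location 0 and
scale ``s``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np

__all__ = [
    "N_SLOT_VALUES",
    "N_CHUNKS",
    "ActivationParams",
    "Chunk",
    "DeclarativeMemory",
    "Retrieval",
    "lifetime",
    "base_level",
    "similarity",
    "context_component",
    "chunk_activation",
    "activation_vector",
    "retrieve",
    "logistic_noise",
]

N_SLOT_VALUES = 12
#: Total preallocated chunk count, one per slot triple.
N_CHUNKS = N_SLOT_VALUES**3  # 1728

# Fixed 0-based lexicographic enumeration of (c1, c2, c3) triples.  Chunk
# index i <-> ((c1-1)*144 + (c2-1)*12 + (c3-1)).
_GRID = np.arange(N_CHUNKS)
SLOT_C1 = _GRID // (N_SLOT_VALUES**2) + 1
SLOT_C2 = (_GRID // N_SLOT_VALUES) % N_SLOT_VALUES + 1
SLOT_C3 = _GRID % N_SLOT_VALUES + 1

TARGET_PRODUCTION = 9


@dataclass(frozen=True)
class ActivationParams:
    """Subsymbolic parameters of the declarative memory.

    tau : retrieval threshold (activation units).
    d   : base-level decay rate, in (0, 1).
    P   : partial-matching (similarity) weight.
    s   : logistic transient-noise scale; 0 disables noise.
    T   : lifetime offset added to the round difference, in rounds.
    M   : magnitude of the sentinel activation assigned to never-presented
          chunks; must dominate the reachable activation range and any
          threshold under study.
    """

    tau: float
    P: float
    d: float = 0.5
    s: float = 0.2
    T: float = 0.05
    M: float = 1000.0

    def __post_init__(self) -> None:
        if not 0.0 < self.d < 1.0:
            raise ValueError(f"decay d must lie in (0, 1), got {self.d}")
        if self.s < 0.0:
            raise ValueError(f"noise scale s must be >= 0, got {self.s}")
        if self.T <= 0.0:
            raise ValueError(f"lifetime offset T must be > 0, got {self.T}")
        if self.M <= abs(self.tau):
            raise ValueError("sentinel magnitude M must dominate |tau|")


@dataclass
class Chunk:
    """A single declarative instance: (workforce, production before, after)."""

    c1: int
    c2: int
    c3: int
    n: int = 0
    t: int = 0
    populated: bool = False


class Retrieval(NamedTuple):
    index: int
    activation: float


def _check_slot(value: float, name: str = "slot") -> None:
    if not 1 <= value <= N_SLOT_VALUES:
        raise ValueError(f"{name} value {value} outside {{1..{N_SLOT_VALUES}}}")


class DeclarativeMemory:
    """Preallocated chunk store over the full ``{1..12}^3`` triple grid.

    Storage is columnar: presentation counts ``n``, creation rounds ``t`` and
    the ``populated`` mask are flat arrays of length 1728 indexed by the fixed
    lexicographic triple enumeration (0-based).
    """

    def __init__(self) -> None:
        self.n = np.zeros(N_CHUNKS, dtype=np.int64)
        self.t = np.zeros(N_CHUNKS, dtype=np.int64)
        self.populated = np.zeros(N_CHUNKS, dtype=bool)

    def __len__(self) -> int:
        return N_CHUNKS

    @staticmethod
    def index_of(c1: int, c2: int, c3: int) -> int:
        """Index of the chunk holding triple ``(c1, c2, c3)`` (a bijection)."""
        for v in (c1, c2, c3):
            _check_slot(v)
        return (c1 - 1) * N_SLOT_VALUES**2 + (c2 - 1) * N_SLOT_VALUES + (c3 - 1)

    @staticmethod
    def triple_of(index: int) -> tuple[int, int, int]:
        if not 0 <= index < N_CHUNKS:
            raise IndexError(index)
        return int(SLOT_C1[index]), int(SLOT_C2[index]), int(SLOT_C3[index])

    def chunk(self, index: int) -> Chunk:
        c1, c2, c3 = self.triple_of(index)
        return Chunk(
            c1,
            c2,
            c3,
            n=int(self.n[index]),
            t=int(self.t[index]),
            populated=bool(self.populated[index]),
        )

    @property
    def populated_indices(self) -> np.ndarray:
        return np.flatnonzero(self.populated)

    @property
    def n_populated(self) -> int:
        return int(self.populated.sum())

    def present(self, triple: Sequence[int], j: int) -> int:
        """Present (create or merge) the chunk for ``triple`` at round ``j``.

        First presentation populates the chunk with ``n=1, t=j``; any later
        presentation of the same triple increments ``n`` and leaves the
        creation round untouched (the lifetime runs from first creation).
        Returns the chunk index.
        """
        c1, c2, c3 = (int(v) for v in triple)
        i = self.index_of(c1, c2, c3)
        if self.populated[i]:
            self.n[i] += 1
        else:
            self.populated[i] = True
            self.n[i] = 1
            self.t[i] = j
        return i

    def reinforce(self, index: int) -> None:
        """Count a retrieval of ``index`` as an extra presentation.

        Only used when the agent is configured to treat recall as
        re-presentation; the default round loop does not call this.
        """
        if not self.populated[index]:
            raise ValueError(f"cannot reinforce unpopulated chunk {index}")
        self.n[index] += 1

    # -- JSON fixtures -----------------------------------------------------
    def to_json(self) -> str:
        idx = self.populated_indices
        return json.dumps(
            {
                "populated": [
                    {
                        "index": int(i),
                        "triple": list(self.triple_of(int(i))),
                        "n": int(self.n[i]),
                        "t": int(self.t[i]),
                    }
                    for i in idx
                ]
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DeclarativeMemory":
        mem = cls()
        for rec in json.loads(text)["populated"]:
            i = int(rec["index"])
            mem.populated[i] = True
            mem.n[i] = int(rec["n"])
            mem.t[i] = int(rec["t"])
        return mem


# ---------------------------------------------------------------------------
# Activation mathematics
# ---------------------------------------------------------------------------

def lifetime(t_creation: int, j: int, T: float) -> float:
    """Lifetime (in rounds) of a chunk created at round ``t_creation``."""
    if j < t_creation:
        raise ValueError(
            f"current round {j} precedes creation round {t_creation}"
        )
    return (j - t_creation) + T


def base_level(n: float, L: float, d: float) -> float:
    """Base-level activation ``ln(n/(1-d)) - d*ln(L)``."""
    if n < 1:
        raise ValueError(f"presentation count must be >= 1, got {n}")
    if L <= 0:
        raise ValueError(f"lifetime must be positive, got {L}")
    return math.log(n / (1.0 - d)) - d * math.log(L)


def similarity(a: float, b: float) -> float:
    """Slot similarity ``-|a-b|/max(a,b)``, in [-1, 0]; 0 iff equal."""
    if a <= 0 or b <= 0:
        raise ValueError(f"similarity requires positive values, got ({a}, {b})")
    return -abs(a - b) / max(a, b)


def context_component(
    chunk: Chunk, request: tuple[float, float], P: float
) -> float:
    """Partial-matching component ``P*(sim(p_j,c2) + sim(p*,c3))``.

    The request matches the current production against the chunk's
    production-before slot and the target production against its
    production-after slot.
    """
    if not chunk.populated:
        raise ValueError("context component is defined for populated chunks")
    p_j, p_star = request
    return P * (similarity(p_j, chunk.c2) + similarity(p_star, chunk.c3))


def chunk_activation(
    chunk: Chunk,
    request: tuple[float, float],
    params: ActivationParams,
    noise: float,
    j: int,
) -> float:
    """Total activation of one chunk; unpopulated chunks sit at exactly -M."""
    if not chunk.populated:
        return -params.M
    L = lifetime(chunk.t, j, params.T)
    return (
        base_level(chunk.n, L, params.d)
        + context_component(chunk, request, params.P)
        + noise
    )


# Precomputed context lookup: _CTX_BY_P[p-1, i] = sim(p, c2_i) + sim(9, c3_i)
# for integer requests p in {1..12} against the fixed triple enumeration.
_VALS = np.arange(1, N_SLOT_VALUES + 1, dtype=float)
_SIM_TABLE = -np.abs(_VALS[:, None] - _VALS[None, :]) / np.maximum(
    _VALS[:, None], _VALS[None, :]
)
_CTX_BY_P = (
    _SIM_TABLE[:, SLOT_C2 - 1] + _SIM_TABLE[TARGET_PRODUCTION - 1, SLOT_C3 - 1]
)


def activation_vector(
    memory: DeclarativeMemory,
    request: tuple[int, int],
    params: ActivationParams,
    j: int,
    noise: Optional[np.ndarray] = None,
    out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Activations of all 1728 chunks for an integer-valued request.

    Unpopulated chunks are pinned at ``-M`` (no noise added to the sentinel);
    populated chunks get base level + partial matching + their noise entry.
    """
    p_j, p_star = request
    _check_slot(p_j, "request p_j")
    if p_star != TARGET_PRODUCTION:
        raise ValueError(f"retrieval target must be {TARGET_PRODUCTION}")
    if noise is not None and len(noise) != N_CHUNKS:
        raise ValueError(
            f"noise vector must have length {N_CHUNKS}, got {len(noise)}"
        )
    if out is None:
        out = np.empty(N_CHUNKS, dtype=float)
    out.fill(-params.M)
    idx = memory.populated_indices
    if idx.size:
        L = (j - memory.t[idx]) + params.T
        B = np.log(memory.n[idx] / (1.0 - params.d)) - params.d * np.log(L)
        A = B + params.P * _CTX_BY_P[p_j - 1, idx]
        if noise is not None:
            A = A + np.asarray(noise)[idx]
        out[idx] = A
    return out


def retrieve(
    memory: DeclarativeMemory,
    request: tuple[int, int],
    params: ActivationParams,
    noise_vector: Optional[np.ndarray],
    j: int,
) -> Optional[Retrieval]:
    """Thresholded retrieval: highest-activation chunk if it clears ``tau``.

    Ties are broken deterministically in favour of the lowest chunk index.
    Returns ``None`` when no activation reaches the threshold.
    """
    A = activation_vector(memory, request, params, j, noise=noise_vector)
    i = int(np.argmax(A))  # first occurrence of the maximum -> lowest index
    if A[i] >= params.tau:
        return Retrieval(i, float(A[i]))
    return None


def logistic_noise(s: float, rng: np.random.Generator) -> float:
    """One transient-noise draw: logistic(0, s); exactly 0 when s == 0."""
    if s < 0:
        raise ValueError(f"noise scale must be >= 0, got {s}")
    if s == 0.0:
        return 0.0
    return float(rng.logistic(loc=0.0, scale=s))
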