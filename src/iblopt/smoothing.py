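"""Continuously differentiable reformulation of the round loop.

Every discrete construct in the model — if/then branches, max, |.|, the
argmax chunk selection, clipping, and the on-target test — is replaced by a
composition of two primitives,

    H(x) = arctan(h*x)/pi + 1/2        (smooth Heaviside, sharpness h)
    delta(x) = exp(-x^2 / a^2)         (smooth equality test, width a)

so that a whole episode becomes a smooth function of the model parameters.
Sharpness is tunable separately per model part: ``h_sim`` for the similarity
terms, ``h_argmax`` for chunk selection and every discrete-semantics test
(grid equality, score indicator), and ``h_env`` for production/workforce
clipping.  In the sharp-selection regime (``h_argmax = 1e7``) the smoothed
episode reproduces the discrete trajectory; lowering ``h_argmax`` blends the
choice over many chunks and degrades learning toward random behavior.

The n-ary smoothed maximum is a pairwise fold in ascending index order.  Each
fold step against a dominated value pulls the running maximum down by about
``1/(pi*h)``, so over the 1728-chunk vector the smoothed maximum sits below
the true maximum by up to ~``N_c/(pi*h)``.  The chunk-selection weights are
the equality tests ``delta(A_i - A*)``: at ``h_argmax = 1e7`` the fold
deflation (~5e-5) is far inside the equality width ``a_delta`` and selection
is exact; at ``h_argmax = 1e3`` the deflation (~0.5) pushes the maximizer
itself outside the width, the selection mass vanishes, and the agent falls
back to random exploration — the mechanism by which the score collapses when
the argmax smoothing is softened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import env
from .agent import SimulationConfig
from .memory import N_CHUNKS, SLOT_C1, SLOT_C2, SLOT_C3
from .streams import InputStreams

__all__ = [
    "SmoothingParams",
    "smooth_heaviside",
    "smooth_delta",
    "smooth_if_then",
    "smooth_max",
    "smooth_abs",
    "smooth_absratio",
    "fold_max",
    "smooth_argmax_select",
    "smooth_clip",
    "smooth_on_target",
    "SmoothedRunResult",
    "run_episode_smoothed",
]

_INV_PI = 1.0 / math.pi

#: Half-width of the grid-equality window: real values within 1/2 of an
#: integer grid point are treated as equal to it.
GRID_HALF_WIDTH = 0.5


@dataclass(frozen=True)
class SmoothingParams:
    """Per-model-part sharpness of the smooth reformulation.

    h_sim    : sharpness for similarity (partial matching) terms.
    h_argmax : sharpness for chunk selection and discrete-semantics tests
               (grid equality, presentation matching, score indicator);
               1e7 is the regime in which the smoothed model matches the
               discrete one.
    h_env    : sharpness for production/workforce clipping.
    a_delta  : width of the Gaussian equality approximation (only used when
               ``walk_test="delta"``).
    walk_test: how the walk's "production equals 9?" branch is smoothed —
               "delta" (default) uses the Gaussian of width ``a_delta``;
               "window" tests |p-9| <= 1/2 with an h_argmax-sharp window
               (robust to the ~1e-2 off-grid drift the h_env clipping
               introduces at its bounds).
    presentation_test: how the "does chunk (x, p, p') already exist?"
               equality is smoothed — "window" (default) tests each slot
               against the nearest grid value with h_argmax-sharp +-1/2
               windows; "delta"/"x_delta" use the Gaussian width on all
               slots / on the workforce slot only.
    indicator: the on-target score test — "window" (default) is the
               h_argmax-sharp band |p-9| <= 3/2, "band_env" the same band
               at h_env sharpness.
    a_star_mode: n-ary maximum as the ascending smooth-max fold ("fold",
               default) or the exact maximum ("exact").
    selection_weight: chunk-selection weights as equality tests
               ``delta(A_i - A*)`` ("delta", default) or normalized
               Heaviside weights ``H(A_i - A*)`` ("heaviside").
    """

    h_sim: float = 10.0
    h_argmax: float = 1.0e7
    h_env: float = 10.0
    a_delta: float = 0.01
    walk_test: str = "delta"
    presentation_test: str = "window"
    indicator: str = "window"
    a_star_mode: str = "fold"
    selection_weight: str = "delta"

    def __post_init__(self) -> None:
        for name in ("h_sim", "h_argmax", "h_env", "a_delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.walk_test not in ("window", "delta"):
            raise ValueError(f"unknown walk_test {self.walk_test!r}")
        if self.presentation_test not in ("window", "delta", "x_delta"):
            raise ValueError(
                f"unknown presentation_test {self.presentation_test!r}"
            )
        if self.indicator not in ("window", "band_env"):
            raise ValueError(f"unknown indicator {self.indicator!r}")
        if self.a_star_mode not in ("exact", "fold"):
            raise ValueError(f"unknown a_star_mode {self.a_star_mode!r}")
        if self.selection_weight not in ("delta", "heaviside"):
            raise ValueError(
                f"unknown selection_weight {self.selection_weight!r}"
            )


# ---------------------------------------------------------------------------
# Primitive smooth operators
# ---------------------------------------------------------------------------

def smooth_heaviside(x, h: float):
    """``arctan(h*x)/pi + 1/2``: strictly increasing, H(0) = 1/2."""
    return np.arctan(h * np.asarray(x, dtype=float)) * _INV_PI + 0.5


def smooth_delta(x, a_delta: float):
    """Gaussian equality bump ``exp(-x^2/a^2)``; 1 at x = 0."""
    x = np.asarray(x, dtype=float)
    return np.exp(-(x * x) / (a_delta * a_delta))


def smooth_if_then(condition_value, then_val, else_val, h: float):
    """``H(c)*then + (1-H(c))*else`` — the smoothed s >= 0 branch."""
    H = smooth_heaviside(condition_value, h)
    return H * then_val + (1.0 - H) * else_val


def smooth_max(x, y, h: float):
    """``H(x-y)*x + (1-H(x-y))*y``; exact when x == y."""
    H = smooth_heaviside(np.asarray(x, dtype=float) - y, h)
    return H * x + (1.0 - H) * y


def smooth_abs(x, h: float):
    """``|x|`` as ``x*(2H(x)-1)``."""
    return np.asarray(x, dtype=float) * (2.0 * smooth_heaviside(x, h) - 1.0)


def smooth_absratio(x, y, h: float):
    """``|x-y|/max(x,y)`` via the two smoothed branches.

    Requires max(x, y) bounded away from zero (slot values are >= 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(np.maximum(x, y) <= 1e-12):
        raise ValueError("absratio requires max(x, y) > 0")
    H = smooth_heaviside(x - y, h)
    return H * (x - y) / x + (1.0 - H) * (y - x) / y


def fold_max(values: Sequence[float], h: float) -> float:
    """n-ary smoothed maximum: pairwise smooth_max in ascending index order."""
    vals = np.asarray(values, dtype=float).tolist()
    if not vals:
        raise ValueError("fold_max of an empty sequence")
    m = vals[0]
    atan = math.atan
    for a in vals[1:]:
        H = atan(h * (m - a)) * _INV_PI + 0.5
        m = H * m + (1.0 - H) * a
    return m


def smooth_argmax_select(
    activations: Sequence[float],
    tau: float,
    b1: Sequence[float],
    b2: float,
    h_argmax: float,
    a_delta: float = 0.01,
) -> float:
    """Smoothed "retrieve-or-explore" choice.

    Computes the smoothed maximum ``A*`` of the activations (the ascending
    pairwise fold), weights each chunk by the equality test
    ``w_i = delta(A_i - A*)`` — "chunk *i* achieves the maximum" — and
    gates retrieval on the threshold term ``gate = H(A* - tau)``:

        x = gate * sum_i w_i * b1_i + (1 - gate * sum_i w_i) * b2.

    The fallback ``b2`` is weighted by "no chunk was retrievable": either
    the maximum fails the threshold (``gate`` small) or no chunk's
    activation matches the smoothed maximum (``sum_i w_i`` small).

    The fold under-estimates the true maximum by roughly ``k/(pi*h)`` for
    ``k`` dominated fold steps.  In the sharp regime that deflation is well
    inside the equality width ``a_delta``, so the maximizer's weight is ~1
    and the choice reproduces the discrete rule.  At small ``h_argmax``
    the deflation exceeds ``a_delta``, the selection mass vanishes, and
    the choice degenerates to the exploration fallback — learning is
    replaced by random behavior.
    """
    A = np.asarray(activations, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    a_star = fold_max(A, h_argmax)
    w = smooth_delta(A - a_star, a_delta)
    gate = smooth_heaviside(a_star - tau, h_argmax)
    return float(gate * np.dot(w, b1) + (1.0 - gate * w.sum()) * b2)


def smooth_clip(y, lo: float, hi: float, h: float):
    """Clip to [lo, hi] by nested smooth branches (upper bound first)."""
    y = np.asarray(y, dtype=float)
    H_hi = smooth_heaviside(y - hi, h)
    H_lo = smooth_heaviside(lo - y, h)
    return H_hi * hi + (1.0 - H_hi) * (H_lo * lo + (1.0 - H_lo) * y)


def smooth_on_target(p, h: float):
    """Smoothed score indicator for the goal band: ``H(3/2 - |p - 9|)``."""
    return smooth_heaviside(1.5 - smooth_abs(np.asarray(p) - env.TARGET, h), h)


def _grid_window(z, h: float):
    """Smoothed grid-equality test ``|z| <= 1/2``."""
    return smooth_heaviside(GRID_HALF_WIDTH - smooth_abs(z, h), h)


# ---------------------------------------------------------------------------
# Smoothed episode runner
# ---------------------------------------------------------------------------

_SLOT_VALUES = np.arange(1, 13, dtype=float)
_C1F = SLOT_C1.astype(float)
_C2I = SLOT_C2 - 1
_C3I = SLOT_C3 - 1

#: Chunks with presentation mass below this play no role in retrieval and are
#: held at the sentinel; purely a numerical cutoff (the mass leaking onto a
#: neighboring triple in the sharp regime is ~1e-7 per round).
ACTIVE_CUTOFF = 1.0e-6


@dataclass
class SmoothedRunResult:
    """Real-valued trajectory of a smoothed episode."""

    x: np.ndarray  # chosen workforce per round
    p: np.ndarray  # production, length n_rounds + 1 (p[0] = p1)
    round_scores: np.ndarray  # smoothed on-target indicator per round
    retrieval_weights: np.ndarray  # gate H(A* - tau) per round
    score: float
    presentation_mass: np.ndarray  # final per-chunk presentation counts

    def to_frame(self):
        import pandas as pd

        n = len(self.x)
        return pd.DataFrame(
            {
                "round": np.arange(1, n + 1),
                "x": self.x,
                "p_before": self.p[:-1],
                "p_after": self.p[1:],
                "round_score": self.round_scores,
                "retrieval_weight": self.retrieval_weights,
            }
        )


def run_episode_smoothed(
    config: SimulationConfig,
    streams: InputStreams,
    smoothing: Optional[SmoothingParams] = None,
) -> SmoothedRunResult:
    """The round loop with every discrete construct smoothed.

    Productions, workforces, presentation counts and the per-round score are
    real numbers throughout; no rounding happens inside the model.  With the
    default sharp selection the trajectory tracks the discrete model's; the
    score is a sum of indicators in [0, 1] and hence lies in [0, N_r].
    """
    if smoothing is None:
        smoothing = SmoothingParams()
    if streams.n_rounds < config.n_rounds:
        raise ValueError("streams too short for the configured rounds")
    if config.count_retrieval_as_presentation:
        raise NotImplementedError(
            "retrieval-as-presentation is only defined for the discrete loop"
        )
    if config.noise_enabled and streams.u_n is None:
        raise ValueError("noise enabled but streams carry no u_n")

    pr = config.params
    h_sim, h_arg, h_env = smoothing.h_sim, smoothing.h_argmax, smoothing.h_env
    log_one_minus_d = math.log(1.0 - pr.d)

    n_mass = np.zeros(N_CHUNKS)  # real-valued presentation counts
    t_creat = np.ones(N_CHUNKS)  # creation round; refreshed until created
    A = np.empty(N_CHUNKS)

    n_rounds = config.n_rounds
    xs = np.empty(n_rounds)
    ps = np.empty(n_rounds + 1)
    scores = np.empty(n_rounds)
    gates = np.empty(n_rounds)

    p = float(config.p1)
    u_w = float(streams.w_init)
    ps[0] = p

    for j in range(1, n_rounds + 1):
        # (1) activations: base level + smoothed partial matching
        A.fill(-pr.M)
        idx = np.flatnonzero(n_mass > ACTIVE_CUTOFF)
        if idx.size:
            L = (j - t_creat[idx]) + pr.T
            B = np.log(n_mass[idx]) - log_one_minus_d - pr.d * np.log(L)
            sim_c2 = -smooth_absratio(p, _SLOT_VALUES, h_sim)
            sim_c3 = -smooth_absratio(float(env.TARGET), _SLOT_VALUES, h_sim)
            act = B + pr.P * (sim_c2[_C2I[idx]] + sim_c3[_C3I[idx]])
            if config.noise_enabled:
                act = act + streams.noise_row(j)[idx]
            A[idx] = act

        # (2)+(3) smoothed selection: retrieve-or-explore
        if smoothing.a_star_mode == "exact":
            a_star = float(A.max())
        else:
            a_star = fold_max(A, h_arg)
        gate = float(smooth_heaviside(a_star - pr.tau, h_arg))
        if smoothing.selection_weight == "delta":
            # retrieve iff the activation clears tau AND some chunk matches
            # the maximum; the total delta-mass is the smoothed "such a
            # chunk exists" indicator.
            w = smooth_delta(A - a_star, smoothing.a_delta)
            mass = float(w.sum())
            x = gate * float(np.dot(w, _C1F)) + (1.0 - gate * mass) * u_w
        else:
            w = smooth_heaviside(A - a_star, h_arg)
            x = gate * float(np.dot(w, _C1F) / w.sum()) + (1.0 - gate) * u_w

        # (4) environment update with smoothed clipping
        p_new = float(
            smooth_clip(2.0 * x - p + float(streams.u_r[j - 1]), 1.0, 12.0, h_env)
        )

        # walk update: on-goal vs off-goal exploration step
        if config.on_target_rule_for_walk == "band_8_10":
            g = float(smooth_on_target(p_new, h_arg))
        elif smoothing.walk_test == "delta":
            g = float(smooth_delta(p_new - env.TARGET, smoothing.a_delta))
        else:
            g = float(_grid_window(p_new - env.TARGET, h_arg))
        anchor = x if config.exploration_anchor == "last_choice" else u_w
        u_w = anchor + g * float(streams.u_on[j - 1]) + (1.0 - g) * float(
            streams.u_off[j - 1]
        )
        u_w = float(smooth_clip(u_w, 1.0, 12.0, h_env))

        # (7) smoothed score indicator
        if smoothing.indicator == "band_env":
            r = float(smooth_on_target(p_new, h_env))
        else:
            r = float(smooth_on_target(p_new, h_arg))

        # (8) smoothed presentation: per-slot equality against the grid
        if smoothing.presentation_test == "delta":
            wx = smooth_delta(x - _SLOT_VALUES, smoothing.a_delta)
            wp = smooth_delta(p - _SLOT_VALUES, smoothing.a_delta)
            wq = smooth_delta(p_new - _SLOT_VALUES, smoothing.a_delta)
        elif smoothing.presentation_test == "x_delta":
            wx = smooth_delta(x - _SLOT_VALUES, smoothing.a_delta)
            wp = _grid_window(p - _SLOT_VALUES, h_arg)
            wq = _grid_window(p_new - _SLOT_VALUES, h_arg)
        else:
            wx = _grid_window(x - _SLOT_VALUES, h_arg)
            wp = _grid_window(p - _SLOT_VALUES, h_arg)
            wq = _grid_window(p_new - _SLOT_VALUES, h_arg)
        w_triple = (
            wx[:, None, None] * wp[None, :, None] * wq[None, None, :]
        ).ravel()
        freeze = smooth_heaviside(n_mass - 0.5, h_arg)
        t_creat = freeze * t_creat + (1.0 - freeze) * j
        n_mass += w_triple

        xs[j - 1] = x
        ps[j] = p_new
        scores[j - 1] = r
        gates[j - 1] = gate
        p = p_new

    return SmoothedRunResult(
        x=xs,
        p=ps,
        round_scores=scores,
        retrieval_weights=gates,
        score=float(scores.sum()),
        presentation_mass=n_mass,
    )
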