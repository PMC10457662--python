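"""The adaptive block main loop: shift, grow, shrink, checkpoint, X-drop.

A square B x B block slides through the DP matrix.  Each step computes one
new S x B (shift right) or B x S (shift down) strip; the shift direction is
chosen greedily by comparing border maxima.  When ``Y = floor(B/S) - 1``
steps pass without a new maximum score, the driver restores the last
checkpoint, doubles B, and recomputes — this is what lets a small block span
long gaps.  When the maximum sits in the block's bottom-right corner cells
the block is halved and recentred.  In X-drop mode the search stops after
two consecutive steps scoring more than X below the running maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dp_core import GLOBAL, NEG_INF, XDROP, DpRegionState, Rect, compute_rect
from .scoring import Pssm, SubstitutionMatrix, pssm_from_sequence
from .traceback import DOWN, RIGHT, Cigar, TraceStack, decode

__all__ = ["AlignParams", "BlockState", "Checkpoint", "AlignmentResult",
           "align", "decide_shift", "grow_trigger", "grow",
           "shrink_trigger", "shrink", "xdrop_check"]

GROW = "GROW"


def _is_pow2(n: int) -> bool:
    return n > 0 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class AlignParams:
    """Tunables for the adaptive block search.

    ``b_min``/``b_max`` are the block size range (powers of two, cells);
    ``s`` is the step size; ``l`` the vector chunk factor (observationally
    inert); ``x`` the X-drop threshold (XDROP mode only); ``clamp16``
    emulates 16-bit score lanes relative to a per-step 32-bit offset.
    """

    mode: str = GLOBAL
    b_min: int = 32
    b_max: int = 256
    s: int = 8
    l: int = 16
    x: int | None = None
    clamp16: bool = False

    def __post_init__(self):
        if self.mode not in (GLOBAL, XDROP):
            raise ValueError(f"bad mode {self.mode!r}")
        if not (_is_pow2(self.b_min) and _is_pow2(self.b_max)):
            raise ValueError("block sizes must be powers of two")
        if not self.s <= self.b_min <= self.b_max:
            raise ValueError("need s <= b_min <= b_max")
        if self.b_min < 2 * self.s:
            raise ValueError("need b_min >= 2*s")
        if self.mode == XDROP and (self.x is None or self.x <= 0):
            raise ValueError("XDROP mode needs a positive x threshold")


@dataclass
class BlockState:
    """Mutable driver state: block position/size plus search bookkeeping."""

    i: int = 0
    j: int = 0
    b: int = 0
    b_prev: int = 0
    dir: str = GROW
    max_score: int = 0
    max_pos: tuple[int, int] = (0, 0)
    curr_score: int = NEG_INF
    steps_since_improve: int = 0
    xdrop_strikes: int = 0
    offset: int = 0


@dataclass
class Checkpoint:
    """Block position/size, border snapshot, and trace length to restore to."""

    i: int
    j: int
    b: int
    borders: tuple
    trace_len: int
    max_pos: tuple[int, int]


@dataclass
class AlignmentResult:
    score: int
    end_pos: tuple[int, int]
    cigar: Cigar
    stats: dict = field(default_factory=dict)

    def __repr__(self):
        return (f"AlignmentResult(score={self.score}, end_pos={self.end_pos}, "
                f"cigar='{self.cigar}')")


def decide_shift(state: BlockState, dp: DpRegionState, s: int) -> str:
    """RIGHT iff the max of the S topmost right-border D scores is >= the
    max of the S leftmost bottom-border D scores (ties break RIGHT)."""
    i, j, b = state.i, state.j, state.b
    right_d, _ = dp.read_col(j + b - 1, i, s)
    bottom_d, _, _ = dp.read_row(i + b - 1, j, s)
    return RIGHT if int(right_d.max()) >= int(bottom_d.max()) else DOWN


def grow_trigger(state: BlockState, params: AlignParams) -> bool:
    """True iff B < Bmax and ``Y = floor(B/S) - 1`` steps passed without a
    new maximum."""
    y = state.b // params.s - 1
    return state.b < params.b_max and state.steps_since_improve >= y


def shrink_trigger(state: BlockState, params: AlignParams) -> bool:
    """True iff B > Bmin and the running max sits in the S/4 rightmost cells
    of the bottom border or the S/4 bottom-most cells of the right border."""
    if state.b <= params.b_min:
        return False
    i, j, b = state.i, state.j, state.b
    mi, mj = state.max_pos
    corner = params.s // 4
    in_bottom = mi == i + b - 1 and j + b - corner <= mj <= j + b - 1
    in_right = mj == j + b - 1 and i + b - corner <= mi <= i + b - 1
    return in_bottom or in_right


def xdrop_check(state: BlockState, params: AlignParams) -> bool:
    """Update the strike counter; True when 2 consecutive steps fall more
    than X below the running maximum (XDROP mode only)."""
    if params.mode != XDROP:
        return False
    if state.curr_score < state.max_score - params.x:
        state.xdrop_strikes += 1
    else:
        state.xdrop_strikes = 0
    return state.xdrop_strikes >= 2


def _save_checkpoint(state: BlockState, dp: DpRegionState,
                     trace: TraceStack) -> Checkpoint:
    return Checkpoint(state.i, state.j, state.b, dp.snapshot(), len(trace),
                      state.max_pos)


def grow(state: BlockState, ckpt: Checkpoint, dp: DpRegionState,
         trace: TraceStack, params: AlignParams) -> BlockState:
    """Restore the checkpoint, double B (capped at Bmax), pop the trace.

    ``Bprev`` becomes the checkpoint's block size so repeated grows from the
    same checkpoint recompute consistent L-shaped extensions; the next step
    runs with ``dir = GROW``.
    """
    state.b_prev = ckpt.b
    state.b = min(2 * state.b, params.b_max)
    state.i, state.j = ckpt.i, ckpt.j
    dp.restore(ckpt.borders)
    trace.pop_to(ckpt.trace_len)
    state.max_pos = ckpt.max_pos
    state.dir = GROW
    return state


def shrink(state: BlockState, dp: DpRegionState,
           trace: TraceStack) -> Checkpoint:
    """Halve B, move the block to ``(i + B/2, j + B/2)`` (new B applied
    first), trim the borders, and save a fresh checkpoint."""
    state.b //= 2
    state.i += state.b
    state.j += state.b
    dp.trim(state.i, state.j, state.b)
    state.steps_since_improve = 0
    return _save_checkpoint(state, dp, trace)


def _clamp16_rebase(dp: DpRegionState, offset: int) -> None:
    """Emulate 16-bit score lanes relative to a 32-bit per-step offset."""
    lo, hi = -(1 << 15), (1 << 15) - 1
    cb, rb = dp.col_border, dp.row_border
    for b, names in ((cb, ("D", "C")), (rb, ("D", "R", "Dp"))):
        if b is None:
            continue
        for name in names:
            v = getattr(b, name)
            setattr(b, name, np.clip(v - offset, lo, hi) + offset)


def align(q: str, target: Pssm | str, params: AlignParams | None = None,
          matrix: SubstitutionMatrix | None = None, g_open: int = -10,
          g_ext: int = -1, g_close: int = 0) -> AlignmentResult:
    """Adaptive block alignment of query ``q`` against a sequence or PSSM.

    A plain-string target is lifted into a PSSM with ``matrix`` and the
    constant gap penalties; a :class:`Pssm` target carries its own penalties.
    Returns the GLOBAL score ``D[|q|][|p|]`` (or the X-drop maximum and its
    position), the decoded CIGAR, and step statistics.
    """
    params = params or AlignParams()
    if isinstance(target, Pssm):
        pssm = target
    else:
        if matrix is None:
            raise ValueError("a substitution matrix is required for a "
                             "plain-sequence target")
        pssm = pssm_from_sequence(target, matrix, g_open, g_ext, g_close)
    if len(q) == 0:
        raise ValueError("empty query")
    q_idx = pssm.alphabet.encode(q)
    nq, np_ = len(q), len(pssm)

    dp = DpRegionState()
    trace = TraceStack()
    st = BlockState(b=params.b_min,
                    max_score=0 if params.mode == XDROP else NEG_INF)
    # Zeroth checkpoint: the origin with block size 0 and no borders, so a
    # grow before any improvement recomputes the doubled block from scratch.
    ckpt = Checkpoint(0, 0, 0, dp.snapshot(), 0, (0, 0))
    stats = {"steps": 0, "grows": 0, "shrinks": 0, "cells": 0}

    def run_rect(rect: Rect, orientation: str) -> tuple[int, tuple | None]:
        rect = rect.clamped(nq + 1, np_ + 1)
        stats["cells"] += rect.w * rect.h
        return compute_rect(dp, rect, q_idx, pssm, orientation, trace,
                            L=params.l)

    while True:
        i, j, b, s = st.i, st.j, st.b, params.s
        if st.dir == RIGHT:
            curr, pos = run_rect(Rect(i, j + b - s, s, b), RIGHT)
        elif st.dir == DOWN:
            curr, pos = run_rect(Rect(i + b - s, j, b, s), DOWN)
        else:  # GROW
            bp = st.b_prev
            c1, p1 = run_rect(Rect(i + bp, j, bp, b - bp), DOWN)
            # left halo of the grow-right rect = checkpoint right border
            # merged with the grow-down rect's rightmost column
            c2, p2 = run_rect(Rect(i, j + bp, b - bp, b), RIGHT)
            curr, pos = (c1, p1) if c1 >= c2 else (c2, p2)
        st.curr_score = curr
        stats["steps"] += 1
        st.steps_since_improve += 1

        if curr > st.max_score:
            st.max_score = curr
            st.max_pos = pos
            ckpt = _save_checkpoint(st, dp, trace)
            st.steps_since_improve = 0
        elif st.dir == GROW:
            # a grow step that finds no new max may regrow immediately
            st.steps_since_improve = max(st.steps_since_improve,
                                         st.b // params.s - 1)

        if params.clamp16:
            st.offset = max(curr, NEG_INF // 2)
            _clamp16_rebase(dp, st.offset)

        if xdrop_check(st, params):
            break
        if i + b > nq and j + b > np_:
            break
        if i + b > nq or j + b > np_:
            # one axis exhausted: forced shift along the other
            st.dir = RIGHT if i + b > nq else DOWN
            if st.dir == RIGHT:
                st.j += s
            else:
                st.i += s
            dp.trim(st.i, st.j, st.b)
            continue

        if grow_trigger(st, params):
            grow(st, ckpt, dp, trace, params)
            stats["grows"] += 1
            continue

        if shrink_trigger(st, params):
            ckpt = shrink(st, dp, trace)
            stats["shrinks"] += 1

        st.dir = decide_shift(st, dp, s)
        if st.dir == RIGHT:
            st.j += s
        else:
            st.i += s
        dp.trim(st.i, st.j, st.b)

    if params.mode == GLOBAL:
        score = dp.read_cell_D(nq, np_)
        end = (nq, np_)
    else:
        score, end = st.max_score, st.max_pos
    cigar = decode(trace, end, q, pssm) if score > NEG_INF // 2 else Cigar()
    return AlignmentResult(score=score, end_pos=end, cigar=cigar, stats=stats)
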