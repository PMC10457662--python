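"""Score computation for rectangular DP regions, plus a full-matrix oracle.

The DP matrix is ``(|q|+1) x (|p|+1)`` with one padding row/column; row ``i``
/ column ``j`` correspond to ``q[i-1]`` / ``p[j-1]``.  For each cell the
generalized Gotoh recurrence is::

    C[i][j]  = max(C[i][j-1] + Gext,  D[i][j-1] + Gopenc[j] + Gext)
    D'[i][j] = max(D[i-1][j-1] + p[j-1][q[i-1]],  C[i][j] + Gclosec[j])
    R[i][j]  = max(R[i-1][j] + Gext,  D'[i-1][j] + Gopenr[j] + Gext)
    D[i][j]  = max(D'[i][j], R[i][j])

with boundary conditions ``D[0][0] = 0``, ``C[i][0] = R[0][j] = -inf``; cells
that are out of bounds, or were never computed (outside all retained block
borders), read as the ``NEG_INF`` sentinel.

Storage is bordered: between steps only the current block's rightmost column
(D, C) and bottom row (D, R, D') are retained, so live score storage is O(B).
Rectangles are evaluated one vector (column or row) at a time; the within-
vector gap recurrence is resolved by a chunked prefix max-scan whose result
is bit-identical for any chunk factor ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scoring import Pssm
from .traceback import (C_EXTEND, D_FROM_R, DOWN, DP_FROM_C, R_EXTEND, RIGHT,
                        Cigar, TraceStack, decode)

__all__ = ["NEG_INF", "Rect", "DpRegionState", "init_origin", "compute_rect",
           "full_dp_oracle", "GLOBAL", "XDROP"]

#: Sentinel for unreachable/uncomputed cells: one quarter of the int64
#: minimum, so adding a couple of penalty terms can never wrap.
NEG_INF = int(np.iinfo(np.int64).min) // 4

GLOBAL = "GLOBAL"
XDROP = "XDROP"


@dataclass(frozen=True)
class Rect:
    """A DP-matrix region ``[r, r+h) x [c, c+w)`` (rows x columns)."""

    r: int
    c: int
    w: int
    h: int

    def __post_init__(self):
        if min(self.r, self.c, self.w, self.h) < 0:
            raise ValueError("rect fields must be non-negative")

    def clamped(self, n_rows: int, n_cols: int) -> "Rect":
        """Truncate at the matrix edges (``n_rows = |q|+1`` etc.)."""
        h = max(0, min(self.r + self.h, n_rows) - self.r)
        w = max(0, min(self.c + self.w, n_cols) - self.c)
        return Rect(self.r, self.c, w, h)


@dataclass
class _ColBorder:
    col: int
    row_start: int
    D: np.ndarray
    C: np.ndarray


@dataclass
class _RowBorder:
    row: int
    col_start: int
    D: np.ndarray
    R: np.ndarray
    Dp: np.ndarray


@dataclass
class DpRegionState:
    """Bordered score storage for the live block region.

    Holds at most one column border (D, C) and one row border (D, R, D') at a
    time; any cell outside them reads as :data:`NEG_INF`.  The origin cell
    ``(0, 0)`` reads as ``D = D' = 0`` until a computed rect covers it.
    """

    col_border: _ColBorder | None = None
    row_border: _RowBorder | None = None
    best: tuple[int, int, int] = (NEG_INF, 0, 0)  # (score, i, j)
    origin: bool = True

    # -- reads ---------------------------------------------------------------
    def _fill_from_col(self, out: dict[str, np.ndarray], col: int,
                       row_start: int, n: int) -> None:
        b = self.col_border
        if b is None or b.col != col:
            return
        lo = max(row_start, b.row_start)
        hi = min(row_start + n, b.row_start + len(b.D))
        if lo >= hi:
            return
        for name in ("D", "C"):
            if name in out:
                out[name][lo - row_start:hi - row_start] = \
                    getattr(b, name)[lo - b.row_start:hi - b.row_start]

    def _fill_from_row(self, out: dict[str, np.ndarray], row: int,
                       col_start: int, n: int) -> None:
        b = self.row_border
        if b is None or b.row != row:
            return
        lo = max(col_start, b.col_start)
        hi = min(col_start + n, b.col_start + len(b.D))
        if lo >= hi:
            return
        for name in ("D", "R", "Dp"):
            if name in out:
                out[name][lo - col_start:hi - col_start] = \
                    getattr(b, name)[lo - b.col_start:hi - b.col_start]

    def read_col(self, col: int, row_start: int, n: int) -> tuple[np.ndarray, np.ndarray]:
        """(D, C) for column ``col`` rows ``[row_start, row_start+n)``."""
        out = {"D": np.full(n, NEG_INF, dtype=np.int64),
               "C": np.full(n, NEG_INF, dtype=np.int64)}
        self._fill_from_col(out, col, row_start, n)
        # a row border may also intersect this column (D only)
        b = self.row_border
        if b is not None and row_start <= b.row < row_start + n \
                and b.col_start <= col < b.col_start + len(b.D):
            out["D"][b.row - row_start] = b.D[col - b.col_start]
        if self.origin and col == 0 and row_start <= 0 < row_start + n:
            out["D"][-row_start] = max(out["D"][-row_start], 0)
        return out["D"], out["C"]

    def read_row(self, row: int, col_start: int, n: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(D, R, D') for row ``row`` cols ``[col_start, col_start+n)``."""
        out = {"D": np.full(n, NEG_INF, dtype=np.int64),
               "R": np.full(n, NEG_INF, dtype=np.int64),
               "Dp": np.full(n, NEG_INF, dtype=np.int64)}
        self._fill_from_row(out, row, col_start, n)
        b = self.col_border
        if b is not None and col_start <= b.col < col_start + n \
                and b.row_start <= row < b.row_start + len(b.D):
            out["D"][b.col - col_start] = b.D[row - b.row_start]
        if self.origin and row == 0 and col_start <= 0 < col_start + n:
            k = -col_start
            out["D"][k] = max(out["D"][k], 0)
            out["Dp"][k] = max(out["Dp"][k], 0)
        return out["D"], out["R"], out["Dp"]

    def read_cell_D(self, i: int, j: int) -> int:
        return int(self.read_col(j, i, 1)[0][0])

    # -- writes --------------------------------------------------------------
    @staticmethod
    def _merge(starts_vals: list[tuple[int, list[np.ndarray]]], n_arrays: int
               ) -> tuple[int, list[np.ndarray]]:
        lo = min(s for s, _ in starts_vals)
        hi = max(s + len(v[0]) for s, v in starts_vals)
        merged = [np.full(hi - lo, NEG_INF, dtype=np.int64) for _ in range(n_arrays)]
        for s, vals in starts_vals:  # later entries win
            for m, v in zip(merged, vals):
                m[s - lo:s - lo + len(v)] = v
        return lo, merged

    def update_col_border(self, col: int, row_start: int,
                          D: np.ndarray, C: np.ndarray) -> None:
        b = self.col_border
        if b is not None and b.col == col:
            row_start, (D, C) = self._merge(
                [(b.row_start, [b.D, b.C]), (row_start, [D, C])], 2)
        self.col_border = _ColBorder(col, row_start, D, C)

    def update_row_border(self, row: int, col_start: int, D: np.ndarray,
                          R: np.ndarray, Dp: np.ndarray) -> None:
        b = self.row_border
        if b is not None and b.row == row:
            col_start, (D, R, Dp) = self._merge(
                [(b.col_start, [b.D, b.R, b.Dp]), (col_start, [D, R, Dp])], 3)
        self.row_border = _RowBorder(row, col_start, D, R, Dp)

    def trim(self, i: int, j: int, b: int) -> None:
        """Keep only the parts of the borders inside block ``[i,i+b)x[j,j+b)``."""
        cb = self.col_border
        if cb is not None:
            lo, hi = max(cb.row_start, i), min(cb.row_start + len(cb.D), i + b)
            if lo >= hi:
                self.col_border = None
            else:
                s = slice(lo - cb.row_start, hi - cb.row_start)
                self.col_border = _ColBorder(cb.col, lo, cb.D[s], cb.C[s])
        rb = self.row_border
        if rb is not None:
            lo, hi = max(rb.col_start, j), min(rb.col_start + len(rb.D), j + b)
            if lo >= hi:
                self.row_border = None
            else:
                s = slice(lo - rb.col_start, hi - rb.col_start)
                self.row_border = _RowBorder(rb.row, lo, rb.D[s], rb.R[s], rb.Dp[s])

    def snapshot(self) -> tuple:
        cb = self.col_border
        rb = self.row_border
        return (
            None if cb is None else _ColBorder(cb.col, cb.row_start,
                                               cb.D.copy(), cb.C.copy()),
            None if rb is None else _RowBorder(rb.row, rb.col_start, rb.D.copy(),
                                               rb.R.copy(), rb.Dp.copy()),
        )

    def restore(self, snap: tuple) -> None:
        cb, rb = snap
        self.col_border = None if cb is None else _ColBorder(
            cb.col, cb.row_start, cb.D.copy(), cb.C.copy())
        self.row_border = None if rb is None else _RowBorder(
            rb.row, rb.col_start, rb.D.copy(), rb.R.copy(), rb.Dp.copy())


def init_origin(state: DpRegionState | None = None) -> DpRegionState:
    """A fresh state: ``D[0][0] = 0``, everything else uncomputed."""
    if state is None:
        return DpRegionState()
    state.col_border = None
    state.row_border = None
    state.best = (NEG_INF, 0, 0)
    state.origin = True
    return state


def _gap_scan(open_cand: np.ndarray, carry: int, g_ext: int, L: int) -> np.ndarray:
    """Resolve ``V[k] = max(V[k-1]+g_ext, open_cand[k])`` with ``V[-1]=carry``.

    Evaluated as a prefix max-scan in chunks of ``L`` lanes with a carry
    between chunks; exact for any ``L`` (the chunking mirrors a SIMD-lane
    layout but is observationally identical to the scalar recurrence).
    """
    n = len(open_cand)
    out = np.empty(n, dtype=np.int64)
    for s in range(0, n, L):
        e = min(s + L, n)
        k = np.arange(e - s, dtype=np.int64)
        m = np.maximum.accumulate(open_cand[s:e] - k * g_ext) + k * g_ext
        np.maximum(m, carry + (k + 1) * g_ext, out=out[s:e])
        carry = out[e - 1]
    return out


def compute_rect(state: DpRegionState, rect: Rect, q: np.ndarray, pssm: Pssm,
                 orientation: str = RIGHT, trace: TraceStack | None = None,
                 L: int = 16) -> tuple[int, tuple[int, int] | None]:
    """Compute all cells of ``rect`` (clamped to the matrix) in one pass.

    ``q`` is the alphabet-encoded query.  RIGHT orientation walks columns
    left to right (vectors along rows); DOWN walks rows top to bottom.  Both
    produce bit-identical scores; only the trace cell order differs.  The
    rect's outer borders replace/merge into ``state``'s borders, the best
    computed D (score, i, j) is merged into ``state.best`` and returned.
    """
    n_rows, n_cols = len(q) + 1, len(pssm) + 1
    rect = Rect(rect.r, rect.c, rect.w, rect.h).clamped(n_rows, n_cols)
    r, c, w, h = rect.r, rect.c, rect.w, rect.h
    if w == 0 or h == 0 or r >= n_rows or c >= n_cols:
        return NEG_INF, None
    gaps = pssm.gaps
    profile = pssm.profile_scores
    if orientation == RIGHT:
        best, pos, codes, lastD, lastC, botD, botR, botDp = _sweep_right(
            state, r, c, w, h, q, profile, gaps, L)
        state.update_col_border(c + w - 1, r, lastD, lastC)
        state.update_row_border(r + h - 1, c, botD, botR, botDp)
    elif orientation == DOWN:
        best, pos, codes, lastD, lastR, lastDp, rightD, rightC = _sweep_down(
            state, r, c, w, h, q, profile, gaps, L)
        state.update_row_border(r + h - 1, c, lastD, lastR, lastDp)
        state.update_col_border(c + w - 1, r, rightD, rightC)
    else:
        raise ValueError(f"bad orientation {orientation!r}")
    if trace is not None:
        trace.push_rect(r, c, w, h, orientation, codes)
    if best > state.best[0]:
        state.best = (best, pos[0], pos[1])
    return best, pos


def _sweep_right(state, r, c, w, h, q, profile, gaps, L):
    """Column-major sweep: one vector of ``h`` rows per target column."""
    rows = np.arange(r, r + h)
    q_sub = np.where(rows >= 1, q[np.maximum(rows - 1, 0)], 0)
    prevD, prevC = state.read_col(c - 1, r, h)
    topD, topR, topDp = state.read_row(r - 1, c - 1, w + 1)
    g_ext = gaps.g_ext
    codes = np.empty((w, h), dtype=np.uint8)
    botD = np.empty(w, dtype=np.int64)
    botR = np.empty(w, dtype=np.int64)
    botDp = np.empty(w, dtype=np.int64)
    best = NEG_INF
    pos = None
    for k in range(w):
        j = c + k
        open_c = prevD + (gaps.g_open_c[j] + g_ext)
        ext_c = prevC + g_ext
        C = np.maximum(ext_c, open_c)
        if j >= 1:
            diag = np.empty(h, dtype=np.int64)
            diag[0] = topD[k]  # D[r-1][j-1]
            diag[1:] = prevD[:-1]
            diag = diag + profile[j - 1, q_sub]
            if r == 0:
                diag[0] = NEG_INF  # no residue above row 1
        else:
            diag = np.full(h, NEG_INF, dtype=np.int64)
        close = C + gaps.g_close_c[j]
        Dp = np.maximum(diag, close)
        if r == 0 and j == 0:
            Dp[0] = 0  # the origin: empty alignment
        open_r = np.empty(h, dtype=np.int64)
        open_r[0] = topDp[k + 1]
        open_r[1:] = Dp[:-1]
        open_r += gaps.g_open_r[j] + g_ext
        R = _gap_scan(open_r, topR[k + 1], g_ext, L)
        D = np.maximum(Dp, R)
        # trace bits (ties: diagonal > R > C; gap ties prefer open)
        b1 = close > diag
        b0 = (R > Dp) | ((R == Dp) & b1)
        prev_r = np.empty(h, dtype=np.int64)
        prev_r[0] = topR[k + 1]
        prev_r[1:] = R[:-1]
        b2 = prev_r + g_ext > open_r
        b3 = ext_c > open_c
        codes[k] = (b0 * D_FROM_R | b1 * DP_FROM_C | b2 * R_EXTEND
                    | b3 * C_EXTEND).astype(np.uint8)
        m = int(D.argmax())
        if int(D[m]) > best:
            best, pos = int(D[m]), (r + m, j)
        botD[k], botR[k], botDp[k] = D[-1], R[-1], Dp[-1]
        prevD, prevC = D, C
    return best, pos, codes, prevD, prevC, botD, botR, botDp


def _sweep_down(state, r, c, w, h, q, profile, gaps, L):
    """Row-major sweep: one vector of ``w`` columns per query row."""
    cols = np.arange(c, c + w)
    g_ext = gaps.g_ext
    g_open_r = gaps.g_open_r[cols]
    g_open_c = gaps.g_open_c[cols]
    g_close_c = gaps.g_close_c[cols]
    prevD, prevR, prevDp = state.read_row(r - 1, c, w)
    leftD, leftC = state.read_col(c - 1, r - 1, h + 1)
    corner = leftD  # D[i-1][c-1] for each row; element 0 is row r-1
    codes = np.empty((h, w), dtype=np.uint8)
    rightD = np.empty(h, dtype=np.int64)
    rightC = np.empty(h, dtype=np.int64)
    best = NEG_INF
    pos = None
    # per-position profile scores need q residue of the row; cols>=1 only
    valid = cols >= 1
    pcols = np.maximum(cols - 1, 0)
    for k in range(h):
        i = r + k
        R = np.maximum(prevR + g_ext, prevDp + g_open_r + g_ext)
        if i >= 1:
            diag = np.empty(w, dtype=np.int64)
            diag[0] = corner[k]  # D[i-1][c-1]
            diag[1:] = prevD[:-1]
            s = profile[pcols, q[i - 1]]
            diag = np.where(valid, diag + s, NEG_INF)
        else:
            diag = np.full(w, NEG_INF, dtype=np.int64)
        E = np.maximum(diag, R)  # D without the C-close path
        if i == 0 and c == 0:
            E[0] = 0  # the origin: empty alignment
        open_c = np.empty(w, dtype=np.int64)
        open_c[0] = leftD[k + 1]  # true D[i][c-1]
        open_c[1:] = E[:-1]  # opening from a C-close-derived D never wins
        open_c += g_open_c + g_ext
        C = _gap_scan(open_c, leftC[k + 1], g_ext, L)
        close = C + g_close_c
        Dp = np.maximum(diag, close)
        D = np.maximum(E, close)
        if i == 0 and c == 0:
            Dp[0] = 0
            D[0] = 0
        b1 = close > diag
        b0 = (R > Dp) | ((R == Dp) & b1)
        true_open = np.empty(w, dtype=np.int64)
        true_open[0] = leftD[k + 1]
        true_open[1:] = D[:-1]
        true_open += g_open_c + g_ext
        prev_c = np.empty(w, dtype=np.int64)
        prev_c[0] = leftC[k + 1]
        prev_c[1:] = C[:-1]
        b2 = prevR + g_ext > prevDp + g_open_r + g_ext
        b3 = prev_c + g_ext > true_open
        codes[k] = (b0 * D_FROM_R | b1 * DP_FROM_C | b2 * R_EXTEND
                    | b3 * C_EXTEND).astype(np.uint8)
        m = int(D.argmax())
        if int(D[m]) > best:
            best, pos = int(D[m]), (i, c + m)
        rightD[k], rightC[k] = D[-1], C[-1]
        prevD, prevR, prevDp = D, R, Dp
    return best, pos, codes, prevD, prevR, prevDp, rightD, rightC


def full_dp_oracle(q_seq: str, pssm: Pssm, mode: str = GLOBAL,
                   x: int | None = None) -> tuple[int, Cigar]:
    """Exact reference: the whole DP matrix, no blocks, no pruning.

    GLOBAL returns ``D[|q|][|p|]``; XDROP returns the maximum computed D over
    the full (unpruned) matrix — an upper bound for any pruning heuristic
    (``x`` is accepted for interface parity and ignored).  The traceback is a
    replay of the same transition codes used by the block path.
    """
    if len(q_seq) == 0 or len(pssm) == 0:
        raise ValueError("empty input")
    q = pssm.alphabet.encode(q_seq)
    nr, nc = len(q) + 1, len(pssm) + 1
    gaps = pssm.gaps
    g_ext = gaps.g_ext
    profile = pssm.profile_scores
    D = np.full(nr, NEG_INF, dtype=np.int64)
    C = np.full(nr, NEG_INF, dtype=np.int64)
    trace = TraceStack()
    codes = np.empty((nc, nr), dtype=np.uint8)
    rows = np.arange(nr)
    q_sub = np.where(rows >= 1, q[np.maximum(rows - 1, 0)], 0)
    best = NEG_INF
    best_pos = (0, 0)
    for j in range(nc):
        open_c = D + (int(gaps.g_open_c[j]) + g_ext)
        ext_c = C + g_ext
        Cn = np.maximum(ext_c, open_c)
        if j >= 1:
            diag = np.empty(nr, dtype=np.int64)
            diag[0] = NEG_INF
            diag[1:] = D[:-1]
            diag = diag + profile[j - 1, q_sub]
            diag[0] = NEG_INF
        else:
            diag = np.full(nr, NEG_INF, dtype=np.int64)
        close = Cn + int(gaps.g_close_c[j])
        Dp = np.maximum(diag, close)
        if j == 0:
            Dp[0] = 0
        open_r = np.empty(nr, dtype=np.int64)
        open_r[0] = NEG_INF
        open_r[1:] = Dp[:-1] + (int(gaps.g_open_r[j]) + g_ext)
        Dn = np.empty(nr, dtype=np.int64)
        R = _gap_scan(open_r, NEG_INF, g_ext, nr)
        np.maximum(Dp, R, out=Dn)
        b1 = close > diag
        b0 = (R > Dp) | ((R == Dp) & b1)
        prev_r = np.empty(nr, dtype=np.int64)
        prev_r[0] = NEG_INF
        prev_r[1:] = R[:-1]
        b2 = prev_r + g_ext > open_r
        b3 = ext_c > open_c
        codes[j] = (b0 * D_FROM_R | b1 * DP_FROM_C | b2 * R_EXTEND
                    | b3 * C_EXTEND).astype(np.uint8)
        m = int(Dn.argmax())
        if int(Dn[m]) > best:
            best, best_pos = int(Dn[m]), (m, j)
        D, C = Dn, Cn
    trace.push_rect(0, 0, nc, nr, RIGHT, codes)
    if mode == GLOBAL:
        score, end = int(D[nr - 1]), (nr - 1, nc - 1)
    elif mode == XDROP:
        score, end = best, best_pos
    else:
        raise ValueError(f"bad mode {mode!r}")
    return score, decode(trace, end, q_seq, pssm)
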