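"""Per-cell trace codes with stack semantics, and CIGAR decoding.

Each computed DP cell stores a 4-bit transition code (kept one code per byte;
only the low 4 bits are meaningful):

* bit 0 (``D_FROM_R``)  -- the cell's final score D was taken from R (a
  vertical-gap end) rather than from D' = max(diagonal, C+close).
* bit 1 (``DP_FROM_C``) -- D' was taken from C + g_close (a horizontal-gap
  close) rather than from the diagonal.
* bit 2 (``R_EXTEND``)  -- R extended the gap from the cell above instead of
  opening from D' of the cell above.
* bit 3 (``C_EXTEND``)  -- C extended the gap from the cell to the left
  instead of opening from D of the cell to the left.

Encoding both the D and the D' choice (rather than a single 3-way direction)
keeps the decoder well-defined after an R gap-open, which lands on the D'
state of the cell above.  Codes are appended rect by rect and popped in whole
rects when a checkpoint is restored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import Pssm

__all__ = ["RIGHT", "DOWN", "TraceStack", "Cigar", "push_rect", "pop_to",
           "decode", "cigar_score", "TracebackError",
           "D_FROM_R", "DP_FROM_C", "R_EXTEND", "C_EXTEND"]

RIGHT = "RIGHT"
DOWN = "DOWN"

D_FROM_R = 1
DP_FROM_C = 2
R_EXTEND = 4
C_EXTEND = 8


class TracebackError(RuntimeError):
    """The traceback path crossed a cell that was never computed/retained."""


@dataclass(frozen=True)
class _RectRecord:
    r: int
    c: int
    w: int
    h: int
    orientation: str
    start: int  # offset of this rect's first code in the stack


class TraceStack:
    """Append-only 4-bit codes for every computed cell, popped by whole rects.

    Cell order within a rect is column-major for RIGHT-oriented rects
    (columns are the outer loop) and row-major for DOWN-oriented rects.
    """

    def __init__(self):
        self._records: list[_RectRecord] = []
        self._codes: list[np.ndarray] = []
        self._len = 0

    def __len__(self) -> int:
        return self._len

    @property
    def records(self) -> list[_RectRecord]:
        return list(self._records)

    def push_rect(self, r: int, c: int, w: int, h: int, orientation: str,
                  codes: np.ndarray) -> None:
        codes = np.asarray(codes, dtype=np.uint8).ravel()
        if w <= 0 or h <= 0:
            if codes.size:
                raise ValueError("codes supplied for an empty rect")
            return
        if codes.size != w * h:
            raise ValueError(f"expected {w * h} codes, got {codes.size}")
        if orientation not in (RIGHT, DOWN):
            raise ValueError(f"bad orientation {orientation!r}")
        self._records.append(_RectRecord(r, c, w, h, orientation, self._len))
        self._codes.append(codes)
        self._len += codes.size

    def pop_to(self, trace_len: int) -> None:
        """Discard codes/rects beyond ``trace_len`` (a rect boundary)."""
        if trace_len > self._len:
            raise ValueError("cannot pop forward")
        while self._len > trace_len:
            rec = self._records[-1]
            if rec.start < trace_len:
                raise ValueError("trace_len does not fall on a rect boundary")
            self._records.pop()
            self._len -= self._codes.pop().size

    def code_at(self, i: int, j: int) -> int:
        """Code of cell (i, j), from the most recent rect containing it."""
        for rec, codes in zip(reversed(self._records), reversed(self._codes)):
            if rec.r <= i < rec.r + rec.h and rec.c <= j < rec.c + rec.w:
                if rec.orientation == RIGHT:
                    k = (j - rec.c) * rec.h + (i - rec.r)
                else:
                    k = (i - rec.r) * rec.w + (j - rec.c)
                return int(codes[k])
        raise TracebackError(f"cell ({i}, {j}) was never computed or was discarded")


def push_rect(trace: TraceStack, r: int, c: int, w: int, h: int,
              orientation: str, codes: np.ndarray) -> TraceStack:
    trace.push_rect(r, c, w, h, orientation, codes)
    return trace

def pop_to(trace: TraceStack, trace_len: int) -> TraceStack:
    trace.pop_to(trace_len)
    return trace


class Cigar:
    """Run-length encoded alignment path.

    ``M`` consumes one residue of both query and target (match or mismatch),
    ``I`` consumes query only (a gap in the target, vertical/R moves), ``D``
    consumes target only (a gap in the query, horizontal/C moves).  The
    target (PSSM) side is the reference.
    """

    OPS = "MID"

    def __init__(self, runs: list[tuple[str, int]] | None = None):
        self.runs: list[tuple[str, int]] = []
        for op, n in runs or []:
            self.append(op, n)

    def append(self, op: str, n: int) -> None:
        if op not in self.OPS:
            raise ValueError(f"bad CIGAR op {op!r}")
        if n < 1:
            raise ValueError("run length must be >= 1")
        if self.runs and self.runs[-1][0] == op:
            self.runs[-1] = (op, self.runs[-1][1] + n)
        else:
            self.runs.append((op, n))

    def __str__(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.runs)

    def __repr__(self) -> str:
        return f"Cigar({str(self)!r})"

    def __eq__(self, other) -> bool:
        if isinstance(other, str):
            return str(self) == other
        return isinstance(other, Cigar) and self.runs == other.runs

    def __len__(self) -> int:
        return sum(n for _, n in self.runs)

    @classmethod
    def from_string(cls, s: str) -> "Cigar":
        runs, num = [], ""
        for ch in s:
            if ch.isdigit():
                num += ch
            else:
                runs.append((ch, int(num)))
                num = ""
        if num:
            raise ValueError(f"trailing length in CIGAR {s!r}")
        return cls(runs)

    def query_span(self) -> int:
        return sum(n for op, n in self.runs if op in "MI")

    def target_span(self) -> int:
        return sum(n for op, n in self.runs if op in "MD")


def decode(trace: TraceStack, end: tuple[int, int], q: str, pssm: Pssm) -> Cigar:
    """Walk the trace state machine from ``end`` back to the origin.

    States: D (read both direction bits of the cell), D' (only the C bit,
    reached after an R gap-open), R-run, C-run.  Raises
    :class:`TracebackError` if the path crosses a discarded cell.
    """
    i, j = end
    ops: list[str] = []
    state = "D"
    while i > 0 or j > 0:
        if state in ("D", "Dp"):
            code = trace.code_at(i, j)
            if state == "D" and code & D_FROM_R:
                state = "R"
            elif code & DP_FROM_C:
                state = "C"
            else:
                ops.append("M")
                i, j = i - 1, j - 1
                state = "D"
        elif state == "R":
            code = trace.code_at(i, j)
            ops.append("I")
            state = "R" if code & R_EXTEND else "Dp"
            i -= 1
        else:  # C
            code = trace.code_at(i, j)
            ops.append("D")
            state = "C" if code & C_EXTEND else "D"
            j -= 1
        if i < 0 or j < 0:
            raise TracebackError("traceback ran past the matrix origin")
    if state in ("R", "C"):
        raise TracebackError("traceback ended inside a gap run")
    cig = Cigar()
    for op in reversed(ops):
        cig.append(op, 1)
    return cig


def cigar_score(cigar: Cigar, q: str, pssm: Pssm) -> int:
    """Re-score an alignment path from the origin under the PSSM's scheme.

    Sums profile scores over M columns and ``g_ext*g + g_open_r[j]`` per I
    run / ``g_ext*g + g_open_c[j_first] + g_close_c[j_last]`` per D run.
    This is the independent audit that every returned alignment must pass.
    """
    gaps = pssm.gaps
    i = j = 0
    total = 0
    for op, n in cigar.runs:
        if op == "M":
            for _ in range(n):
                i, j = i + 1, j + 1
                total += pssm.lookup(j, q[i - 1])
        elif op == "I":
            # vertical gap: stays in column j
            total += int(gaps.g_open_r[j]) + n * gaps.g_ext
            i += n
        else:  # D
            total += int(gaps.g_open_c[j + 1]) + n * gaps.g_ext
            j += n
            total += int(gaps.g_close_c[j])
    if i > len(q) or j > len(pssm):
        raise ValueError("CIGAR overruns the sequences")
    return int(total)
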