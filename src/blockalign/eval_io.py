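"""Evaluation metrics and TSV/FASTA plumbing.

The evaluation contract: each pair is aligned with the adaptive block driver
and with the full-DP oracle under the same scoring scheme; a pair whose
block score falls below the optimum is an error, and the percent error of
such a pair is ``(true - pred) / true``.
"""

from __future__ import annotations

import csv
import sys
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

from .block_driver import AlignParams, align
from .dp_core import full_dp_oracle
from .scoring import (DNA, PROTEIN, Alphabet, GapParams, Pssm,
                      SubstitutionMatrix, pssm_from_sequence)

__all__ = ["EvalRecord", "percent_error", "error_rate", "evaluate_pairs",
           "block_range_for_length", "read_pair_tsv", "write_pair_tsv",
           "read_fasta", "read_pssm_tsv", "write_pssm_tsv"]


@dataclass
class EvalRecord:
    pair_id: str
    oracle_score: int
    block_score: int

    @property
    def equal(self) -> bool:
        return self.oracle_score == self.block_score

    @property
    def percent_error(self) -> float | None:
        if self.equal:
            return 0.0
        if self.oracle_score <= 0:
            return None  # undefined; excluded from the mean
        return percent_error(self.oracle_score, self.block_score)


def percent_error(true_score: int, pred_score: int) -> float:
    """(true - pred) / true; undefined for true == 0."""
    if true_score == 0:
        raise ZeroDivisionError("percent error is undefined for a zero "
                                "true score")
    return (true_score - pred_score) / true_score


def error_rate(records: list[EvalRecord]) -> tuple[float, float]:
    """(fraction of suboptimal pairs, mean percent error over those pairs).

    Pairs with non-positive true scores are excluded from the mean with a
    warning (the percent-error formula is undefined there).
    """
    if not records:
        raise ValueError("no records")
    bad = [r for r in records if not r.equal]
    rate = len(bad) / len(records)
    errs = [r.percent_error for r in bad if r.percent_error is not None]
    skipped = len(bad) - len(errs)
    if skipped:
        print(f"warning: {skipped} suboptimal pair(s) with non-positive true "
              "score excluded from mean % error", file=sys.stderr)
    return rate, (float(np.mean(errs)) if errs else 0.0)


def _pow2_ceil(n: int) -> int:
    return 1 << max(0, (int(n) - 1).bit_length())


def block_range_for_length(length: int, min_frac: float = 0.01,
                           max_frac: float = 0.10, floor: int = 32
                           ) -> tuple[int, int]:
    """Block range from percent-of-length bounds: each bound is rounded up
    to the next power of two and floored at ``floor`` cells."""
    b_min = max(floor, _pow2_ceil(max(1, round(length * min_frac))))
    b_max = max(b_min, _pow2_ceil(max(1, round(length * max_frac))))
    return b_min, b_max


def evaluate_pairs(pairs: list[tuple[str, str, str]],
                   matrix: SubstitutionMatrix, g_open: int, g_ext: int,
                   g_close: int = 0, params: AlignParams | None = None,
                   block_frac: tuple[float, float] | None = None,
                   ) -> list[EvalRecord]:
    """Align each (id, q, p) pair with the block driver and the oracle.

    If ``block_frac`` is given, block sizes are derived per pair from
    ``max(|q|, |p|)``; otherwise ``params`` supplies fixed sizes.
    """
    out = []
    for pair_id, q, p in pairs:
        pssm = pssm_from_sequence(p, matrix, g_open, g_ext, g_close)
        if block_frac is not None:
            b_min, b_max = block_range_for_length(max(len(q), len(p)),
                                                  *block_frac)
            pp = AlignParams(b_min=b_min, b_max=b_max,
                             **({} if params is None else
                                {"mode": params.mode, "s": params.s,
                                 "l": params.l, "x": params.x,
                                 "clamp16": params.clamp16}))
        else:
            pp = params or AlignParams()
        res = align(q, pssm, pp)
        true_score, _ = full_dp_oracle(q, pssm)
        out.append(EvalRecord(pair_id, true_score, res.score))
    return out


# ---------------------------------------------------------------------------
# file formats

def read_fasta(path: str) -> list[tuple[str, str]]:
    """(id, sequence) records from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(path, "fasta")]


def read_pair_tsv(path: str) -> list[tuple[str, str, str, float | None]]:
    """Rows of (id, seq1, seq2, true_identity?) from a pair manifest TSV.

    A header row beginning with ``id`` is optional; the identity column may
    be absent.
    """
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            if row[0] == "id":
                continue
            ident = float(row[3]) if len(row) > 3 and row[3] != "" else None
            rows.append((row[0], row[1].upper(), row[2].upper(), ident))
    return rows


def write_pair_tsv(path: str, pairs: list[tuple[str, str, float | None]]
                   ) -> None:
    """Write (seq1, seq2, identity) pairs as an id-keyed manifest TSV."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "seq1", "seq2", "true_identity"])
        for k, (q, p, ident) in enumerate(pairs):
            w.writerow([f"pair{k}", q, p,
                        "" if ident is None else f"{ident:.6f}"])


_GAP_COLS = ("open_r", "open_c", "close_c")


def read_pssm_tsv(path: str, g_open: int = -10, g_ext: int = -1,
                  g_close: int = 0) -> Pssm:
    """Read a PSSM from the package's TSV dialect.

    Header row names the alphabet columns (one single-character column per
    residue), optionally followed by ``open_r``/``open_c``/``close_c``
    columns giving per-position gap penalties; one row per target position.
    Positions missing the optional columns fall back to the constant
    penalties supplied here.
    """
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t")
                if r and not r[0].startswith("#")]
    header = rows[0]
    res_cols = [c for c in header if c not in _GAP_COLS]
    if any(len(c) != 1 for c in res_cols):
        raise ValueError("alphabet columns must be single characters")
    symbols = "".join(res_cols)
    if symbols == DNA.symbols:
        alphabet: Alphabet = DNA
    elif symbols == PROTEIN.symbols:
        alphabet = PROTEIN
    else:
        alphabet = Alphabet(symbols)
    idx = {c: header.index(c) for c in header}
    n = len(rows) - 1
    profile = np.zeros((n, len(alphabet)), dtype=np.int64)
    g_open_r = np.full(n + 1, g_open, dtype=np.int64)
    g_open_c = np.full(n + 1, g_open, dtype=np.int64)
    g_close_c = np.full(n + 1, g_close, dtype=np.int64)
    for k, row in enumerate(rows[1:]):
        for a, ch in enumerate(alphabet.symbols):
            profile[k, a] = int(row[idx[ch]])
        if "open_r" in idx and row[idx["open_r"]] != "":
            g_open_r[k + 1] = int(row[idx["open_r"]])
        if "open_c" in idx and row[idx["open_c"]] != "":
            g_open_c[k + 1] = int(row[idx["open_c"]])
        if "close_c" in idx and row[idx["close_c"]] != "":
            g_close_c[k + 1] = int(row[idx["close_c"]])
    gaps = GapParams(g_ext, g_open_r, g_open_c, g_close_c)
    return Pssm(alphabet, profile, gaps)


def write_pssm_tsv(path: str, pssm: Pssm, include_gaps: bool = False) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        header = list(pssm.alphabet.symbols)
        if include_gaps:
            header += list(_GAP_COLS)
        w.writerow(header)
        g = pssm.gaps
        for k in range(len(pssm)):
            row = [int(v) for v in pssm.profile_scores[k]]
            if include_gaps:
                row += [int(g.g_open_r[k + 1]), int(g.g_open_c[k + 1]),
                        int(g.g_close_c[k + 1])]
            w.writerow(row)
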